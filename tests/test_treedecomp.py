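import pytest

import rnadesign as rd
from rnadesign.oracle import exact_treewidth, random_instance
from rnadesign.structures_io import parse_structures
from rnadesign.treedecomp import (
    Hypergraph,
    TreeDecomposition,
    build_cluster_tree,
    build_hypergraph,
    greedy_fillin,
    treewidth,
    validate_decomposition,
)


def _network(feats, n):
    return rd.build_network(feats, n=n)


def test_build_hypergraph_collects_dep_sets(st_params):
    net = _network([rd.gc_feature(3)], 3)
    assert build_hypergraph(net).hyperedges == frozenset(
        {frozenset({1}), frozenset({2}), frozenset({3})}
    )
    structs = parse_structures("()\n")
    net2 = _network([rd.gc_feature(2), rd.validity_feature(structs)], 2)
    assert build_hypergraph(net2).hyperedges == frozenset(
        {frozenset({1}), frozenset({2}), frozenset({1, 2})}
    )
    structs3 = parse_structures("((..))\n")
    net3 = _network([rd.stacking_feature(structs3[0], st_params, "E1")], 6)
    assert frozenset({1, 2, 5, 6}) in build_hypergraph(net3).hyperedges


def test_uncovered_positions_get_singleton_hyperedges():
    structs = parse_structures("((..))\n")
    net = _network([rd.validity_feature(structs)], 6)
    hg = build_hypergraph(net)
    assert frozenset({3}) in hg.hyperedges and frozenset({4}) in hg.hyperedges


def _graph_hg(n, edges):
    return Hypergraph(n=n, hyperedges=frozenset(frozenset(e) for e in edges))


@pytest.mark.parametrize(
    "hg,expected_width",
    [
        (_graph_hg(3, [(1, 2), (2, 3)]), 1),                      # path: a tree
        (_graph_hg(4, [(1, 2), (2, 3), (3, 4), (1, 4)]), 2),      # 4-cycle
        (_graph_hg(4, [(1, 3), (2, 4)]), 1),                      # matching
    ],
)
def test_greedy_fillin_widths(hg, expected_width):
    td = greedy_fillin(hg)
    assert validate_decomposition(td, hg).valid
    assert treewidth(td) == expected_width


def test_validate_decomposition_reports_violations():
    hg = _graph_hg(3, [(1, 2), (2, 3)])
    ok = TreeDecomposition(bags={0: frozenset({1, 2}), 1: frozenset({2, 3})},
                           edges=[(0, 1)])
    assert validate_decomposition(ok, hg).valid
    uncovered = TreeDecomposition(bags={0: frozenset({1}), 1: frozenset({2}),
                                        2: frozenset({3})}, edges=[(0, 1), (1, 2)])
    rep = validate_decomposition(uncovered, hg)
    assert frozenset({1, 2}) in rep.uncovered_hyperedges
    disconnected = TreeDecomposition(
        bags={0: frozenset({1, 2}), 1: frozenset({3}), 2: frozenset({2, 3})},
        edges=[(0, 1), (1, 2)],
    )
    rep2 = validate_decomposition(disconnected, hg)
    assert 2 in rep2.disconnected_vertices


def test_treewidth_definition():
    assert treewidth(TreeDecomposition(bags={0: frozenset({1, 2}),
                                             1: frozenset({2, 3})},
                                       edges=[(0, 1)])) == 1
    assert treewidth(TreeDecomposition(bags={0: frozenset({1, 2, 3, 4})},
                                       edges=[])) == 3
    assert treewidth(TreeDecomposition(bags={0: frozenset()}, edges=[])) == -1


@pytest.mark.parametrize("seed", range(12))
def test_greedy_fillin_valid_and_at_least_optimal(seed, st_params):
    """Min-fill decomposes random small instances validly, never below optimum."""
    structs = random_instance(8, 2, seed=seed, min_separation=1,
                              density=0.5, crossing_prob=0.3)
    feats = [rd.gc_feature(8), rd.validity_feature(structs),
             rd.stacking_feature(structs[0], st_params, "E1")]
    hg = build_hypergraph(_network(feats, 8))
    td = greedy_fillin(hg)
    assert validate_decomposition(td, hg).valid
    assert treewidth(td) >= exact_treewidth(hg)


@pytest.mark.parametrize(
    "hg,optimum",
    [
        (_graph_hg(6, [(1, 2), (2, 3), (4, 5)]), 1),                       # forest
        (_graph_hg(5, [(1, 2), (2, 3), (3, 4), (4, 5), (1, 5)]), 2),       # 5-cycle
        (_graph_hg(6, [(1, 4), (2, 5), (3, 6)]), 1),                       # matching
    ],
)
def test_greedy_fillin_exact_on_forests_and_cycles(hg, optimum):
    assert treewidth(greedy_fillin(hg)) == optimum == exact_treewidth(hg)


def test_cluster_tree_structure_and_partition(st_params):
    structs = parse_structures("((..))\n")
    net = _network([rd.gc_feature(6), rd.validity_feature(structs),
                    rd.stacking_feature(structs[0], st_params, "E1")], 6)
    td = greedy_fillin(build_hypergraph(net))
    ct = build_cluster_tree(td, net)
    assert ct.bags[ct.root] == ()
    assert ct.phi[ct.root] == []
    for u in ct.nodes:
        if u != ct.root:
            assert ct.intro(u) is not None  # exactly one new position per descent
    # phi partitions the contribution set
    assert sum(len(ct.phi[u]) for u in ct.nodes) == len(net.contributions)
    for u in ct.nodes:
        for c in ct.phi[u]:
            assert set(c.dep) <= set(ct.bags[u])
    # expansion never increases the width
    assert ct.width() == treewidth(td)


def test_cluster_tree_root_has_one_child_per_component():
    structs = parse_structures("().()\n")
    net = _network([rd.validity_feature(structs)], 5)
    td = greedy_fillin(build_hypergraph(net))
    ct = build_cluster_tree(td, net)
    # components: {1,2}, {3}, {4,5}
    assert len(ct.children[ct.root]) == 3


def test_cluster_tree_single_bag_expands_to_chain():
    net = _network([rd.validity_feature(parse_structures("()\n"))], 2)
    td = TreeDecomposition(bags={0: frozenset({1, 2})}, edges=[])
    ct = build_cluster_tree(td, net)
    order = ct.topological_order()
    assert [ct.bags[u] for u in order] == [(), (1,), (1, 2)]
    assert [len(ct.phi[u]) for u in order] == [0, 0, 1]


def test_export_td_text_format():
    from rnadesign.treedecomp import export_td

    td = TreeDecomposition(bags={0: frozenset({1, 2}), 1: frozenset({2, 3})},
                           edges=[(0, 1)])
    text = export_td(td)
    lines = text.strip().splitlines()
    assert lines[0] == "s td 2 2 3"
    assert "b 1 1 2" in lines and "b 2 2 3" in lines
    assert lines[-1] == "1 2"
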