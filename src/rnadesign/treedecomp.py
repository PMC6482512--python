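"""Tree decompositions of the contribution dependency hypergraph.

The dependency hypergraph has one vertex per sequence position and one
hyperedge per distinct dependency set of the contribution network. A tree
decomposition (Definition: a tree of *bags* covering every vertex and every
hyperedge, with the running-intersection property) guides the dynamic
programming: its *treewidth* (max bag size minus one) is the exponent of the
algorithm's complexity.

Decompositions are computed by a deterministic min-fill elimination
heuristic, validated against the defining conditions, and finally converted
into a rooted *cluster tree*: an empty-bag root, edges oriented towards it,
at most one new position introduced per parent-to-child step, and every
contribution assigned to exactly one bag containing its dependencies.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from rnadesign.feature_network import Contribution, ContributionSet

__all__ = [
    "Hypergraph",
    "TreeDecomposition",
    "ClusterTree",
    "ValidationReport",
    "build_hypergraph",
    "greedy_fillin",
    "validate_decomposition",
    "treewidth",
    "build_cluster_tree",
    "export_td",
]


@dataclass(frozen=True)
class Hypergraph:
    """Vertices 1..n and a set of nonempty hyperedges (position sets)."""

    n: int
    hyperedges: frozenset[frozenset[int]]

    def __post_init__(self):
        object.__setattr__(self, "hyperedges",
                           frozenset(frozenset(h) for h in self.hyperedges))
        for h in self.hyperedges:
            if not h:
                raise ValueError("empty hyperedge")
            if not all(1 <= v <= self.n for v in h):
                raise ValueError(f"hyperedge {set(h)} outside 1..{self.n}")

    def primal_adjacency(self) -> dict[int, set[int]]:
        """Adjacency of the primal graph: each hyperedge turned into a clique."""
        adj: dict[int, set[int]] = {v: set() for v in range(1, self.n + 1)}
        for h in self.hyperedges:
            for a, b in itertools.combinations(sorted(h), 2):
                adj[a].add(b)
                adj[b].add(a)
        return adj


@dataclass
class TreeDecomposition:
    """Bags indexed by node id and tree edges (a forest for disconnected graphs)."""

    bags: dict[int, frozenset[int]]
    edges: list[tuple[int, int]]

    def adjacency(self) -> dict[int, set[int]]:
        adj: dict[int, set[int]] = {u: set() for u in self.bags}
        for a, b in self.edges:
            adj[a].add(b)
            adj[b].add(a)
        return adj


@dataclass
class ValidationReport:
    """Outcome of checking the tree-decomposition conditions; empty => valid."""

    uncovered_vertices: list[int] = field(default_factory=list)
    uncovered_hyperedges: list[frozenset[int]] = field(default_factory=list)
    disconnected_vertices: list[int] = field(default_factory=list)

    @property
    def valid(self) -> bool:
        return not (self.uncovered_vertices or self.uncovered_hyperedges
                    or self.disconnected_vertices)


@dataclass
class ClusterTree:
    """Rooted tree decomposition with contributions partitioned over nodes.

    The root has an empty bag and no contributions; every other node
    introduces exactly one position not present in its parent's bag
    (``intro[u]``), which is the position sampled when descending into u.
    """

    root: int
    bags: dict[int, tuple[int, ...]]
    parent: dict[int, int]
    children: dict[int, list[int]]
    phi: dict[int, list[Contribution]]
    n: int

    @property
    def nodes(self) -> list[int]:
        return list(self.bags)

    def intro(self, u: int) -> int | None:
        """The single position introduced at non-root node u (None for the root)."""
        if u == self.root:
            return None
        new = set(self.bags[u]) - set(self.bags[self.parent[u]])
        if len(new) > 1:
            raise AssertionError(f"node {u} introduces {len(new)} positions")
        return next(iter(new), None)

    def separator(self, u: int) -> tuple[int, ...]:
        """sep(u, parent(u)) = bag(u) intersect bag(parent(u)), ascending."""
        return tuple(sorted(set(self.bags[u]) & set(self.bags[self.parent[u]])))

    def topological_order(self) -> list[int]:
        """Root-first order (parents before children), deterministic."""
        order = [self.root]
        i = 0
        while i < len(order):
            order.extend(self.children[order[i]])
            i += 1
        return order

    def width(self) -> int:
        return max(len(b) for b in self.bags.values()) - 1


def build_hypergraph(contribs: ContributionSet) -> Hypergraph:
    """Dependency hypergraph: one hyperedge per distinct dep set.

    Positions not covered by any contribution are added as singleton
    hyperedges, so the decomposition (and hence the sampler) still assigns
    them a nucleotide — uniformly, since no contribution constrains them.
    """
    if contribs.n < 1:
        raise ValueError("need at least one position")
    edges = {frozenset(c.dep) for c in contribs.contributions}
    covered = set().union(*edges) if edges else set()
    for v in range(1, contribs.n + 1):
        if v not in covered:
            edges.add(frozenset({v}))
    return Hypergraph(n=contribs.n, hyperedges=frozenset(edges))


def greedy_fillin(hg: Hypergraph) -> TreeDecomposition:
    """Min-fill elimination on the primal graph.

    Repeatedly eliminates the vertex whose neighborhood needs the fewest
    fill-in edges to become a clique (ties broken by smallest position, so
    the result is deterministic). Bags are the elimination cliques; each bag
    is attached to the bag of the earliest-eliminated remaining neighbor,
    and bags contained in an adjacent bag are merged away.
    """
    adj = hg.primal_adjacency()
    remaining = sorted(adj)
    elim_bags: list[tuple[int, frozenset[int]]] = []  # (eliminated vertex, bag)

    work = {v: set(nb) for v, nb in adj.items()}
    while remaining:
        best_v, best_fill = None, None
        for v in remaining:
            nbs = sorted(work[v])
            fill = sum(1 for a, b in itertools.combinations(nbs, 2)
                       if b not in work[a])
            if best_fill is None or fill < best_fill:
                best_v, best_fill = v, fill
        v = best_v
        nbs = sorted(work[v])
        elim_bags.append((v, frozenset([v] + nbs)))
        for a, b in itertools.combinations(nbs, 2):
            work[a].add(b)
            work[b].add(a)
        for a in nbs:
            work[a].discard(v)
        del work[v]
        remaining.remove(v)

    # attach each bag to the bag of its earliest-later-eliminated member
    elim_index = {v: i for i, (v, _) in enumerate(elim_bags)}
    bags = {i: bag for i, (_, bag) in enumerate(elim_bags)}
    edges = []
    for i, (v, bag) in enumerate(elim_bags):
        later = [elim_index[u] for u in bag if u != v]
        if later:
            edges.append((i, min(later)))

    return _merge_subset_bags(TreeDecomposition(bags=bags, edges=edges))


def _merge_subset_bags(td: TreeDecomposition) -> TreeDecomposition:
    """Contract any bag that is a subset of an adjacent bag."""
    bags = dict(td.bags)
    adj = td.adjacency()
    changed = True
    while changed:
        changed = False
        for u in sorted(bags):
            for v in sorted(adj[u]):
                if bags[u] <= bags[v]:
                    for w in adj[u]:
                        if w != v:
                            adj[w].discard(u)
                            adj[w].add(v)
                            adj[v].add(w)
                    adj[v].discard(u)
                    del bags[u], adj[u]
                    changed = True
                    break
            if changed:
                break
    edges = sorted({tuple(sorted((a, b))) for a in adj for b in adj[a]})
    return TreeDecomposition(bags=bags, edges=[tuple(e) for e in edges])


def validate_decomposition(td: TreeDecomposition, hg: Hypergraph) -> ValidationReport:
    """Check the three defining conditions; returns a report, never raises.

    (1) every vertex occurs in some bag; (2) the nodes containing a given
    vertex induce a connected subtree; (3) every hyperedge fits in some bag.
    """
    report = ValidationReport()
    all_in_bags = set().union(*td.bags.values()) if td.bags else set()
    for v in range(1, hg.n + 1):
        if v not in all_in_bags:
            report.uncovered_vertices.append(v)
    for h in sorted(hg.hyperedges, key=sorted):
        if not any(h <= bag for bag in td.bags.values()):
            report.uncovered_hyperedges.append(h)
    adj = td.adjacency()
    for v in sorted(all_in_bags):
        holding = {u for u, bag in td.bags.items() if v in bag}
        start = next(iter(holding))
        seen = {start}
        stack = [start]
        while stack:
            u = stack.pop()
            for w in adj[u]:
                if w in holding and w not in seen:
                    seen.add(w)
                    stack.append(w)
        if seen != holding:
            report.disconnected_vertices.append(v)
    return report


def treewidth(td: TreeDecomposition) -> int:
    """Max bag size minus 1 (-1 for the degenerate all-empty decomposition)."""
    if not td.bags:
        raise ValueError("empty tree decomposition")
    return max(len(b) for b in td.bags.values()) - 1


def build_cluster_tree(td: TreeDecomposition, contribs: ContributionSet) -> ClusterTree:
    """Root, orient, and expand a tree decomposition into a cluster tree.

    A dedicated root with empty bag is connected to one node of each
    connected component of the decomposition; edges are oriented towards the
    root; chains of intermediate bags are inserted so that each descent step
    introduces exactly one new position (in ascending position order, which
    keeps the construction deterministic and never increases the width);
    every contribution is assigned to the first eligible node in
    breadth-first order from the root.
    """
    hg = build_hypergraph(contribs)
    report = validate_decomposition(td, hg)
    if not report.valid:
        raise ValueError(f"invalid tree decomposition: {report}")

    adj = td.adjacency()
    # components, each represented by its smallest node id
    comp_reps = []
    seen: set[int] = set()
    for u in sorted(td.bags):
        if u in seen:
            continue
        comp_reps.append(u)
        stack = [u]
        seen.add(u)
        while stack:
            x = stack.pop()
            for w in adj[x]:
                if w not in seen:
                    seen.add(w)
                    stack.append(w)

    root = 0
    next_id = 1
    bags: dict[int, tuple[int, ...]] = {root: ()}
    parent: dict[int, int] = {}
    children: dict[int, list[int]] = {root: []}

    # BFS over the original decomposition, inserting expansion chains
    queue: list[tuple[int, int]] = []  # (original node, cluster-tree parent id)
    for rep in comp_reps:
        queue.append((rep, root))
    visited: set[int] = set()
    while queue:
        orig, par = queue.pop(0)
        visited.add(orig)
        bag = sorted(td.bags[orig])
        sep = sorted(set(bag) & set(bags[par]))
        diff = [p for p in bag if p not in bags[par]]
        cur = par
        grown = list(sep)
        for p in diff[:-1]:
            grown.append(p)
            grown.sort()
            node = next_id
            next_id += 1
            bags[node] = tuple(grown)
            parent[node] = cur
            children.setdefault(cur, []).append(node)
            children[node] = []
            cur = node
        node = next_id
        next_id += 1
        bags[node] = tuple(bag)
        parent[node] = cur
        children.setdefault(cur, []).append(node)
        children[node] = []
        for w in sorted(adj[orig]):
            if w not in visited:
                visited.add(w)
                queue.append((w, node))

    phi: dict[int, list[Contribution]] = {u: [] for u in bags}
    bfs_order = [root]
    i = 0
    while i < len(bfs_order):
        bfs_order.extend(children[bfs_order[i]])
        i += 1
    bag_sets = {u: set(bags[u]) for u in bags}
    for c in contribs.contributions:
        dep = set(c.dep)
        for u in bfs_order:
            if dep <= bag_sets[u]:
                phi[u].append(c)
                break
        else:
            raise ValueError(f"no bag contains dep {sorted(dep)}")

    return ClusterTree(root=root, bags=bags, parent=parent, children=children,
                       phi=phi, n=contribs.n)


def export_td(td: TreeDecomposition) -> str:
    """Render a decomposition in the PACE .td text format (for external cross-checks)."""
    node_ids = {u: i for i, u in enumerate(sorted(td.bags), start=1)}
    nverts = max((v for b in td.bags.values() for v in b), default=0)
    width = max((len(b) for b in td.bags.values()), default=0)
    lines = [f"s td {len(td.bags)} {width} {nverts}"]
    for u in sorted(td.bags):
        lines.append("b " + " ".join(str(x) for x in [node_ids[u]] + sorted(td.bags[u])))
    for a, b in sorted((min(node_ids[x], node_ids[y]), max(node_ids[x], node_ids[y]))
                       for x, y in td.edges):
        lines.append(f"{a} {b}")
    return "\n".join(lines) + "\n"
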