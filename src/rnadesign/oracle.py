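"""Brute-force references and fixture generation.

Everything here is deliberately independent of the message-passing engine:
partition functions and Boltzmann distributions by exhaustive enumeration
over all 4^n sequences, valid-sequence counting by constraint backtracking,
independent-set counting by branch recursion, exact treewidth by memoized
elimination, and a seeded random-structure generator for property tests.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from rnadesign.feature_network import (
    ALPHABET,
    CANONICAL_INDEX_PAIRS,
    ContributionSet,
    Feature,
    NT_INDEX,
)
from rnadesign.structures_io import DependencyGraph, TargetStructure
from rnadesign.treedecomp import Hypergraph

__all__ = [
    "ExactDistribution",
    "brute_force_partition",
    "brute_force_distribution",
    "count_valid_sequences",
    "count_valid_sequences_graph",
    "count_independent_sets",
    "random_instance",
    "exact_treewidth",
    "toy_basepair_params",
    "toy_stacking_params",
    "concatenated_hairpins",
    "two_target_instance",
]

_MAX_BRUTE_N = 10

_CANONICAL_SET = frozenset(CANONICAL_INDEX_PAIRS)


def _sequence_weights(contribs: ContributionSet) -> np.ndarray:
    """Boltzmann factor of every sequence, indexed base-4 (A=0..U=3), vectorized."""
    n = contribs.n
    if n > _MAX_BRUTE_N:
        raise ValueError(f"refusing brute force for n={n} > {_MAX_BRUTE_N}")
    size = 4 ** n
    idx = np.arange(size)
    digits = {p: (idx // 4 ** (n - p)) % 4 for p in range(1, n + 1)}
    total = np.ones(size)
    for c in contribs.contributions:
        p = len(c.dep)
        flat = np.zeros(size, dtype=np.int64)
        for q, pos in enumerate(c.dep):
            flat += digits[pos] * 4 ** (p - 1 - q)
        total *= np.exp(-c.table.ravel())[flat]
    return total


def brute_force_partition(contribs: ContributionSet) -> float:
    """Exact Z: sum over all 4^n sequences of prod_l pi_l^(-F_l(S))."""
    return float(_sequence_weights(contribs).sum())


@dataclass(frozen=True)
class ExactDistribution:
    """Exact Boltzmann distribution on an enumerable instance.

    ``probs`` maps each positive-probability sequence to its probability;
    zero-weight sequences (hard-constraint violators) are excluded.
    """

    probs: dict[str, float]

    def expectation(self, feature: Feature) -> float:
        """Exact E[F] under the distribution."""
        total = 0.0
        for s, p in self.probs.items():
            assignment = {i + 1: NT_INDEX[c] for i, c in enumerate(s)}
            total += p * sum(c.evaluate(assignment) for c in feature.contributions)
        return total


def brute_force_distribution(contribs: ContributionSet) -> ExactDistribution:
    """Normalized Boltzmann weights over all sequences, by full enumeration."""
    w = _sequence_weights(contribs)
    z = w.sum()
    if z == 0.0:
        raise ValueError("partition function is zero: no sequence has positive weight")
    n = contribs.n
    probs: dict[str, float] = {}
    for flat in np.flatnonzero(w):
        s = "".join(ALPHABET[(int(flat) // 4 ** (n - p)) % 4] for p in range(1, n + 1))
        probs[s] = float(w[flat] / z)
    return ExactDistribution(probs=probs)


def count_valid_sequences_graph(g: DependencyGraph) -> int:
    """Number of sequences whose every graph edge carries a canonical pair.

    Counts per connected component by backtracking over positions (checking
    each new letter only against already-assigned neighbors), multiplying
    component counts; isolated positions contribute a factor 4 each.
    """
    adj: dict[int, set[int]] = {v: set() for v in range(1, g.n + 1)}
    for a, b in g.edges:
        adj[a].add(b)
        adj[b].add(a)

    seen: set[int] = set()
    total = 1
    for start in range(1, g.n + 1):
        if start in seen:
            continue
        comp = [start]
        seen.add(start)
        qi = 0
        while qi < len(comp):  # BFS order: each later vertex touches an earlier one
            for w in sorted(adj[comp[qi]]):
                if w not in seen:
                    seen.add(w)
                    comp.append(w)
            qi += 1
        if len(comp) == 1:
            total *= 4
            continue
        pos_index = {v: i for i, v in enumerate(comp)}
        assigned = [0] * len(comp)

        def count_from(i: int) -> int:
            if i == len(comp):
                return 1
            v = comp[i]
            earlier = [pos_index[w] for w in adj[v] if pos_index[w] < i]
            c = 0
            for letter in range(4):
                if all((letter, assigned[j]) in _CANONICAL_SET for j in earlier):
                    assigned[i] = letter
                    c += count_from(i + 1)
            return c

        total *= count_from(0)
    return total


def count_valid_sequences(structures: list[TargetStructure]) -> int:
    """Number of sequences valid for every structure (all pairs canonical)."""
    from rnadesign.structures_io import base_pair_dependency_graph

    return count_valid_sequences_graph(base_pair_dependency_graph(structures))


def count_independent_sets(g: DependencyGraph) -> int:
    """Number of independent vertex subsets (the empty set included).

    Branch recursion count(G) = count(G - v) + count(G - N[v]) on the
    highest-degree vertex, per connected component.
    """
    adj: dict[int, frozenset[int]] = {v: frozenset() for v in range(1, g.n + 1)}
    tmp: dict[int, set[int]] = {v: set() for v in range(1, g.n + 1)}
    for a, b in g.edges:
        tmp[a].add(b)
        tmp[b].add(a)
    adj = {v: frozenset(nb) for v, nb in tmp.items()}

    def count(vertices: frozenset[int]) -> int:
        if not vertices:
            return 1
        v = max(vertices, key=lambda x: (len(adj[x] & vertices), x))
        if not (adj[v] & vertices):
            return 2 * count(vertices - {v})
        return count(vertices - {v}) + count(vertices - ({v} | adj[v]))

    return count(frozenset(adj))


def random_instance(
    n: int,
    k: int,
    seed: int,
    density: float = 0.3,
    crossing_prob: float = 0.2,
    min_separation: int = 3,
) -> list[TargetStructure]:
    """k random structures of length n, deterministic per seed.

    Pairs are drawn by repeatedly sampling disjoint (i, j) with
    j - i >= min_separation until round(density * n / 2) pairs are placed (or
    attempts run out); each draw ignores the nesting constraint with
    probability ``crossing_prob``, so pseudoknots appear at that rate. The
    default minimum separation mimics hairpin loop geometry; set it to 1 for
    adversarial dependency graphs.
    """
    if n < 1 or k < 1:
        raise ValueError("need n >= 1 and k >= 1")
    rng = np.random.default_rng(seed)
    structures = []
    target_pairs = int(round(density * n / 2))
    for _ in range(k):
        pairs: set[tuple[int, int]] = set()
        used: set[int] = set()
        attempts = 0
        while len(pairs) < target_pairs and attempts < 200 * max(n, 1):
            attempts += 1
            i = int(rng.integers(1, n + 1))
            j = int(rng.integers(1, n + 1))
            i, j = min(i, j), max(i, j)
            if j - i < min_separation or i in used or j in used:
                continue
            allow_crossing = rng.random() < crossing_prob
            if not allow_crossing and any(
                a < i < b < j or i < a < j < b for a, b in pairs
            ):
                continue
            pairs.add((i, j))
            used.update((i, j))
        structures.append(TargetStructure(length=n, pairs=frozenset(pairs)))
    return structures


def exact_treewidth(hg: Hypergraph) -> int:
    """Exact treewidth of the primal graph by memoized elimination.

    Minimizes, over all elimination orders, the largest elimination-clique
    size minus one; the graph obtained after eliminating any vertex set is
    order-independent (two survivors are adjacent iff joined by a path
    through eliminated vertices), which allows memoization on the remaining
    set. Exponential: intended for instances with at most ~14 vertices.
    """
    adj = hg.primal_adjacency()
    vertices = tuple(sorted(adj))
    if len(vertices) > 16:
        raise ValueError("exact treewidth limited to 16 vertices")

    def filled_degrees(remaining: frozenset[int]) -> dict[int, int]:
        eliminated = set(vertices) - remaining
        degs = {}
        for v in remaining:
            reach: set[int] = set()
            stack = [v]
            visited = {v}
            while stack:
                x = stack.pop()
                for w in adj[x]:
                    if w in visited:
                        continue
                    visited.add(w)
                    if w in remaining:
                        reach.add(w)
                    else:
                        stack.append(w)  # pass through eliminated vertices
            degs[v] = len(reach)
        return degs

    @lru_cache(maxsize=None)
    def best(remaining: frozenset[int]) -> int:
        if not remaining:
            return -1
        degs = filled_degrees(remaining)
        return min(max(degs[v], best(remaining - {v})) for v in remaining)

    result = best(frozenset(vertices))
    best.cache_clear()
    return result


def toy_basepair_params() -> "EnergyParams":
    """Explicit toy base-pair table: GC -3, AU -2, GU -1 kcal/mol (both orders)."""
    from rnadesign.feature_network import EnergyParams

    table = {}
    strength = {frozenset("GC"): -3.0, frozenset("AU"): -2.0, frozenset("GU"): -1.0}
    for a, b in CANONICAL_INDEX_PAIRS:
        table[ALPHABET[a] + ALPHABET[b]] = strength[frozenset((ALPHABET[a], ALPHABET[b]))]
    return EnergyParams(model="basepair", table=table)


def toy_stacking_params(base: float = -1.0, gc_bonus: float = -0.25) -> "EnergyParams":
    """Explicit toy stacking table: base + gc_bonus per GC pair in the stack.

    GU pairs score like AU; all 36 canonical combinations are written out.
    The gentle default slope keeps the feature variance small enough for the
    multiplicative calibration at gamma = 1.2 to be stable on ~50 nt
    instances (the expected value responds to the log-weight with slope
    -Var(F), so steep tables push the plain iteration into a limit cycle).
    """
    from rnadesign.feature_network import EnergyParams

    table = {}
    for xi, xj in CANONICAL_INDEX_PAIRS:
        for xi1, xj1 in CANONICAL_INDEX_PAIRS:
            v = base
            for a, b in ((xi, xj), (xi1, xj1)):
                if frozenset((ALPHABET[a], ALPHABET[b])) == frozenset("GC"):
                    v += gc_bonus
            key = ALPHABET[xi] + ALPHABET[xi1] + ALPHABET[xj1] + ALPHABET[xj]
            table[key] = v
    return EnergyParams(model="stacking", table=table)


def concatenated_hairpins(n: int, unit: str = "(((....)))") -> TargetStructure:
    """A length-n structure made of repeated short hairpins (constant treewidth).

    The dependency structure of each hairpin is independent of the others, so
    message passing on the family scales linearly in n at fixed width.
    """
    if n % len(unit) != 0:
        raise ValueError(f"n={n} must be a multiple of the unit length {len(unit)}")
    from rnadesign.structures_io import parse_structure

    return parse_structure(unit * (n // len(unit)))


def two_target_instance():
    """A two-structure design instance on 50 nt with the toy stacking model.

    Structure 1 is a single 21-bp hairpin (20 stacks); structure 2 has two
    10-bp hairpins (18 stacks). Returns (structures, features, n) with
    features GC, validity, E1, E2 at unit/default weights.
    """
    from rnadesign.feature_network import gc_feature, stacking_feature, validity_feature
    from rnadesign.structures_io import parse_structures

    r1 = "(" * 21 + "." * 8 + ")" * 21
    r2 = "(" * 10 + "." * 4 + ")" * 10 + "(" * 10 + "." * 4 + ")" * 10 + ".."
    structures = parse_structures(r1 + "\n" + r2 + "\n")
    params = toy_stacking_params()
    n = 50
    features = [
        gc_feature(n),
        validity_feature(structures),
        stacking_feature(structures[0], params, "E1"),
        stacking_feature(structures[1], params, "E2"),
    ]
    return structures, features, n
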