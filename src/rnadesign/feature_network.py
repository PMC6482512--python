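"""Features as sums of local contributions over sequence positions.

A *feature* F maps a sequence S over {A, C, G, U} to an extended real,
F(S) = sum of f(S restricted to dep(f)) over its *contributions* f. A value
of +inf encodes a hard constraint: the Boltzmann factor pi^(-F(S)) of such a
sequence is exactly 0 for every positive weight pi. The standard features are

* the GC feature (one unary contribution per position, -1 on G/C, 0 otherwise,
  so F counts G/C occurrences negated),
* the validity feature (one binary contribution per distinct base pair of any
  target structure: 0 on canonical pairs {AU, GC, GU}, +inf otherwise),
* base-pair and stacking energy features (table lookups in kcal/mol).

Weights are folded into the contributions by the transformation f -> ln(pi)*f,
since exp(-ln(pi)*f(S)) = pi^(-f(S)); the weighted network is then a plain
sum of transformed contributions.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from rnadesign.structures_io import TargetStructure

__all__ = [
    "ALPHABET",
    "NT_INDEX",
    "CANONICAL_PAIRS",
    "Contribution",
    "Feature",
    "ContributionSet",
    "EnergyParams",
    "gc_feature",
    "validity_feature",
    "basepair_feature",
    "stacking_feature",
    "build_network",
    "evaluate_feature",
    "evaluate_sequence_features",
]

ALPHABET = "ACGU"
NT_INDEX = {c: i for i, c in enumerate(ALPHABET)}

#: Canonical (Watson-Crick + wobble) pairs, unordered.
CANONICAL_PAIRS = frozenset(
    frozenset(p) for p in [("A", "U"), ("G", "C"), ("G", "U")]
)


def _is_canonical(a: int, b: int) -> bool:
    return frozenset((ALPHABET[a], ALPHABET[b])) in CANONICAL_PAIRS


#: ordered index pairs (a, b) with {a, b} canonical
CANONICAL_INDEX_PAIRS = tuple(
    (a, b) for a in range(4) for b in range(4) if _is_canonical(a, b)
)


@dataclass(frozen=True)
class Contribution:
    """A local term of a feature: a table over assignments of a few positions.

    ``dep`` is the ordered tuple of distinct positions (ascending, 1-based);
    ``table`` has shape ``(4,)*len(dep)`` indexed in A, C, G, U order along
    each axis, with values in R union {+inf}.
    """

    dep: tuple[int, ...]
    table: np.ndarray
    feature_id: str

    def __post_init__(self):
        dep = tuple(self.dep)
        if len(set(dep)) != len(dep):
            raise ValueError(f"dep positions must be distinct: {dep}")
        if dep != tuple(sorted(dep)):
            raise ValueError(f"dep positions must be ascending: {dep}")
        table = np.asarray(self.table, dtype=float)
        if table.shape != (4,) * len(dep):
            raise ValueError(f"table shape {table.shape} != {(4,) * len(dep)}")
        if np.isnan(table).any() or (np.isinf(table) & (table < 0)).any():
            raise ValueError("table values must be in R union {+inf}")
        table = table.copy()
        table.setflags(write=False)
        object.__setattr__(self, "dep", dep)
        object.__setattr__(self, "table", table)

    def evaluate(self, assignment: dict[int, int]) -> float:
        """Value under a partial assignment position -> nucleotide index.

        The assignment domain may be any superset of ``dep``; superfluous
        positions are ignored.
        """
        idx = tuple(assignment[p] for p in self.dep)
        return float(self.table[idx])


@dataclass
class Feature:
    """A named feature: a set of contributions, a positive weight, an optional target."""

    id: str
    contributions: list[Contribution]
    weight: float = 1.0
    target: float | None = None

    def __post_init__(self):
        if self.weight <= 0:
            raise ValueError(f"feature weight must be positive, got {self.weight}")
        for c in self.contributions:
            if c.feature_id != self.id:
                raise ValueError(
                    f"contribution feature_id {c.feature_id!r} != feature id {self.id!r}"
                )


@dataclass(frozen=True)
class ContributionSet:
    """Weight-transformed contributions (each equal to ln(pi)*f) plus the length n.

    exp(-sum of transformed contributions on S) equals the Boltzmann factor
    prod_l pi_l^(-F_l(S)).
    """

    contributions: tuple[Contribution, ...]
    n: int


@dataclass(frozen=True)
class EnergyParams:
    """Energy parameter table for the base-pair or stacking model.

    Keys are nucleotide tuples flattened to strings in dependency order:
    2 letters ``(s_i, s_j)`` for the base-pair model, 4 letters
    ``(s_i, s_{i+1}, s_{j-1}, s_j)`` for the stacking model. Values are
    kcal/mol. No symmetry folding is applied: symmetric parameterizations
    must be written out. Missing canonical tuples default to 0; tuples with a
    non-canonical pair are +inf (forbidden).
    """

    model: str
    table: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.model not in ("basepair", "stacking"):
            raise ValueError(f"unknown model {self.model!r}")
        klen = 2 if self.model == "basepair" else 4
        for key in self.table:
            if len(key) != klen or any(c not in NT_INDEX for c in key):
                raise ValueError(f"bad parameter key {key!r} for model {self.model}")

    @classmethod
    def from_json(cls, path: str | Path) -> "EnergyParams":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(model=obj["model"], table={k: float(v) for k, v in obj["params"].items()})

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({"model": self.model, "params": self.table}, fh, indent=1, sort_keys=True)

    def basepair_value(self, a: int, b: int) -> float:
        """kcal/mol for the ordered pair (S_i, S_j); +inf if non-canonical."""
        if not _is_canonical(a, b):
            return math.inf
        return self.table.get(ALPHABET[a] + ALPHABET[b], 0.0)

    def stack_value(self, xi: int, xi1: int, xj1: int, xj: int) -> float:
        """kcal/mol for a stack (S_i, S_{i+1}, S_{j-1}, S_j); +inf if either pair non-canonical."""
        if not (_is_canonical(xi, xj) and _is_canonical(xi1, xj1)):
            return math.inf
        key = ALPHABET[xi] + ALPHABET[xi1] + ALPHABET[xj1] + ALPHABET[xj]
        return self.table.get(key, 0.0)


def gc_feature(n: int, feature_id: str = "GC", weight: float = 1.0,
               target: float | None = None) -> Feature:
    """GC-count feature: n unary contributions, -1 on G or C, 0 on A or U.

    F(S) = -(#G + #C), so larger weights favor GC-rich sequences.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    unary = np.array([0.0, -1.0, -1.0, 0.0])  # A, C, G, U
    contribs = [Contribution(dep=(i,), table=unary, feature_id=feature_id)
                for i in range(1, n + 1)]
    return Feature(id=feature_id, contributions=contribs, weight=weight, target=target)


def _validity_table() -> np.ndarray:
    t = np.full((4, 4), np.inf)
    for a, b in CANONICAL_INDEX_PAIRS:
        t[a, b] = 0.0
    return t


def validity_feature(structures: list[TargetStructure], feature_id: str = "BP",
                     weight: float = 1.0) -> Feature:
    """Hard canonical-pairing constraint over all structures.

    One binary contribution per distinct base pair occurring in any structure;
    0 iff the pair is canonical ({AU, GC, GU}, either orientation), else +inf.
    The feature value is 0 exactly on sequences valid for every structure.
    """
    n = structures[0].length if structures else 0
    for s in structures:
        if s.length != n:
            raise ValueError("structures must share a common length")
    table = _validity_table()
    pairs = sorted({p for s in structures for p in s.pairs})
    contribs = [Contribution(dep=(i, j), table=table, feature_id=feature_id)
                for i, j in pairs]
    return Feature(id=feature_id, contributions=contribs, weight=weight)


def basepair_feature(structure: TargetStructure, params: EnergyParams,
                     feature_id: str, weight: float = 1.0,
                     target: float | None = None) -> Feature:
    """Base-pair model energy of one structure: sum of DG(S_i, S_j) over its pairs."""
    if params.model != "basepair":
        raise ValueError(f"params.model must be 'basepair', got {params.model!r}")
    contribs = []
    for i, j in sorted(structure.pairs):
        table = np.array([[params.basepair_value(a, b) for b in range(4)]
                          for a in range(4)])
        contribs.append(Contribution(dep=(i, j), table=table, feature_id=feature_id))
    return Feature(id=feature_id, contributions=contribs, weight=weight, target=target)


def stacking_feature(structure: TargetStructure, params: EnergyParams,
                     feature_id: str, weight: float = 1.0,
                     target: float | None = None) -> Feature:
    """Stacking model energy: sum of DG(S_i, S_j, S_{i+1}, S_{j-1}) over stacks.

    A stack is an index pair where both (i, j) and (i+1, j-1) are pairs of the
    structure; the contribution depends on positions {i, i+1, j-1, j} and is
    +inf whenever either pair is non-canonical. Structures without stacks
    yield an empty contribution set (feature value 0).
    """
    if params.model != "stacking":
        raise ValueError(f"params.model must be 'stacking', got {params.model!r}")
    contribs = []
    for i, j in structure.stacks():
        # table axes follow ascending dep order (i, i+1, j-1, j)
        table = np.empty((4, 4, 4, 4))
        for xi, xi1, xj1, xj in itertools.product(range(4), repeat=4):
            table[xi, xi1, xj1, xj] = params.stack_value(xi, xi1, xj1, xj)
        contribs.append(Contribution(dep=(i, i + 1, j - 1, j), table=table,
                                     feature_id=feature_id))
    return Feature(id=feature_id, contributions=contribs, weight=weight, target=target)


def _transform_table(table: np.ndarray, weight: float) -> np.ndarray:
    """ln(pi)*f with +inf preserved regardless of the weight (hard constraints stay hard)."""
    hard = np.isinf(table)
    out = np.where(hard, np.inf, math.log(weight) * np.where(hard, 0.0, table))
    return out


def build_network(features: list[Feature], n: int | None = None) -> ContributionSet:
    """Fold feature weights into their contributions: the weighted network.

    Each contribution f of a feature with weight pi becomes ln(pi)*f, so
    that exp(-sum) over the network equals prod_l pi_l^(-F_l(S)); +inf
    entries stay +inf (Boltzmann factor exactly 0) for every positive weight.
    """
    if n is None:
        n = max((p for f in features for c in f.contributions for p in c.dep), default=0)
    transformed = []
    for feat in features:
        if feat.weight <= 0:
            raise ValueError(f"non-positive weight for feature {feat.id!r}")
        for c in feat.contributions:
            transformed.append(Contribution(
                dep=c.dep,
                table=_transform_table(c.table, feat.weight),
                feature_id=feat.id,
            ))
    return ContributionSet(contributions=tuple(transformed), n=n)


def evaluate_feature(feature: Feature, sequence: str) -> float:
    """F(S): sum of contribution values on a full sequence; +inf absorbs."""
    assignment = {i + 1: NT_INDEX[c] for i, c in enumerate(sequence)}
    total = 0.0
    for c in feature.contributions:
        v = c.evaluate(assignment)
        if math.isinf(v):
            return math.inf
        total += v
    return total


def evaluate_sequence_features(features: list[Feature], sequence: str) -> dict[str, float]:
    """Per-feature values of a full sequence, keyed by feature id."""
    return {f.id: evaluate_feature(f, sequence) for f in features}
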