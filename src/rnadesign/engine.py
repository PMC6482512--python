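"""Partition-function message passing and stochastic backtracking.

Messages are passed leaves-to-root over the cluster tree: the message from a
node u to its parent v tabulates, for every partial sequence over the
separator sep(u, v), the partition function of the subtree below u. The
total partition function is the product of the 0-ary messages received by
the (empty-bag) root. Sampling then traverses the tree root-to-leaves,
drawing the one position introduced at each node from its conditional
distribution given the positions already fixed; the resulting full-sequence
law is exactly the Boltzmann distribution P(S) = prod_l pi_l^(-F_l(S)) / Z.

Tables hold Boltzmann factors (not logs) in double precision; each node
table is rescaled by its maximum and the log of the scale is accumulated, so
Z is reported as (mantissa, log-scale) and never overflows for long
sequences or extreme weights.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from rnadesign.feature_network import (
    ALPHABET,
    ContributionSet,
    Feature,
    build_network,
)
from rnadesign.treedecomp import (
    ClusterTree,
    build_cluster_tree,
    build_hypergraph,
    greedy_fillin,
)

__all__ = [
    "Message",
    "Messages",
    "PartitionValue",
    "SampleRecord",
    "compute_messages",
    "partition_function",
    "sample",
    "make_sampler",
    "draw_samples",
]

_NT = np.array(list(ALPHABET))


@dataclass(frozen=True)
class PartitionValue:
    """A nonnegative real stored as mantissa * exp(log_scale)."""

    mantissa: float
    log_scale: float = 0.0

    def to_float(self) -> float:
        """Plain float value (may overflow to inf for extreme instances)."""
        return self.mantissa * math.exp(self.log_scale)

    def log(self) -> float:
        """Natural log of the value (-inf if zero)."""
        if self.mantissa == 0.0:
            return -math.inf
        return math.log(self.mantissa) + self.log_scale

    @property
    def is_zero(self) -> bool:
        return self.mantissa == 0.0


@dataclass(frozen=True)
class Message:
    """Partition functions of the subtree of ``source`` per separator assignment.

    ``table`` has shape (4,)*len(dep) (a scalar array for the 0-ary message
    to the root) and is rescaled so its maximum is 1; the true values carry
    the factor exp(log_scale).
    """

    source: int
    target: int
    dep: tuple[int, ...]
    table: np.ndarray
    log_scale: float


@dataclass
class Messages:
    """All upward messages, plus the per-node joint tables used for sampling.

    ``node_table[u]`` is the (rescaled) product of the local contribution
    factors at u and all incoming child messages, tabulated over the full bag
    of u — exactly the quantity whose marginals drive stochastic backtracking.
    """

    by_edge: dict[tuple[int, int], Message] = field(default_factory=dict)
    node_table: dict[int, np.ndarray] = field(default_factory=dict)
    node_log: dict[int, float] = field(default_factory=dict)


def _aligned(table: np.ndarray, dep: tuple[int, ...], bag: tuple[int, ...]) -> np.ndarray:
    """Reshape a table over dep (ascending) to broadcast over the bag's axes."""
    shape = tuple(4 if p in dep else 1 for p in bag)
    return table.reshape(shape)


def compute_messages(ct: ClusterTree) -> Messages:
    """Pass messages from the leaves to the root (the partition-function DP).

    For each edge u -> v the message is the sum, over nucleotide assignments
    of bag(u) \\ sep(u, v), of the product of the factors exp(-f) of the
    contributions assigned to u and of all messages received from u's
    children, evaluated consistently with the separator assignment.
    """
    msgs = Messages()
    order = ct.topological_order()
    for u in reversed(order):
        if u == ct.root:
            continue
        bag = ct.bags[u]
        dep_set = set(bag)
        table = np.ones((4,) * len(bag))
        log_acc = 0.0
        for c in ct.phi[u]:
            table = table * _aligned(np.exp(-c.table), c.dep, bag)
        for child in ct.children[u]:
            m = msgs.by_edge[(child, u)]
            table = table * _aligned(m.table, m.dep, bag)
            log_acc += m.log_scale
        peak = table.max() if table.size else 1.0
        if peak > 0.0:
            table = table / peak
            log_acc += math.log(peak)
        msgs.node_table[u] = table
        msgs.node_log[u] = log_acc
        sep = ct.separator(u)
        sum_axes = tuple(i for i, p in enumerate(bag) if p not in sep)
        out = table.sum(axis=sum_axes) if sum_axes else table.copy()
        msgs.by_edge[(u, ct.parent[u])] = Message(
            source=u, target=ct.parent[u], dep=sep, table=out, log_scale=log_acc
        )
        del dep_set
    return msgs


def partition_function(ct: ClusterTree, messages: Messages) -> PartitionValue:
    """Product of the 0-ary messages sent to the root: the weighted Z.

    Equals the sum over all sequences of prod_l pi_l^(-F_l(S)); sequences
    violating a hard (+inf) contribution contribute factor 0.
    """
    log_scale = 0.0
    for child in ct.children[ct.root]:
        m = messages.by_edge[(child, ct.root)]
        v = float(m.table)
        if v == 0.0:
            return PartitionValue(0.0, 0.0)
        log_scale += math.log(v) + m.log_scale
    return PartitionValue(1.0, log_scale)


@dataclass(frozen=True)
class SampleRecord:
    """One sampled sequence with its per-feature values and the weights used."""

    sequence: str
    feature_values: dict[str, float]
    weights_used: dict[str, float]


def sample(
    ct: ClusterTree,
    messages: Messages,
    rng: np.random.Generator,
    count: int,
    features: list[Feature] | None = None,
) -> list[SampleRecord]:
    """Draw ``count`` sequences from the Boltzmann distribution.

    Traverses the cluster tree from the root; at each node the single newly
    introduced position is drawn with probability proportional to the node's
    joint table, sliced at the already-fixed separator assignment (inverse
    CDF in fixed A, C, G, U order, so the stream is pinned by the seed). All
    samples are drawn in one vectorized pass per node.
    """
    if partition_function(ct, messages).is_zero:
        raise ValueError("no valid sequence exists (partition function is zero)")
    n = ct.n
    seq = np.zeros((count, n), dtype=np.int64)
    for u in ct.topological_order():
        if u == ct.root:
            continue
        bag = ct.bags[u]
        new = ct.intro(u)
        table = messages.node_table[u]
        axis = bag.index(new)
        moved = np.moveaxis(table, axis, -1)
        fixed = [p for p in bag if p != new]
        if fixed:
            probs = moved[tuple(seq[:, p - 1] for p in fixed)]
        else:
            probs = np.broadcast_to(moved, (count, 4))
        totals = probs.sum(axis=1)
        r = rng.random(count) * totals
        cdf = np.cumsum(probs, axis=1)
        draw = np.minimum((cdf <= r[:, None]).sum(axis=1), 3)
        # guard against rounding landing on a zero-probability cell
        bad = probs[np.arange(count), draw] == 0.0
        if bad.any():
            for i in np.flatnonzero(bad):
                draw[i] = np.flatnonzero(probs[i])[-1]
        seq[:, new - 1] = draw

    weights = {f.id: f.weight for f in features} if features else {}
    values = np.zeros((count, len(features) if features else 0))
    ids: list[str] = []
    if features:
        for fi, feat in enumerate(features):
            ids.append(feat.id)
            for c in feat.contributions:
                values[:, fi] += c.table[tuple(seq[:, p - 1] for p in c.dep)]
    letters = _NT[seq]
    records = []
    for i in range(count):
        records.append(SampleRecord(
            sequence="".join(letters[i]),
            feature_values={ids[j]: float(values[i, j]) for j in range(len(ids))},
            weights_used=dict(weights),
        ))
    return records


def make_sampler(features: list[Feature], n: int) -> tuple[ClusterTree, Messages]:
    """Full pipeline from features to a ready-to-sample cluster tree.

    Builds the weighted network, its dependency hypergraph, a min-fill tree
    decomposition, the rooted cluster tree, and all messages.
    """
    network = build_network(features, n=n)
    hg = build_hypergraph(network)
    td = greedy_fillin(hg)
    ct = build_cluster_tree(td, network)
    return ct, compute_messages(ct)


def draw_samples(
    features: list[Feature],
    n: int,
    rng: np.random.Generator,
    count: int,
) -> list[SampleRecord]:
    """Convenience wrapper: make_sampler + sample with feature annotation."""
    ct, msgs = make_sampler(features, n)
    return sample(ct, msgs, rng, count, features=features)
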