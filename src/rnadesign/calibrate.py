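"""Multidimensional Boltzmann calibration of feature weights.

Given per-feature targets (energies in kcal/mol for each target structure,
a GC count), the calibration loop alternates sampling at the current
weights, estimating per-feature sample means, and applying the
multiplicative update

    pi_l  <-  pi_l * gamma^(mean_l - target_l),       gamma > 1,

starting from the thermodynamically natural weights pi^[0] = e^beta with
beta = 1/(RT) at 37 C. Because the expected value of each feature is
decreasing in its own weight, the update steers every mean towards its
target; iteration stops when all means are within tolerance. A final
rejection step keeps only samples whose targeted values lie in the interval
with endpoints target*(1-eps) and target*(1+eps) (absolute half-width
eps*n for the GC feature, whose target may be near zero).

Energies of a richer model (e.g. full nearest-neighbor energies from an
external evaluator) relate to stacking-model energies by a structure-specific
affine law E_full ~ slope*E_st + intercept; fitting that law on a homogeneous
sample allows re-targeting the simple model so the rich-model target is hit
on average.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from rnadesign.engine import (
    SampleRecord,
    make_sampler,
    partition_function,
    sample,
)
from rnadesign.feature_network import Feature

__all__ = [
    "GAS_CONSTANT_KCAL",
    "TEMPERATURE_K",
    "BETA",
    "CalibrationOptions",
    "CalibrationResult",
    "AffineFit",
    "DesignInstance",
    "estimate_means",
    "update_weights",
    "learn_weights",
    "rejection_filter",
    "affine_fit",
    "adjust_target",
    "multidefect",
]

#: gas constant in kcal/(mol*K) and physiological temperature (37 C)
GAS_CONSTANT_KCAL = 1.98717e-3
TEMPERATURE_K = 310.15
#: 1/(RT) in mol/kcal: the inverse temperature making e^(-beta*E) dimensionless
BETA = 1.0 / (GAS_CONSTANT_KCAL * TEMPERATURE_K)


@dataclass
class CalibrationOptions:
    """Knobs of the adaptive loop.

    gamma is the base of the multiplicative weight update (> 1; larger means
    more aggressive steps); epsilon the relative half-width of the final
    rejection interval; tolerance the per-feature absolute stopping
    tolerance on |mean - target| (a scalar applies to every feature;
    energies are in kcal/mol, the GC feature in counts). max_step clamps the
    update exponent to [-max_step, max_step]: far from the target the raw
    update gamma^(mean - target) can jump by orders of magnitude and throw
    the means from one saturation regime to the other; the clamp is a trust
    region that leaves the fixed point, and the update within max_step of the
    target, unchanged. None disables it.

    The loop additionally adapts the clamp per feature: the expected feature
    value responds to the log-weight with local slope -Var(F), so for
    high-variance features (e.g. the GC count of a long sequence) a fixed
    base gamma overshoots and the plain iteration settles into a limit cycle
    around the target instead of converging. Whenever the sign of
    (mean - target) flips, the per-feature clamp is halved (down to
    min_step); while the sign persists it is grown by factor gamma back up
    to max_step. This is the standard sign-based step-size control, leaves
    the fixed point unchanged, and reduces to the raw update when the
    iteration is already stable.
    """

    gamma: float = 1.2
    samples_per_iter: int = 100
    max_iters: int = 100
    tolerance: float | dict[str, float] = 0.5
    epsilon: float = 0.1
    beta: float = BETA
    max_step: float | None = 5.0
    min_step: float = 0.1

    def __post_init__(self):
        if self.gamma <= 1:
            raise ValueError(f"gamma must be > 1, got {self.gamma}")
        if self.epsilon < 0:
            raise ValueError(f"epsilon must be >= 0, got {self.epsilon}")

    def tol(self, feature_id: str) -> float:
        if isinstance(self.tolerance, dict):
            return self.tolerance[feature_id]
        return float(self.tolerance)


@dataclass
class DesignInstance:
    """The design problem handed to the calibration loop: features over length n."""

    features: list[Feature]
    n: int

    def with_weights(self, weights: dict[str, float]) -> list[Feature]:
        return [replace(f, weight=weights.get(f.id, f.weight)) for f in self.features]


@dataclass
class CalibrationResult:
    """Learned weights with the iteration trace (for diagnostics and logging)."""

    weights: dict[str, float]
    converged: bool
    iterations: int
    trace: list[dict] = field(default_factory=list)
    samples: list[SampleRecord] = field(default_factory=list)


def estimate_means(samples: list[SampleRecord]) -> dict[str, float]:
    """Arithmetic mean of each annotated feature over the sample set."""
    if not samples:
        raise ValueError("cannot estimate means from an empty sample set")
    ids = samples[0].feature_values.keys()
    return {
        fid: float(np.mean([s.feature_values[fid] for s in samples])) for fid in ids
    }


def update_weights(
    weights: dict[str, float],
    means: dict[str, float],
    targets: dict[str, float],
    gamma: float,
    max_step: float | None = None,
) -> dict[str, float]:
    """Multiplicative update pi <- pi * gamma^(mean - target), targeted features only.

    With ``max_step`` the exponent is clamped to [-max_step, max_step]
    (trust region; the update is unchanged whenever |mean - target| <= max_step).
    """
    if gamma <= 1:
        raise ValueError(f"gamma must be > 1, got {gamma}")
    out = dict(weights)
    for fid, target in targets.items():
        step = means[fid] - target
        if max_step is not None:
            step = max(-max_step, min(max_step, step))
        out[fid] = weights[fid] * gamma ** step
    return out


def learn_weights(
    instance: DesignInstance,
    targets: dict[str, float],
    opts: CalibrationOptions,
    rng: np.random.Generator,
) -> CalibrationResult:
    """Iterate sample -> estimate means -> update weights until targets are met.

    Messages are recomputed each iteration, since the weights enter the
    contribution tables. Convergence: every |mean_l - target_l| within the
    per-feature tolerance, judged on the current iteration's sample only.
    On non-convergence the best-seen weights (smallest worst-case
    tolerance-scaled deviation) are returned with ``converged=False``.
    """
    weights = {f.id: (math.exp(opts.beta) if f.id in targets else f.weight)
               for f in instance.features}
    best: CalibrationResult | None = None
    best_score = math.inf
    trace: list[dict] = []
    step_cap = {fid: opts.max_step for fid in targets}
    prev_sign: dict[str, int] = {}
    for t in range(opts.max_iters):
        feats = instance.with_weights(weights)
        ct, msgs = make_sampler(feats, instance.n)
        if partition_function(ct, msgs).is_zero:
            raise ValueError("infeasible instance: partition function is zero")
        samples = sample(ct, msgs, rng, opts.samples_per_iter, features=feats)
        means = estimate_means(samples)
        deviations = {fid: means[fid] - targets[fid] for fid in targets}
        trace.append({
            "iteration": t,
            "weights": dict(weights),
            "means": {fid: means[fid] for fid in targets},
            "targets": dict(targets),
        })
        score = max(abs(d) / opts.tol(fid) for fid, d in deviations.items())
        if score < best_score:
            best_score = score
            best = CalibrationResult(
                weights=dict(weights), converged=False, iterations=t + 1,
                trace=trace, samples=samples,
            )
        if all(abs(d) <= opts.tol(fid) for fid, d in deviations.items()):
            return CalibrationResult(
                weights=dict(weights), converged=True, iterations=t + 1,
                trace=trace, samples=samples,
            )
        if opts.max_step is not None:
            for fid, d in deviations.items():
                sign = (d > 0) - (d < 0)
                if fid in prev_sign and sign and sign != prev_sign[fid]:
                    step_cap[fid] = max(step_cap[fid] / 2.0, opts.min_step)
                elif sign and prev_sign.get(fid) == sign:
                    step_cap[fid] = min(step_cap[fid] * opts.gamma, opts.max_step)
                if sign:
                    prev_sign[fid] = sign
            for fid in targets:
                weights[fid] = weights[fid] * opts.gamma ** max(
                    -step_cap[fid], min(step_cap[fid], deviations[fid]))
        else:
            weights = update_weights(weights, means, targets, opts.gamma)
    assert best is not None
    best.trace = trace
    return best


def rejection_filter(
    samples: list[SampleRecord],
    targets: dict[str, float],
    epsilon: float,
    absolute_tolerances: dict[str, float] | None = None,
) -> list[SampleRecord]:
    """Keep samples whose every targeted value lies in its acceptance interval.

    The interval for a target E* is [E*(1-eps), E*(1+eps)] with endpoints
    sorted, so negative energy targets behave symmetrically. Features listed
    in ``absolute_tolerances`` (typically the GC feature, whose target can be
    near zero) use the absolute interval [E* - a, E* + a] instead. The filter
    is idempotent.
    """
    if epsilon < 0:
        raise ValueError(f"epsilon must be >= 0, got {epsilon}")
    absolute_tolerances = absolute_tolerances or {}
    intervals: dict[str, tuple[float, float]] = {}
    for fid, target in targets.items():
        if fid in absolute_tolerances:
            a = absolute_tolerances[fid]
            intervals[fid] = (target - a, target + a)
        else:
            lo, hi = sorted((target * (1 - epsilon), target * (1 + epsilon)))
            intervals[fid] = (lo, hi)
    kept = []
    for s in samples:
        if all(intervals[fid][0] <= s.feature_values[fid] <= intervals[fid][1]
               for fid in targets):
            kept.append(s)
    return kept


@dataclass(frozen=True)
class AffineFit:
    """Least-squares affine relation between two energy models."""

    slope: float
    intercept: float
    r2: float


def affine_fit(simple_energies, full_energies) -> AffineFit:
    """Fit full ~ slope*simple + intercept by least squares."""
    x = np.asarray(simple_energies, dtype=float)
    y = np.asarray(full_energies, dtype=float)
    if x.size < 3 or x.size != y.size:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0.0:
        raise ValueError("degenerate fit: simple energies have zero variance")
    res = stats.linregress(x, y)
    return AffineFit(slope=float(res.slope), intercept=float(res.intercept),
                     r2=float(res.rvalue) ** 2)


def adjust_target(full_target: float, fit: AffineFit) -> float:
    """Map a rich-model target into the simple model: (target - intercept)/slope."""
    if fit.slope == 0.0:
        raise ValueError("cannot adjust target with zero slope")
    return (full_target - fit.intercept) / fit.slope


def multidefect(per_structure_energies, ensemble_energy: float) -> float:
    """Multi-target design objective (lower is better).

    Mean distance of the per-structure energies from the ensemble free
    energy, plus the mean pairwise energy dispersion:

        (1/m) sum_l (E_l - G) + (1/(2*C(m,2))) sum_{l<j} |E_l - E_j|,

    with the dispersion term defined as 0 for a single structure. Zero iff
    every target achieves the ensemble free energy.
    """
    energies = list(per_structure_energies)
    m = len(energies)
    if m < 1:
        raise ValueError("need at least one energy")
    first = sum(e - ensemble_energy for e in energies) / m
    if m == 1:
        return first
    pairs = m * (m - 1) // 2
    second = sum(abs(energies[a] - energies[b])
                 for a in range(m) for b in range(a + 1, m)) / (2 * pairs)
    return first + second
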