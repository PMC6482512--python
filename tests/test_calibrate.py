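import math

import numpy as np
import pytest

import rnadesign as rd
from rnadesign.calibrate import (
    BETA,
    CalibrationOptions,
    DesignInstance,
    adjust_target,
    affine_fit,
    estimate_means,
    learn_weights,
    multidefect,
    rejection_filter,
    update_weights,
)
from rnadesign.engine import SampleRecord
from rnadesign.oracle import brute_force_distribution


def _records(values, fid="E1"):
    return [SampleRecord(sequence="A", feature_values={fid: v}, weights_used={})
            for v in values]


def test_estimate_means():
    assert estimate_means(_records([-10, -20]))["E1"] == -15
    assert estimate_means(_records([-7.5]))["E1"] == -7.5
    assert estimate_means(_records([3, 3, 3]))["E1"] == 3
    with pytest.raises(ValueError):
        estimate_means([])


def test_update_weights_multiplicative_rule():
    w = update_weights({"E1": 1.0}, {"E1": -8.0}, {"E1": -10.0}, gamma=1.2)
    assert w["E1"] == pytest.approx(1.2 ** 2)  # mean - target = 2
    same = update_weights({"E1": 3.0}, {"E1": -10.0}, {"E1": -10.0}, gamma=1.2)
    assert same["E1"] == 3.0
    up = update_weights({"E1": 1.0}, {"E1": -5.0}, {"E1": -10.0}, gamma=1.5)
    assert up["E1"] > 1.0  # mean above target -> raise weight -> lower the mean
    clamped = update_weights({"E1": 1.0}, {"E1": 40.0}, {"E1": 0.0},
                             gamma=1.2, max_step=2.0)
    assert clamped["E1"] == pytest.approx(1.2 ** 2)
    with pytest.raises(ValueError):
        update_weights({}, {}, {}, gamma=1.0)


def test_expected_feature_value_monotone_in_weight():
    """Exact E[GC feature] strictly decreases as its weight grows."""
    structs = rd.parse_structures("(..)\n")
    values = []
    gc = rd.gc_feature(4)
    for pi in (0.5, 1.0, 2.0, 4.0, 8.0):
        feats = [rd.gc_feature(4, weight=pi), rd.validity_feature(structs)]
        dist = brute_force_distribution(rd.build_network(feats, 4))
        values.append(dist.expectation(gc))
    assert all(a > b for a, b in zip(values, values[1:]))


def test_learn_weights_gc_target_converges():
    """GC-only instance: per-position odds solve the target in closed form."""
    n, g = 20, 0.5
    inst = DesignInstance(features=[rd.gc_feature(n)], n=n)
    opts = CalibrationOptions(tolerance=0.5, max_iters=50)
    res = learn_weights(inst, {"GC": -g * n}, opts, np.random.default_rng(2))
    assert res.converged and res.iterations <= 50
    final = res.trace[res.iterations - 1]
    assert abs(final["means"]["GC"] + 10) <= 0.5
    assert res.weights["GC"] > 0


def test_learn_weights_immediate_convergence_at_matching_target():
    """Targets equal to the initial-weight means converge in one iteration."""
    n = 10
    pi0 = math.exp(BETA)
    exact_mean = -n * pi0 / (1 + pi0)  # per-position G/C probability pi/(1+pi)
    inst = DesignInstance(features=[rd.gc_feature(n)], n=n)
    opts = CalibrationOptions(tolerance=0.5, samples_per_iter=400)
    res = learn_weights(inst, {"GC": exact_mean}, opts, np.random.default_rng(0))
    assert res.converged and res.iterations == 1


def test_learn_weights_infeasible_instance_raises():
    structs = [rd.TargetStructure(3, {(1, 2)}), rd.TargetStructure(3, {(2, 3)}),
               rd.TargetStructure(3, {(1, 3)})]
    inst = DesignInstance(
        features=[rd.gc_feature(3), rd.validity_feature(structs)], n=3)
    with pytest.raises(ValueError, match="infeasible"):
        learn_weights(inst, {"GC": -1.5}, CalibrationOptions(),
                      np.random.default_rng(0))


def test_learn_weights_reports_non_convergence():
    """An unreachable target (below the feature minimum) is flagged, not hidden."""
    inst = DesignInstance(features=[rd.gc_feature(4)], n=4)
    opts = CalibrationOptions(tolerance=0.5, max_iters=5)
    res = learn_weights(inst, {"GC": -40.0}, opts, np.random.default_rng(1))
    assert not res.converged
    assert len(res.trace) == 5


def test_rejection_filter_intervals_and_idempotence():
    recs = _records([-19.0, -25.0, -18.0, -22.0, -20.0])
    kept = rejection_filter(recs, {"E1": -20.0}, epsilon=0.1)
    assert [r.feature_values["E1"] for r in kept] == [-19.0, -18.0, -22.0, -20.0]
    assert rejection_filter(kept, {"E1": -20.0}, epsilon=0.1) == kept
    assert rejection_filter(recs, {"E1": -20.0}, epsilon=0.0) == [recs[4]]
    assert rejection_filter(recs, {"E1": -20.0}, epsilon=10.0) == recs


def test_rejection_filter_absolute_tolerance_for_gc():
    recs = _records([-9.0, -13.0, -11.5], fid="GC")
    kept = rejection_filter(recs, {"GC": -11.0}, epsilon=0.1,
                            absolute_tolerances={"GC": 2.0})
    assert [r.feature_values["GC"] for r in kept] == [-9.0, -13.0, -11.5]
    tight = rejection_filter(recs, {"GC": -11.0}, epsilon=0.1,
                             absolute_tolerances={"GC": 1.0})
    assert [r.feature_values["GC"] for r in tight] == [-11.5]


def test_affine_fit_and_target_adjustment():
    x = np.arange(10, dtype=float)
    fit = affine_fit(x, 2 * x + 3)
    assert fit.slope == pytest.approx(2.0)
    assert fit.intercept == pytest.approx(3.0)
    assert fit.r2 == pytest.approx(1.0)
    with pytest.raises(ValueError):
        affine_fit([1.0, 1.0, 1.0], [2.0, 3.0, 4.0])
    with pytest.raises(ValueError):
        affine_fit([1.0, 2.0], [1.0, 2.0])

    rng = np.random.default_rng(42)
    xs = rng.uniform(-5, 5, size=100)
    noisy = affine_fit(xs, 2 * xs + 3 + rng.normal(0, 0.1, size=100))
    assert 1.9 <= noisy.slope <= 2.1

    assert adjust_target(-17.0, rd.AffineFit(2.0, 3.0, 1.0)) == -10.0
    assert adjust_target(5.5, rd.AffineFit(1.0, 0.0, 1.0)) == 5.5
    assert adjust_target(4.0, rd.AffineFit(0.5, -1.0, 1.0)) == 10.0
    with pytest.raises(ValueError):
        adjust_target(1.0, rd.AffineFit(0.0, 0.0, 1.0))


def test_multidefect_values_and_properties():
    assert multidefect([-10.0], -12.0) == pytest.approx(2.0)
    assert multidefect([-10.0, -10.0], -10.0) == pytest.approx(0.0)
    assert multidefect([-8.0, -12.0], -12.0) == pytest.approx(4.0)
    # nonnegative whenever G lower-bounds the energies; zero iff all equal G
    assert multidefect([-5.0, -4.0, -3.0], -5.0) >= 0
    assert multidefect([-5.0, -5.0, -5.0], -5.0) == 0
    with pytest.raises(ValueError):
        multidefect([], -1.0)
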