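"""Tests of the cutoff-selection engine: standardization, windows, spatial
weights, coordinate smoothing, the power sweep and the jackknife."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

import ircut
from ircut.engine import P_GRID, _smoothed_mean_curves
from ircut.errors import DegenerateInputError, DomainError

from conftest import make_two_group_instance


# ---------------------------------------------------------------------------
# standardization

def test_standardize_example_and_roundtrip():
    pair = ircut.standardize([1.0, 2.0, 3.0], [10.0, 30.0, 20.0])
    np.testing.assert_allclose(pair.xz, [-1.0, 0.0, 1.0])
    np.testing.assert_allclose(pair.xz * pair.x_sd + pair.x_mean, [1, 2, 3],
                               atol=1e-12)
    np.testing.assert_allclose(pair.yz * pair.y_sd + pair.y_mean, [10, 30, 20],
                               atol=1e-12)
    assert pair.xz.mean() == pytest.approx(0.0, abs=1e-9)
    assert pair.xz.std(ddof=1) == pytest.approx(1.0, abs=1e-9)


def test_standardize_rejects_constant_or_tiny_input():
    with pytest.raises(DegenerateInputError):
        ircut.standardize([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])
    with pytest.raises(DegenerateInputError):
        ircut.standardize([1.0, 2.0], [1.0, 2.0])


@given(
    hnp.arrays(
        float,
        st.integers(min_value=3, max_value=25),
        elements=st.floats(-1e6, 1e6, allow_nan=False),
    ).filter(lambda a: np.std(a) > 1e-9)
)
def test_standardize_roundtrip_property(values):
    other = np.arange(values.size, dtype=float)
    pair = ircut.standardize(values, other)
    np.testing.assert_allclose(
        pair.xz * pair.x_sd + pair.x_mean, values, rtol=1e-9, atol=1e-6
    )


# ---------------------------------------------------------------------------
# windows

def test_window_separation_matsuda_like():
    values = np.array([3.7, 1.0, 2.0, 4.3, 9.0, 16.6])
    ir = np.array([True, True, True, False, False, False])
    win = ircut.window_midpoint(values, ir, "IR_low")
    assert win.kind == "separation"
    assert win.midpoint == pytest.approx(4.0)


def test_window_overlap_ir_high():
    values = np.array([6.0, 10.0, 5.0, 8.0])
    ir = np.array([True, True, False, False])
    win = ircut.window_midpoint(values, ir, "IR_high")
    assert win.kind == "overlap"
    assert win.midpoint == pytest.approx(7.0)  # (min IR 6 + max nonIR 8)/2


def test_window_identical_extremes_is_overlap():
    values = np.array([2.0, 5.0, 5.0, 9.0])
    ir = np.array([True, True, False, False])
    win = ircut.window_midpoint(values, ir, "IR_low")
    assert win.kind == "overlap"
    assert win.midpoint == pytest.approx(5.0)


def test_window_requires_both_groups():
    with pytest.raises(DegenerateInputError):
        ircut.window_midpoint([1.0, 2.0], [True, True], "IR_low")


# ---------------------------------------------------------------------------
# weight matrix

def test_weight_matrix_hand_example():
    xz = np.array([0.0, 3.0, 6.0])
    yz = np.array([0.0, 4.0, 8.0])
    W = ircut.build_weight_matrix(xz, yz, p=1.0)
    np.testing.assert_allclose(
        W.entries, [[0.0, 1.0, 0.0], [0.5, 0.0, 0.5], [0.0, 1.0, 0.0]], atol=1e-12
    )


def test_weight_matrix_equidistant_uniform_fallback():
    # equilateral triangle: all pairwise distances equal
    xz = np.array([0.0, 1.0, 0.5])
    yz = np.array([0.0, 0.0, np.sqrt(3) / 2])
    W = ircut.build_weight_matrix(xz, yz, p=1.3)
    np.testing.assert_allclose(
        W.entries, [[0, 0.5, 0.5], [0.5, 0, 0.5], [0.5, 0.5, 0]], atol=1e-12
    )


def test_weight_matrix_duplicate_points_get_highest_weight():
    xz = np.array([0.0, 0.0, 3.0, 5.0])
    yz = np.array([0.0, 0.0, 0.0, 0.0])
    W = ircut.build_weight_matrix(xz, yz, p=1.0)
    assert np.isfinite(W.entries).all()
    # the duplicate pair dominates its rows
    assert W.entries[0, 1] == W.entries[0].max()
    assert W.entries[1, 0] == W.entries[1].max()


@given(
    seed=st.integers(0, 10_000),
    n=st.integers(3, 20),
    p=st.sampled_from([0.5, 0.77, 1.0, 1.62, 2.5]),
)
def test_weight_matrix_contract_properties(seed, n, p):
    """Zero diagonal, nonnegative entries, unit row sums for any power."""
    rng = np.random.default_rng(seed)
    xz, yz = rng.standard_normal((2, n))
    W = ircut.build_weight_matrix(xz, yz, p).entries
    assert np.all(np.diag(W) == 0)
    assert np.all(W >= 0)
    np.testing.assert_allclose(W.sum(axis=1), 1.0, atol=1e-9)


def test_weight_matrix_rejects_bad_power_or_size():
    with pytest.raises(DomainError):
        ircut.build_weight_matrix([0.0, 1.0, 2.0], [0.0, 1.0, 2.0], p=0.0)
    with pytest.raises(DegenerateInputError):
        ircut.build_weight_matrix([0.0, 1.0], [0.0, 1.0], p=1.0)


def test_fast_power_curves_match_materialized_matrices():
    """The vectorized power-sweep path reproduces mean(W_p @ v) computed from
    the explicitly built weight matrix at every probed power."""
    rng = np.random.default_rng(5)
    xz, yz = rng.standard_normal((2, 17))
    xz = (xz - xz.mean()) / xz.std(ddof=1)
    yz = (yz - yz.mean()) / yz.std(ddof=1)
    a, b = _smoothed_mean_curves(xz, yz, P_GRID)
    for k in [0, 50, 100, 137, 200]:
        W = ircut.build_weight_matrix(xz, yz, float(P_GRID[k])).entries
        assert a[k] == pytest.approx((W @ xz).mean(), abs=1e-9)
        assert b[k] == pytest.approx((W @ yz).mean(), abs=1e-9)


# ---------------------------------------------------------------------------
# spearman, smoothing, distance

def test_spearman_examples():
    assert ircut.spearman_r([1, 2, 3, 4], [10, 20, 30, 40]) == pytest.approx(1.0)
    assert ircut.spearman_r([1, 2, 3, 4], [9, 7, 5, 3]) == pytest.approx(-1.0)
    assert ircut.spearman_r([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)
    with pytest.raises(DegenerateInputError):
        ircut.spearman_r([1, 1, 1], [1, 2, 3])


def test_smoothing_limits_and_hand_example():
    pair = ircut.standardize([1.0, 2.0, 3.0], [3.0, 1.0, 2.0])
    W = ircut.build_weight_matrix(np.array([0.0, 3.0, 6.0]),
                                  np.array([0.0, 4.0, 8.0]), 1.0)
    x0, y0 = ircut.smooth_coordinates(W, pair, r=0.0)
    np.testing.assert_allclose(x0, pair.xz)
    np.testing.assert_allclose(y0, pair.yz)
    x0, y0 = ircut.smooth_coordinates(W, pair, r=1.0)
    np.testing.assert_allclose(x0, W.entries @ pair.xz)
    # r^2 = 0.25 with W xz = 0 leaves 0.75 xz
    x0, _ = ircut.smooth_coordinates(W, pair, r=0.5)
    np.testing.assert_allclose(x0, 0.75 * pair.xz, atol=1e-12)


def test_candidate_distance_examples():
    assert ircut.candidate_distance([0.0], [0.0], 3.0, 4.0) == pytest.approx(5.0)
    assert ircut.candidate_distance([1.0], [1.0], 1.0, 0.0) == pytest.approx(1.0)
    assert ircut.candidate_distance([2.0], [7.0], 2.0, 7.0) == pytest.approx(0.0)


# ---------------------------------------------------------------------------
# power sweep

def test_sweep_grid_contract():
    assert P_GRID.size == 201
    assert P_GRID[0] == 0.50 and P_GRID[-1] == 2.50
    rng = np.random.default_rng(2)
    x = rng.normal(5.0, 2.0, 30)
    y = 2.0 * x + rng.normal(0.0, 1.0, 30)
    ir = x < np.median(x)
    pair = ircut.standardize(x, y)
    r = ircut.spearman_r(x, y)
    xwin = ircut.window_midpoint(pair.xz, ir, "IR_low")
    ywin = ircut.window_midpoint(pair.yz, ir, "IR_low")
    cand = ircut.sweep_power(pair, (xwin, ywin), r)
    assert 0.50 <= cand.p <= 2.50
    assert cand.cutoff_y == pytest.approx(cand.y0_mean * pair.y_sd + pair.y_mean)
    # the sweep minimum cannot exceed the p=1 distance, computed independently
    W1 = ircut.build_weight_matrix(pair.xz, pair.yz, 1.0)
    x0, y0 = ircut.smooth_coordinates(W1, pair, r)
    d1 = ircut.candidate_distance(x0, y0, xwin.midpoint, ywin.midpoint)
    assert cand.distance <= d1 + 1e-12


def test_sweep_orientation_follows_correlation_sign():
    rng = np.random.default_rng(3)
    x = rng.normal(0.0, 1.0, 25)
    ir = x < 0
    pair = ircut.standardize(x, -x + rng.normal(0, 0.1, 25))
    r = ircut.spearman_r(pair.xz, pair.yz)
    win_x = ircut.window_midpoint(pair.xz, ir, "IR_low")
    win_y = ircut.window_midpoint(pair.yz, ir, "IR_high")
    assert ircut.sweep_power(pair, (win_x, win_y), r).orientation == "high_is_IR"


# ---------------------------------------------------------------------------
# jackknife selection

def test_jackknife_on_cleanly_separated_groups_matches_oracle():
    rng = np.random.default_rng(0)
    n = 20
    ir = np.zeros(n, dtype=bool)
    ir[:10] = True
    x = np.where(ir, 2.0, 8.0) + rng.normal(0, 0.8, n)
    y = np.where(ir, 10.0, 2.0) + rng.normal(0, 1.0, n)
    res = ircut.jackknife_select(x, y, ir)
    gap_lo, gap_hi = y[~ir].max(), y[ir].min()
    assert res.youden == pytest.approx(1.0)
    assert res.sensitivity == 1.0 and res.specificity == 1.0
    assert gap_lo < res.cutoff < gap_hi
    _, _, oracle = ircut.brute_force_best_cutoff(ir, y)
    assert res.youden == pytest.approx(oracle)


def test_jackknife_replicate_count_and_errors():
    rng = np.random.default_rng(1)
    x, y, ir = make_two_group_instance(rng, separated=True)
    curves = ircut.JackknifeCurves(x, y)
    assert len(curves._replicates) == x.size
    with pytest.raises(DegenerateInputError):
        ircut.jackknife_select(x, y, np.zeros(x.size, dtype=bool))
    with pytest.raises(DegenerateInputError):
        ircut.jackknife_select([1.0, 2.0, 3.0], [1.0, 2.0, 3.0],
                               [True, False, True])


def test_scale_equivariance_of_cutoff():
    """y -> a*y + b (a > 0) rescales the cutoff and leaves the confusion
    metrics unchanged."""
    rng = np.random.default_rng(4)
    x, y, ir = make_two_group_instance(rng, separated=False)
    base = ircut.jackknife_select(x, y, ir)
    a, b = 3.7, -21.0
    scaled = ircut.jackknife_select(x, a * y + b, ir)
    assert scaled.cutoff == pytest.approx(a * base.cutoff + b, rel=1e-9)
    assert scaled.sensitivity == pytest.approx(base.sensitivity)
    assert scaled.specificity == pytest.approx(base.specificity)
    assert scaled.youden == pytest.approx(base.youden)


def test_label_symmetry_under_sign_flip():
    rng = np.random.default_rng(6)
    x, y, ir = make_two_group_instance(rng, separated=False)
    base = ircut.jackknife_select(x, y, ir)
    flipped = ircut.jackknife_select(x, -y, ir)
    assert flipped.spearman_r == pytest.approx(-base.spearman_r)
    assert flipped.youden == pytest.approx(base.youden)
    assert flipped.cutoff == pytest.approx(-base.cutoff)


def test_parameter_recovery_cutoff_inside_known_gap():
    """With a known inter-group gap the selected cutoff falls inside it in
    >= 99% of 500 seeded replications."""
    hits = 0
    for seed in range(500):
        rng = np.random.default_rng(seed)
        x, y, ir = make_two_group_instance(rng, n_lo=20, n_hi=30, separated=True)
        res = ircut.jackknife_select(x, y, ir)
        if y[ir].min() > y[~ir].max():
            gap = (y[~ir].max(), y[ir].min())
        else:
            gap = (y[ir].max(), y[~ir].min())
        hits += gap[0] < res.cutoff < gap[1]
    assert hits >= 495


# ---------------------------------------------------------------------------
# Matsuda reference refinement

def test_refine_on_bimodal_matsuda_lands_in_gap():
    rng = np.random.default_rng(8)
    nonir = rng.uniform(4.3, 16.6, 48)
    ir = rng.uniform(0.6, 3.7, 45)
    m = np.concatenate([nonir, ir])
    cutoff, labels = ircut.refine_matsuda_cutoff(m, 4.0)
    assert 3.7 < cutoff < 4.3
    np.testing.assert_array_equal(labels, m <= cutoff)
    summary = ircut.confusion(labels, m, cutoff, "low_is_IR")
    assert summary.fp == 0 and summary.fn == 0
    assert summary.sensitivity == 1.0 and summary.specificity == 1.0


def test_refine_requires_threshold_inside_range():
    m = np.array([1.0, 2.0, 8.0, 9.0])
    with pytest.raises(DomainError):
        ircut.refine_matsuda_cutoff(m, 0.5)
    with pytest.raises(DomainError):
        ircut.refine_matsuda_cutoff(m, 20.0)


def test_refine_is_stable_to_initial_threshold(default_panel):
    """Different admissible starting thresholds converge to the same cutoff
    on a cohort with a clear Matsuda gap."""
    m = default_panel["matsuda"].to_numpy()
    c1, l1 = ircut.refine_matsuda_cutoff(m, 3.5)
    c2, l2 = ircut.refine_matsuda_cutoff(m, 4.5)
    assert c1 == pytest.approx(c2)
    np.testing.assert_array_equal(l1, l2)
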