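"""Quadric tuning surfaces, Q index, and speed/scale axis angles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from speedscale import QuadricTuningSurface, axes_angles, fit_quadric, q_index
from speedscale.tuning import QuadricFit


def _coords(cmap):
    return np.array([[c.log2_sf, c.log2_tf] for c in cmap.values()])


def _eval_quadric(q, x, t):
    return q[0] + q[1] * x + q[2] * t + q[3] * x**2 + q[4] * x * t + q[5] * t**2


def test_noiseless_quadric_recovered_exactly(cmap, rng):
    X = _coords(cmap)
    q_true = np.array([0.3, -1.2, 0.8, -0.5, 0.25, -0.9])
    y = _eval_quadric(q_true, X[:, 0], X[:, 1])
    fit = fit_quadric(np.column_stack([X, y]))
    np.testing.assert_allclose(fit.coefficients, q_true, atol=1e-8)
    assert fit.adjusted_r2 == pytest.approx(1.0, abs=1e-9)


def test_rank_deficient_design_raises():
    x = np.linspace(0, 1, 10)
    pts = np.column_stack([x, 2 * x, np.ones(10)])  # collinear coordinates
    with pytest.raises(ValueError, match="rank-deficient"):
        fit_quadric(pts)


def test_separable_log_gaussian_has_no_cross_term(cmap):
    X = _coords(cmap)
    log_amp = -((X[:, 0] + 1.0) ** 2) / (2 * 0.8**2) - (X[:, 1] - 3.5) ** 2 / (
        2 * 0.8**2
    )
    fit = fit_quadric(np.column_stack([X, log_amp]))
    assert fit.coefficients[4] == pytest.approx(0.0, abs=1e-8)
    assert q_index(fit) == pytest.approx(-1.0, abs=1e-8)


def test_speed_tuned_surface_q_relation(cmap):
    X = _coords(cmap)
    v = X[:, 1] - X[:, 0]
    log_amp = -((v - math.log2(24)) ** 2) / (2 * 1.0**2)
    fit = fit_quadric(np.column_stack([X, log_amp]))
    q = fit.coefficients
    assert q[4] == pytest.approx(-2 * q[5], abs=1e-8)
    assert q_index(fit) == pytest.approx(0.0, abs=1e-8)


def test_q_index_direct_substitution():
    fit = QuadricFit(np.array([0, 0, 0, -1.0, 0.0, -1.0]), 1.0)
    assert q_index(fit) == pytest.approx(-1.0)
    degenerate = QuadricFit(np.array([0, 0, 0, -1.0, 0.5, 0.0]), 1.0)
    assert q_index(degenerate) is None


def test_q_index_invariant_to_axis_rescaling_and_offset(cmap):
    X = _coords(cmap)
    q_true = np.array([0.1, 0.4, -0.3, -0.7, 0.2, -0.5])
    y = _eval_quadric(q_true, X[:, 0], X[:, 1])
    q0 = q_index(fit_quadric(np.column_stack([X, y])))
    for a in (0.5, 2.0):
        fit_scaled = fit_quadric(np.column_stack([a * X, y]))
        assert q_index(fit_scaled) == pytest.approx(q0, abs=1e-8)
    fit_off = fit_quadric(np.column_stack([X, y + 7.3]))
    assert q_index(fit_off) == pytest.approx(q0, abs=1e-8)


def test_phi_anchor_angles(cmap):
    X = _coords(cmap)
    # speed-tuned surface (function of t - x): main axis along the speed axis
    y_speed = -((X[:, 1] - X[:, 0] - 4.0) ** 2)
    ang = axes_angles(fit_quadric(np.column_stack([X, y_speed])))
    assert ang.phi == pytest.approx(0.0, abs=1e-6)
    # function of spatial frequency only: main axis at -45 deg
    y_sf = -((X[:, 0] + 1.0) ** 2)
    ang_sf = axes_angles(fit_quadric(np.column_stack([X, y_sf])))
    assert ang_sf.phi == pytest.approx(-45.0, abs=1e-6)
    # function of temporal frequency only: +45 deg
    y_tf = -((X[:, 1] - 3.5) ** 2)
    ang_tf = axes_angles(fit_quadric(np.column_stack([X, y_tf])))
    assert ang_tf.phi == pytest.approx(45.0, abs=1e-6)


def _brute_force_theta(q, u_range=(-2, 2), w_range=(-6, 6), n=2001):
    """Oracle: per-speed argmax over a dense scale grid, then a line fit,
    in the same speed/scale angle convention."""
    us = np.linspace(*u_range, 41)
    ws = np.linspace(*w_range, n)
    # (x, t) from speed-scale coordinates
    locs = []
    for u in us:
        x = (ws - u) / math.sqrt(2)
        t = (ws + u) / math.sqrt(2)
        r = _eval_quadric(q, x, t)
        locs.append(ws[np.argmax(r)])
    slope = np.polyfit(us, locs, 1)[0]
    # direction (du, dw) = (1, slope); angle = atan2(-du, dw)
    ang = math.degrees(math.atan2(-1.0, slope))
    ang = (ang + 90.0) % 180.0 - 90.0
    return 90.0 if ang == -90.0 else ang


def test_theta_matches_brute_force_argmax_oracle(rng):
    for _ in range(10):
        q = np.concatenate([rng.normal(0, 1, 3), -np.abs(rng.normal(1, 0.3, 3))])
        q[4] = rng.normal(0, 0.4)
        fit = QuadricFit(q, 1.0)
        ang = axes_angles(fit)
        if not ang.theta_defined:
            continue
        oracle = _brute_force_theta(q)
        # compare as axial angles (mod 180)
        diff = abs(ang.theta - oracle) % 180.0
        assert min(diff, 180.0 - diff) < 1.0


def test_theta_anchor_iso_sf_locus(cmap):
    # surface depending only on x has its per-speed maxima on an iso-sf line
    X = _coords(cmap)
    y = -((X[:, 0] + 1.0) ** 2) - 0.001 * (X[:, 1] - X[:, 0]) ** 2
    ang = axes_angles(fit_quadric(np.column_stack([X, y])))
    assert ang.theta == pytest.approx(-45.0, abs=0.1)


def test_saddle_is_flagged():
    fit = QuadricFit(np.array([0, 0, 0, 1.0, 0.0, -1.0]), 1.0)
    assert axes_angles(fit).saddle


def test_estimator_api(cmap):
    X = _coords(cmap)
    y = -((X[:, 1] - X[:, 0] - 4.0) ** 2) + 5.0
    est = QuadricTuningSurface().fit(X, y)
    np.testing.assert_allclose(est.predict(X), y, atol=1e-8)
    assert est.q_index_ == pytest.approx(0.0, abs=1e-8)
    assert est.get_params() == {"q5_tol": 1e-12}


@settings(deadline=None, max_examples=25, derandomize=True)
@given(
    q=st.lists(st.floats(-2, 2), min_size=6, max_size=6),
)
def test_fit_is_exact_interpolation_for_any_quadric(q):
    rng = np.random.default_rng(7)
    X = rng.uniform(-3, 3, size=(12, 2))
    if np.linalg.matrix_rank(
        np.column_stack(
            [np.ones(12), X[:, 0], X[:, 1], X[:, 0] ** 2, X[:, 0] * X[:, 1], X[:, 1] ** 2]
        )
    ) < 6:
        return
    y = _eval_quadric(np.array(q), X[:, 0], X[:, 1])
    fit = fit_quadric(np.column_stack([X, y]))
    np.testing.assert_allclose(
        _eval_quadric(fit.coefficients, X[:, 0], X[:, 1]), y, atol=1e-7
    )


def test_tuning_table_recovers_surface_per_window(cmap):
    from speedscale import tuning_table
    from speedscale.traces import WINDOWS_MS, TrialSet, window_stats

    # traces whose window means follow a known speed-tuned surface
    traces = {}
    for cid, c in cmap.items():
        amp = float(np.exp(-((c.log2_tf - c.log2_sf - np.log2(24)) ** 2) / 2.0))
        traces[cid] = np.full((6, 400), 5.0 * amp)
    table = tuning_table(window_stats(TrialSet(traces=traces)), cmap)
    assert len(table) == len(WINDOWS_MS)
    assert set(table.columns) >= {"q0", "q5", "adjusted_r2", "q_index", "theta", "phi"}
    # raw-amplitude fit of a speed-tuned surface: main axis near the speed axis
    assert np.all(np.abs(table.phi) < 15.0)
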