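"""Quadric spatiotemporal tuning surfaces and the speed/scale axes.

Response amplitude over the 15 stimulus coordinates is fitted with a quadric
R(x, t) = q0 + q1 x + q2 t + q3 x^2 + q4 x t + q5 t^2 in (x, t) = (log2 sf,
log2 tf).  From the fit we extract:

* Q = -(1 + q4 / (2 q5)): the separability index (0 = speed tuned,
  -1 = independent spatial/temporal frequency coding);
* Theta: the angle of the max speed-scale locus (the scale maximizing R at
  each stimulus speed; analytically a straight line for a quadric);
* Phi: the angle of the surface's main (major) axis.

Angle convention: angles are measured from the speed axis (the iso-velocity
direction), positive rotating so the temporal-frequency axis sits at +45 deg
and the spatial-frequency axis at -45 deg; the scale axis is at 90 deg.  For
an undirected direction (dx, dt) the angle is
atan2(dx - dt, dx + dt) folded into (-90, 90].
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "QuadricFit",
    "AxesAngles",
    "QuadricTuningSurface",
    "fit_quadric",
    "q_index",
    "axes_angles",
    "speed_scale_angle",
]


def speed_scale_angle(dx: float, dt: float) -> float:
    """Angle (deg, in (-90, 90]) of a direction in the log-frequency plane,
    measured from the speed (iso-velocity) axis."""
    ang = math.degrees(math.atan2(dx - dt, dx + dt))
    ang = (ang + 90.0) % 180.0 - 90.0
    return 90.0 if ang == -90.0 else ang


@dataclass(frozen=True)
class QuadricFit:
    coefficients: np.ndarray  # q0..q5
    adjusted_r2: float

    @property
    def q(self) -> np.ndarray:
        return self.coefficients


@dataclass(frozen=True)
class AxesAngles:
    theta: float | None  # max speed-scale axis vs speed axis (deg)
    phi: float  # main axis vs speed axis (deg)
    saddle: bool = False
    theta_defined: bool = True


def _design(x: np.ndarray, t: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones_like(x), x, t, x**2, x * t, t**2])


class QuadricTuningSurface(BaseEstimator, RegressorMixin):
    """Least-squares quadric fit to response amplitudes over log frequency.

    X is (n, 2) with columns (log2 sf, log2 tf); y are response amplitudes.
    Fitted attributes: ``coef_`` (q0..q5), ``adjusted_r2_``, ``q_index_``,
    ``theta_``, ``phi_``, ``saddle_``.
    """

    def __init__(self, q5_tol: float = 1e-12):
        self.q5_tol = q5_tol

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must be (n, 2): (log2 sf, log2 tf)")
        if len(X) < 7:
            raise ValueError("quadric fit needs at least 7 points")
        A = _design(X[:, 0], X[:, 1])
        if np.linalg.matrix_rank(A) < 6:
            raise ValueError(
                "rank-deficient design: stimulus coordinates are degenerate "
                "(collinear or coincident)"
            )
        coef, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        n, p = len(y), 6
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p) if n > p else r2
        self.coef_ = coef
        self.adjusted_r2_ = adj
        q = coef
        self.q_index_ = (
            -(1.0 + q[4] / (2.0 * q[5])) if abs(q[5]) > self.q5_tol else None
        )
        angles = axes_angles(QuadricFit(coef, adj))
        self.theta_ = angles.theta
        self.phi_ = angles.phi
        self.saddle_ = angles.saddle
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = np.asarray(X, dtype=float)
        return _design(X[:, 0], X[:, 1]) @ self.coef_

    def quadric_(self) -> QuadricFit:
        check_is_fitted(self, "coef_")
        return QuadricFit(self.coef_, self.adjusted_r2_)


def fit_quadric(points) -> QuadricFit:
    """OLS quadric through (x, t, amplitude) triples."""
    pts = np.asarray(points, dtype=float)
    est = QuadricTuningSurface().fit(pts[:, :2], pts[:, 2])
    return est.quadric_()


def q_index(fit: QuadricFit, q5_tol: float = 1e-12) -> float | None:
    """Separability index Q = -(1 + q4/(2 q5)); None when q5 ~ 0."""
    q = fit.q
    if abs(q[5]) <= q5_tol:
        return None
    return float(-(1.0 + q[4] / (2.0 * q[5])))


def tuning_table(stats, components) -> "pd.DataFrame":
    """Per-window quadric fits to component window statistics.

    ``stats`` is a list of :class:`speedscale.traces.WindowStats` for
    component conditions; one quadric is fitted per 50-ms window to the mean
    velocities over the component coordinates.  Returns a tidy table with
    q0..q5, adjusted R^2, Q, theta and phi per window.
    """
    import pandas as pd

    cmap = components if isinstance(components, dict) else {c.id: c for c in components}
    rows = []
    windows = sorted({s.window for s in stats})
    for win in windows:
        pts = [
            (cmap[s.condition_id].log2_sf, cmap[s.condition_id].log2_tf, s.mu)
            for s in stats
            if s.window == win and s.condition_id in cmap
        ]
        if len(pts) < 7:
            continue
        fit = fit_quadric(np.asarray(pts))
        ang = axes_angles(fit)
        rows.append(
            {
                "window_start_ms": win[0],
                "window_stop_ms": win[1],
                **{f"q{i}": fit.coefficients[i] for i in range(6)},
                "adjusted_r2": fit.adjusted_r2,
                "q_index": q_index(fit),
                "theta": ang.theta,
                "phi": ang.phi,
                "saddle": ang.saddle,
            }
        )
    return pd.DataFrame(rows)


def axes_angles(fit: QuadricFit, tol: float = 1e-12) -> AxesAngles:
    """Theta (max speed-scale locus) and Phi (main axis) of a quadric.

    Along each iso-speed line the quadric's maximum lies on the straight line
    (q1+q2) + (2 q3 + q4) x + (q4 + 2 q5) t = 0, whose direction is
    (-(q4 + 2 q5), 2 q3 + q4); theta is its speed-scale angle, defined only
    when the curvature along the speed axis, q3 + q4 + q5, is negative.  Phi
    is the speed-scale angle of the Hessian eigenvector with the smallest
    absolute curvature (the surface's long axis); a saddle Hessian is
    flagged.
    """
    q = fit.q
    curv_speed = q[3] + q[4] + q[5]  # second derivative along iso-velocity dir
    if curv_speed < -tol:
        dx = -(q[4] + 2.0 * q[5])
        dt = 2.0 * q[3] + q[4]
        theta = speed_scale_angle(dx, dt)
        theta_defined = True
    else:
        theta = None
        theta_defined = False
    H = np.array([[2.0 * q[3], q[4]], [q[4], 2.0 * q[5]]])
    evals, evecs = np.linalg.eigh(H)
    saddle = bool(evals[0] * evals[1] < -tol)
    major = evecs[:, int(np.argmin(np.abs(evals)))]
    phi = speed_scale_angle(float(major[0]), float(major[1]))
    return AxesAngles(theta=theta, phi=phi, saddle=saddle, theta_defined=theta_defined)
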