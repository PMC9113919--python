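"""Linear predictions, the nonlinearity ratio, and separation times.

The linear prediction for a pattern is the sample-wise average of its
component-driven mean velocity traces.  R_NL = e_obs / e_pred compares
observed pattern responses against that prediction per 50-ms window (>1
supralinear, <1 sublinear).  The separation time is the first 5-ms bin at
which observed and predicted trial populations differ significantly
(Welch t test, sustained over k consecutive bins); separation-time samples
are compared across conditions with a bootstrap trimmed-mean test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .catalog import PatternSpec

__all__ = [
    "LinearPrediction",
    "RNLEntry",
    "SeparationTime",
    "SeparationConfig",
    "linear_prediction",
    "resample_prediction_trials",
    "r_nl",
    "separation_time",
    "bootstrap_trimmed_mean_test",
]


@dataclass(frozen=True)
class LinearPrediction:
    pattern_id: str
    predicted_trace: np.ndarray  # deg/s per ms
    predicted_window_means: dict[tuple[int, int], float]


@dataclass(frozen=True)
class RNLEntry:
    pattern_id: str
    window: tuple[int, int]
    e_obs: float
    e_pred: float
    r_nl: float | None
    defined: bool


@dataclass(frozen=True)
class SeparationTime:
    pattern_id: str
    time_ms: float | None
    defined: bool


@dataclass(frozen=True)
class SeparationConfig:
    bin_ms: int = 5
    alpha: float = 0.05
    k_consecutive: int = 3
    t_start_ms: int = 0
    t_stop_ms: int = 400


def linear_prediction(
    component_traces: dict[str, np.ndarray],
    pattern: PatternSpec,
    windows=None,
) -> LinearPrediction:
    """Sample-wise mean of the pattern's component mean traces."""
    from .traces import WINDOWS_MS, window_mean

    windows = windows or WINDOWS_MS
    traces = []
    n_ref = None
    for cid in pattern.component_ids:
        arr = np.asarray(component_traces[cid], dtype=float)
        mean_trace = arr.mean(axis=0) if arr.ndim == 2 else arr
        if n_ref is None:
            n_ref = len(mean_trace)
        elif len(mean_trace) != n_ref:
            raise ValueError("component traces are on mismatched time bases")
        traces.append(mean_trace)
    pred = np.mean(traces, axis=0)
    return LinearPrediction(
        pattern_id=pattern.id,
        predicted_trace=pred,
        predicted_window_means={w: window_mean(pred, w) for w in windows},
    )


def resample_prediction_trials(
    component_traces: dict[str, np.ndarray],
    pattern: PatternSpec,
    n_trials: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Pseudo-trials for the prediction: each is the average of one randomly
    drawn trial per component, giving the linear prediction an empirical
    across-trial variance."""
    stacks = [np.asarray(component_traces[c], dtype=float) for c in pattern.component_ids]
    n_samples = stacks[0].shape[1]
    out = np.empty((n_trials, n_samples))
    for k in range(n_trials):
        picks = [s[rng.integers(0, len(s))] for s in stacks]
        out[k] = np.mean(picks, axis=0)
    return out


def r_nl(
    e_obs: float,
    prediction: LinearPrediction,
    window: tuple[int, int],
    min_pred: float = 0.0,
) -> RNLEntry:
    """Observed/predicted window-mean ratio; undefined when e_pred <= min_pred."""
    e_pred = prediction.predicted_window_means[window]
    if e_pred <= min_pred:
        return RNLEntry(prediction.pattern_id, window, e_obs, e_pred, None, False)
    return RNLEntry(prediction.pattern_id, window, e_obs, e_pred, e_obs / e_pred, True)


def separation_time(
    observed_trials: np.ndarray,
    predicted_trials: np.ndarray,
    cfg: SeparationConfig | None = None,
    pattern_id: str = "",
) -> SeparationTime:
    """First 5-ms bin starting a run of k consecutive significant Welch
    t tests between observed and predicted trial populations."""
    cfg = cfg or SeparationConfig()
    obs = np.asarray(observed_trials, dtype=float)
    pred = np.asarray(predicted_trials, dtype=float)
    if len(obs) < 2 or len(pred) < 2:
        raise ValueError("need at least 2 trials per side")
    edges = np.arange(cfg.t_start_ms, cfg.t_stop_ms + 1, cfg.bin_ms)
    n_bins = len(edges) - 1
    sig = np.zeros(n_bins, dtype=bool)
    for b in range(n_bins):
        a = obs[:, edges[b] : edges[b + 1]].mean(axis=1)
        c = pred[:, edges[b] : edges[b + 1]].mean(axis=1)
        if np.std(a) == 0 and np.std(c) == 0:
            sig[b] = not np.isclose(a.mean(), c.mean())
            continue
        _, p = stats.ttest_ind(a, c, equal_var=False)
        sig[b] = bool(p < cfg.alpha)
    run = 0
    for b in range(n_bins - 1, -1, -1):
        run = run + 1 if sig[b] else 0
        sig[b] = run >= cfg.k_consecutive  # bin starts a long-enough run
    hits = np.flatnonzero(sig)
    if hits.size == 0:
        return SeparationTime(pattern_id, None, False)
    return SeparationTime(pattern_id, float(edges[hits[0]]), True)


def bootstrap_trimmed_mean_test(
    times_a,
    times_b,
    reps: int = 1000,
    trim: float = 0.2,
    rng: np.random.Generator | None = None,
) -> float:
    """Two-sided bootstrap test on the trimmed-mean difference of two
    separation-time samples.

    Resamples each group with replacement, computes the trimmed-mean
    difference, and reports 2*min(P(diff<=0), P(diff>=0)) with an add-one
    correction.
    """
    a = np.asarray(times_a, dtype=float)
    b = np.asarray(times_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if not 0.0 <= trim <= 0.25:
        raise ValueError("trim must lie in [0, 0.25]")
    if reps < 100:
        warnings.warn(f"reps={reps} is small for a bootstrap p value", stacklevel=2)
    rng = rng or np.random.default_rng()
    diffs = np.empty(reps)
    for r in range(reps):
        ra = rng.choice(a, size=a.size, replace=True)
        rb = rng.choice(b, size=b.size, replace=True)
        diffs[r] = stats.trim_mean(ra, trim) - stats.trim_mean(rb, trim)
    p_le = (np.sum(diffs <= 0) + 1) / (reps + 1)
    p_ge = (np.sum(diffs >= 0) + 1) / (reps + 1)
    return float(min(1.0, 2.0 * min(p_le, p_ge)))
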