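"""Eye-trace preprocessing and windowed velocity statistics.

Raw 1-kHz eye-position trials are low-pass filtered (5th-order Butterworth,
40 Hz), differentiated by central differences over samples 10 ms apart, and
the velocity low-pass filtered again at 30 Hz.  Filters run zero-phase
(forward-backward) so latency-sensitive quantities carry no group delay.
Leftward trials are sign-flipped so tracking is always positive.  Artifact
trials (saccades, blinks, oscillations) are rejected by velocity/acceleration
thresholds, the mean blank-trial velocity is subtracted, and mean eye
velocity is summarized in five successive 50-ms windows between 50 and
300 ms after stimulus onset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "WINDOWS_MS",
    "PreprocessConfig",
    "RejectConfig",
    "RawTrial",
    "VelocityTrace",
    "TrialSet",
    "WindowStats",
    "preprocess",
    "reject_and_subtract",
    "window_stats",
    "window_mean",
    "cohort_window_frame",
]

#: Inclusive 50-ms analysis windows (ms from stimulus onset).
WINDOWS_MS: tuple[tuple[int, int], ...] = (
    (51, 100),
    (101, 150),
    (151, 200),
    (201, 250),
    (251, 300),
)


@dataclass(frozen=True)
class PreprocessConfig:
    fs: float = 1000.0
    position_cutoff_hz: float = 40.0
    velocity_cutoff_hz: float = 30.0
    order: int = 5
    diff_half_ms: int = 5  # central difference over samples 2*half apart


@dataclass(frozen=True)
class RejectConfig:
    velocity_limit: float = 80.0  # deg/s
    acceleration_limit: float = 5000.0  # deg/s^2
    sustain_ms: int = 5


@dataclass(frozen=True)
class RawTrial:
    trial_id: int
    condition_id: str
    direction: str  # "left" or "right"
    samples: np.ndarray  # eye position in degrees, 1 kHz
    is_blank: bool = False

    def __post_init__(self) -> None:
        if self.direction not in ("left", "right"):
            raise ValueError(f"bad direction {self.direction!r}")
        if len(self.samples) < 400:
            raise ValueError("trial needs at least 400 samples (400 ms at 1 kHz)")


@dataclass(frozen=True)
class VelocityTrace:
    trial_id: int
    condition_id: str
    velocity: np.ndarray  # deg/s, one sample per ms
    valid: bool = True


@dataclass
class TrialSet:
    """Cleaned, blank-subtracted velocity traces grouped by condition."""

    traces: dict[str, np.ndarray]  # condition -> (n_valid, n_samples)
    n_rejected: dict[str, int] = field(default_factory=dict)
    n_total: dict[str, int] = field(default_factory=dict)

    @property
    def rejection_fraction(self) -> float:
        total = sum(self.n_total.values())
        return sum(self.n_rejected.values()) / total if total else 0.0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cond, arr in self.traces.items():
            for k, trace in enumerate(arr):
                rows.append(
                    pd.DataFrame(
                        {
                            "condition": cond,
                            "trial": k,
                            "time_ms": np.arange(len(trace)),
                            "velocity_deg_s": trace,
                        }
                    )
                )
        return pd.concat(rows, ignore_index=True)


@dataclass(frozen=True)
class WindowStats:
    condition_id: str
    window: tuple[int, int]
    trial_means: np.ndarray
    mu: float
    sigma: float
    cv: float | None
    sigma_d: float | None
    low_n: bool = False


def _butter_filtfilt(x: np.ndarray, cutoff: float, cfg: PreprocessConfig) -> np.ndarray:
    b, a = signal.butter(cfg.order, cutoff / (cfg.fs / 2.0))
    return signal.filtfilt(b, a, x)


def preprocess(raw: RawTrial, cfg: PreprocessConfig | None = None) -> VelocityTrace:
    """Position -> filtered velocity trace (one estimate per millisecond)."""
    cfg = cfg or PreprocessConfig()
    pos = np.asarray(raw.samples, dtype=float)
    pad = 3 * (cfg.order + 1)
    if len(pos) <= pad:
        raise ValueError("trace shorter than filter warm-up; rejected")
    pos_f = _butter_filtfilt(pos, cfg.position_cutoff_hz, cfg)
    h = cfg.diff_half_ms
    vel = np.empty_like(pos_f)
    dt = 2 * h / cfg.fs
    vel[h:-h] = (pos_f[2 * h:] - pos_f[:-2 * h]) / dt
    vel[:h] = vel[h]
    vel[-h:] = vel[-h - 1]
    vel = _butter_filtfilt(vel, cfg.velocity_cutoff_hz, cfg)
    if raw.direction == "left":
        vel = -vel
    return VelocityTrace(raw.trial_id, raw.condition_id, vel, valid=True)


def _is_artifact(vel: np.ndarray, cfg: RejectConfig, fs: float = 1000.0) -> bool:
    acc = np.gradient(vel) * fs
    bad = (np.abs(vel) > cfg.velocity_limit) | (np.abs(acc) > cfg.acceleration_limit)
    # Sustained for at least sustain_ms consecutive samples.
    run = 0
    need = max(1, int(cfg.sustain_ms * fs / 1000.0))
    for flag in bad:
        run = run + 1 if flag else 0
        if run >= need:
            return True
    return False


def reject_and_subtract(
    trials: list[VelocityTrace],
    blanks: list[VelocityTrace],
    cfg: RejectConfig | None = None,
) -> TrialSet:
    """Flag artifact trials and subtract the mean blank velocity.

    Blank subtraction removes residual postsaccadic drift; it is idempotent on
    the blank mean itself.
    """
    cfg = cfg or RejectConfig()
    if not blanks:
        raise ValueError("blank subtraction requires at least one blank trial")
    blank_mean = np.mean([b.velocity for b in blanks], axis=0)
    kept: dict[str, list[np.ndarray]] = {}
    n_rej: dict[str, int] = {}
    n_tot: dict[str, int] = {}
    for tr in trials:
        n_tot[tr.condition_id] = n_tot.get(tr.condition_id, 0) + 1
        if not tr.valid or _is_artifact(tr.velocity, cfg):
            n_rej[tr.condition_id] = n_rej.get(tr.condition_id, 0) + 1
            continue
        kept.setdefault(tr.condition_id, []).append(tr.velocity - blank_mean)
    if not kept:
        raise ValueError("all trials rejected as artifacts")
    traces = {c: np.vstack(v) for c, v in kept.items()}
    for c in n_tot:
        n_rej.setdefault(c, 0)
    return TrialSet(traces=traces, n_rejected=n_rej, n_total=n_tot)


def window_mean(trace: np.ndarray, window: tuple[int, int]) -> float:
    """Mean velocity over an inclusive [start, stop] ms window (1-kHz samples)."""
    start, stop = window
    return float(np.mean(trace[start : stop + 1]))


def window_stats(
    trial_set: TrialSet,
    windows: tuple[tuple[int, int], ...] = WINDOWS_MS,
    min_trials: int = 5,
) -> list[WindowStats]:
    """Per condition x window Gaussian summary of per-trial mean velocities.

    The Gaussian fit is moment matching (sample mean/SD, which is the MLE for
    a Gaussian); cv = sigma/mu is defined only for mu > 0 and
    sigma_d = sigma - sqrt(mu) quantifies deviation from the shot-noise-like
    square-root law between variability and response amplitude.
    """
    out: list[WindowStats] = []
    for cond, arr in trial_set.traces.items():
        for win in windows:
            means = arr[:, win[0] : win[1] + 1].mean(axis=1)
            mu = float(np.mean(means))
            sigma = float(np.std(means, ddof=1)) if len(means) > 1 else 0.0
            cv = sigma / mu if mu > 0 else None
            sigma_d = sigma - math.sqrt(mu) if mu > 0 else None
            out.append(
                WindowStats(
                    condition_id=cond,
                    window=win,
                    trial_means=means,
                    mu=mu,
                    sigma=sigma,
                    cv=cv,
                    sigma_d=sigma_d,
                    low_n=len(means) < min_trials,
                )
            )
    return out


def process_raw_trials(
    raws: list[RawTrial],
    pre_cfg: PreprocessConfig | None = None,
    rej_cfg: RejectConfig | None = None,
    blank_condition: str = "blank",
) -> TrialSet:
    """Full preprocessing chain: filter/differentiate every raw trial, then
    reject artifacts and subtract the mean blank velocity."""
    vels = [preprocess(r, pre_cfg) for r in raws]
    blanks = [
        v for v, r in zip(vels, raws) if r.is_blank or r.condition_id == blank_condition
    ]
    stim = [
        v
        for v, r in zip(vels, raws)
        if not (r.is_blank or r.condition_id == blank_condition)
    ]
    return reject_and_subtract(stim, blanks, rej_cfg)


def cohort_window_frame(stats: list[WindowStats]) -> pd.DataFrame:
    """Tidy window-statistics table."""
    return pd.DataFrame(
        {
            "condition": [s.condition_id for s in stats],
            "window_start_ms": [s.window[0] for s in stats],
            "window_stop_ms": [s.window[1] for s in stats],
            "n_trials": [len(s.trial_means) for s in stats],
            "mu": [s.mu for s in stats],
            "sigma": [s.sigma for s in stats],
            "cv": [s.cv for s in stats],
            "sigma_d": [s.sigma_d for s in stats],
            "low_n": [s.low_n for s in stats],
        }
    )
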