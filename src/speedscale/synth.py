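"""Synthetic eye-movement cohorts with the statistical structure the
analysis chain assumes.

Two generation modes:

* ``phenomenological`` — trial velocity rises with a saturating exponential
  (60-ms time constant) after a Gaussian tracking latency (85 +- 10 ms)
  toward a condition plateau (capped near 10 deg/s for 24 deg/s stimuli,
  since ocular following reaches only a fraction of stimulus speed).
  Across-trial window-mean SD follows the square-root law sigma =
  kappa*sqrt(mu) in windows up to 200 ms (the injected noise variance is
  kappa^2*mu minus the variance contributed by latency jitter), optionally
  inflated late for high-scale gratings.  Saccade-like artifacts are
  injected at a configurable rate and blank trials carry only postsaccadic
  drift.

* ``model_driven`` — per-window velocities are samples from the channel
  model's posterior over speed (the prior at omega = 0), for closed-loop
  parameter-recovery tests.

Positions are the integral of velocity; leftward trials are sign-flipped so
the preprocessing chain must re-align them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog import component_map, scale_rank
from .channels import ChannelBank, InteractionParams, ParticipantParams, run_windows
from .traces import WINDOWS_MS, RawTrial

__all__ = [
    "GroundTruth",
    "SyntheticCohort",
    "default_plateau_map",
    "generate_cohort",
    "forward_simulate_responses",
]

_N_SAMPLES = 400
_SEGMENTS = tuple((1 + 50 * k, 50 * (k + 1)) for k in range(8))


@dataclass(frozen=True)
class GroundTruth:
    """Generator parameters; the defaults are the emulated study conditions."""

    mode: str = "phenomenological"
    latency_mean: float = 85.0
    latency_sd: float = 10.0
    plateau_map: dict[str, float] | None = None
    noise_kappa: float = 1.0
    dg_late_inflation: float = 1.5
    artifact_rate: float = 0.08
    drift_amplitude: float = 0.5
    rise_tau_ms: float = 60.0
    baseline_sd: float = 0.15
    stimulus_type: str = "MC"
    divergence: dict[str, tuple[float, float]] = field(default_factory=dict)
    participant: ParticipantParams | None = None
    interactions: InteractionParams | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("phenomenological", "model_driven"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not 0.0 <= self.artifact_rate <= 1.0:
            raise ValueError("artifact_rate must lie in [0, 1]")
        if not 50.0 <= self.latency_mean <= 150.0:
            raise ValueError("latency_mean must lie in [50, 150] ms")


@dataclass
class SyntheticCohort:
    participants: int
    trials_per_condition: int
    by_participant: dict[int, list[RawTrial]]
    truth: GroundTruth

    def trials(self, participant: int = 0) -> list[RawTrial]:
        return self.by_participant[participant]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for pid, trials in self.by_participant.items():
            for tr in trials:
                rows.append(
                    pd.DataFrame(
                        {
                            "participant": pid,
                            "trial": tr.trial_id,
                            "condition": tr.condition_id,
                            "direction": tr.direction,
                            "time_ms": np.arange(len(tr.samples)),
                            "position_deg": tr.samples,
                        }
                    )
                )
        return pd.concat(rows, ignore_index=True)

    def save_hdf5(self, path) -> None:
        import h5py, json
        from dataclasses import asdict

        with h5py.File(path, "w") as f:
            truth = asdict(self.truth)
            for key in ("participant", "interactions"):
                if truth.get(key) is not None:
                    truth[key] = asdict(getattr(self.truth, key))
            f.attrs["provenance"] = json.dumps(truth, default=str)
            for pid, trials in self.by_participant.items():
                grp = f.create_group(f"participant_{pid}")
                grp.create_dataset(
                    "positions", data=np.vstack([t.samples for t in trials])
                )
                grp.create_dataset(
                    "condition",
                    data=np.array([t.condition_id for t in trials], dtype="S"),
                )
                grp.create_dataset(
                    "direction",
                    data=np.array([t.direction for t in trials], dtype="S"),
                )


def raw_trials_from_frame(df: pd.DataFrame) -> list[RawTrial]:
    """Rebuild RawTrial records from the tidy position table produced by
    :meth:`SyntheticCohort.to_frame` (single participant)."""
    trials = []
    for (tid, cond, direction), grp in df.groupby(
        ["trial", "condition", "direction"], sort=False
    ):
        grp = grp.sort_values("time_ms")
        trials.append(
            RawTrial(
                trial_id=int(tid),
                condition_id=str(cond),
                direction=str(direction),
                samples=grp["position_deg"].to_numpy(),
                is_blank=cond == "blank",
            )
        )
    return trials


def default_plateau_map(
    components,
    patterns=None,
    gain_at_24: float = 10.0,
    exponent: float = 0.4,
) -> dict[str, float]:
    """Compressive speed-to-plateau rule with patterns set to the linear
    (component-average) prediction, so the null R_NL = 1 holds by design."""
    cmap = components if isinstance(components, dict) else component_map(components)
    plateaus = {
        cid: gain_at_24 * (c.v0 / 24.0) ** exponent for cid, c in cmap.items()
    }
    if patterns:
        for pat in patterns:
            plateaus[pat.id] = float(
                np.mean([plateaus[c] for c in pat.component_ids])
            )
    return plateaus


def _ramp(plateau: float, latency: float, tau: float) -> np.ndarray:
    t = np.arange(_N_SAMPLES, dtype=float)
    out = np.zeros(_N_SAMPLES)
    late = t > latency
    out[late] = plateau * (1.0 - np.exp(-(t[late] - latency) / tau))
    return out


def _latency_window_moments(
    plateau: float, truth: GroundTruth, n_quad: int = 33
) -> tuple[np.ndarray, np.ndarray]:
    """Mean and variance of segment-mean velocity induced by latency jitter."""
    qs = (np.arange(n_quad) + 0.5) / n_quad
    lats = truth.latency_mean + truth.latency_sd * np.sqrt(2) * _erfinv(2 * qs - 1)
    seg_means = np.empty((n_quad, len(_SEGMENTS)))
    for i, lat in enumerate(lats):
        ramp = _ramp(plateau, lat, truth.rise_tau_ms)
        for k, (a, b) in enumerate(_SEGMENTS):
            seg_means[i, k] = ramp[a : b + 1].mean()
    return seg_means.mean(axis=0), seg_means.var(axis=0)


def _erfinv(x):
    from scipy.special import erfinv

    return erfinv(x)


def _smooth_baseline(rng: np.random.Generator, sd: float) -> np.ndarray:
    """Low-frequency baseline noise (boxcar-smoothed white noise)."""
    raw = rng.normal(0.0, 1.0, _N_SAMPLES + 40)
    kernel = np.ones(21) / 21.0
    sm = np.convolve(raw, kernel, mode="valid")[: _N_SAMPLES]
    sd_sm = sm.std() or 1.0
    return sd * sm / sd_sm


def _phenomenological_velocity(
    cond: str,
    plateau: float,
    truth: GroundTruth,
    high_scale: bool,
    rng: np.random.Generator,
    moments_cache: dict,
) -> np.ndarray:
    lat = rng.normal(truth.latency_mean, truth.latency_sd)
    vel = _ramp(plateau, lat, truth.rise_tau_ms)
    if cond not in moments_cache:
        moments_cache[cond] = _latency_window_moments(plateau, truth)
    mu_seg, var_lat = moments_cache[cond]
    # One perturbation draw per trial, shaped by the square-root profile so
    # the across-trial window-mean SD (latency jitter included) is kappa
    # sqrt(mu); a single smooth source survives the analysis filters intact.
    z = rng.normal()
    shape = np.zeros(_N_SAMPLES)
    for k, (a, b) in enumerate(_SEGMENTS):
        target_sd = truth.noise_kappa * math.sqrt(max(mu_seg[k], 0.0))
        if truth.stimulus_type == "DG" and high_scale and a > 200:
            target_sd *= truth.dg_late_inflation
        shape[a : min(b + 1, _N_SAMPLES)] = math.sqrt(
            max(target_sd**2 - var_lat[k], 0.0)
        )
    vel = vel + z * shape + _smooth_baseline(rng, truth.baseline_sd)
    if cond in truth.divergence:
        onset, delta = truth.divergence[cond]
        t = np.arange(_N_SAMPLES, dtype=float)
        late = t >= onset
        # Fast-rising step (5-ms time constant) so the divergence onset is
        # sharp on the 5-ms analysis grid.
        vel[late] += delta * (1.0 - np.exp(-(t[late] - onset) / 5.0))
    return vel


def _blank_velocity(truth: GroundTruth, rng: np.random.Generator) -> np.ndarray:
    t = np.arange(_N_SAMPLES, dtype=float)
    drift = truth.drift_amplitude * np.exp(-t / 150.0)
    return drift + _smooth_baseline(rng, truth.baseline_sd)


def _inject_artifact(vel: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    t = np.arange(_N_SAMPLES, dtype=float)
    center = rng.uniform(80.0, 350.0)
    amp = rng.uniform(100.0, 300.0) * rng.choice([-1.0, 1.0])
    return vel + amp * np.exp(-0.5 * ((t - center) / 8.0) ** 2)


def _model_driven_velocity(
    window_speeds: np.ndarray,
    truth: GroundTruth,
    rng: np.random.Generator,
) -> np.ndarray:
    """Trace whose window means track per-window speeds sampled from the
    model posterior (omega = 0..3 mapped onto the 101-300 ms windows)."""
    lat = rng.normal(truth.latency_mean, truth.latency_sd)
    mids = [0.5 * (a + b) for a, b in WINDOWS_MS[1:]]  # 125.5 .. 275.5
    knots_t = [0.0, lat] + mids + [float(_N_SAMPLES)]
    knots_v = [0.0, 0.0] + list(window_speeds) + [window_speeds[-1]]
    t = np.arange(_N_SAMPLES, dtype=float)
    vel = np.interp(t, knots_t, knots_v)
    return vel + _smooth_baseline(rng, truth.baseline_sd)


def generate_cohort(
    truth: GroundTruth,
    components,
    patterns=(),
    participants: int = 1,
    trials_per_condition: int = 40,
    conditions: list[str] | None = None,
    bank: ChannelBank | None = None,
) -> SyntheticCohort:
    """Generate a fully interleaved cohort (every condition plus blanks for
    every participant); same seed gives a bit-identical cohort."""
    cmap = components if isinstance(components, dict) else component_map(components)
    pmap = {p.id: p for p in patterns}
    if conditions is None:
        conditions = list(cmap) + list(pmap)
    if trials_per_condition <= 0 or participants <= 0:
        raise ValueError("participants and trials_per_condition must be positive")

    if truth.mode == "phenomenological":
        plateaus = truth.plateau_map or default_plateau_map(
            cmap, list(pmap.values())
        )
        missing = [c for c in conditions if c not in plateaus]
        if missing:
            raise ValueError(f"no plateau for conditions {missing}")
    else:
        if truth.participant is None:
            raise ValueError("model_driven mode needs ParticipantParams")
        if bank is None:
            from .channels import build_bank

            bank = build_bank()

    high = {
        cid for cid, lab in scale_rank(list(cmap.values())).items() if lab == "high"
    }
    by_participant: dict[int, list[RawTrial]] = {}
    rng = np.random.default_rng(truth.seed)
    for pid in range(participants):
        trials: list[RawTrial] = []
        tid = 0
        posterior_cache: dict[str, object] = {}
        moments_cache: dict[str, tuple] = {}
        for cond in list(conditions) + ["blank"]:
            for k in range(trials_per_condition):
                if cond == "blank":
                    vel = _blank_velocity(truth, rng)
                elif truth.mode == "phenomenological":
                    vel = _phenomenological_velocity(
                        cond, plateaus[cond], truth, cond in high, rng, moments_cache
                    )
                else:
                    if cond not in posterior_cache:
                        stim = cmap.get(cond) or pmap[cond]
                        posterior_cache[cond] = run_windows(
                            stim,
                            truth.participant,
                            truth.interactions,
                            bank,
                            components=cmap,
                        )
                    seq = posterior_cache[cond]
                    speeds = np.array(
                        [seq.sample_speeds(w, 1, rng)[0] for w in range(4)]
                    )
                    vel = _model_driven_velocity(speeds, truth, rng)
                if cond != "blank" and rng.uniform() < truth.artifact_rate:
                    vel = _inject_artifact(vel, rng)
                direction = "left" if k % 2 else "right"
                signed = -vel if direction == "left" else vel
                pos = np.cumsum(signed) / 1000.0
                trials.append(
                    RawTrial(
                        trial_id=tid,
                        condition_id=cond,
                        direction=direction,
                        samples=pos,
                        is_blank=cond == "blank",
                    )
                )
                tid += 1
        by_participant[pid] = trials
    return SyntheticCohort(participants, trials_per_condition, by_participant, truth)


def forward_simulate_responses(
    stimuli: dict,
    participant: ParticipantParams,
    interactions: InteractionParams | None,
    bank: ChannelBank,
    n_trials: int,
    seed: int,
    components=None,
    n_windows: int = 3,
    include_omega0: bool = False,
) -> dict[str, np.ndarray]:
    """Per-window trial velocities sampled from each window's posterior
    (omega = 0 samples the prior).  Returns sid -> (n_windows[, +1], n_trials)."""
    rng = np.random.default_rng(seed)
    out = {}
    for sid, stim in stimuli.items():
        seq = run_windows(
            stim, participant, interactions, bank,
            components=components, n_windows=n_windows,
        )
        first = 0 if include_omega0 else 1
        out[sid] = np.vstack(
            [seq.sample_speeds(w, n_trials, rng) for w in range(first, n_windows + 1)]
        )
    return out
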