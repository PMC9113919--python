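"""Maximum-likelihood fitting of the channel model and AIC comparison.

Observed per-trial window-mean eye velocities are scored under the model's
per-window posterior density over speed (log2 mapping with the
change-of-variables Jacobian); parameters maximize the summed log-likelihood
over trials, windows and stimuli via bounded multi-start Powell search.
Model variants with and without channel interactions are compared by
AIC = 2k - 2 loglik; the interaction variant carries five extra parameters
(alpha and the four kernel SDs; the rotation is fixed).
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize
from sklearn.base import BaseEstimator

from .channels import (
    LN2,
    ChannelBank,
    InteractionParams,
    ParticipantParams,
    WeightPolynomial,
    default_speed_grid,
    run_windows,
    stimulus_drive,
)

__all__ = [
    "ModelDataset",
    "build_dataset",
    "FitSpec",
    "FitResult",
    "DEFAULT_BOUNDS",
    "data_loglik",
    "fit",
    "aic_compare",
    "ChannelModelFit",
]

PARTICIPANT_FIELDS = ("g", "mu_prior", "sigma_prior")
INTERACTION_FIELDS = ("alpha", "sigma_e1", "sigma_e2", "sigma_i1", "sigma_i2")
WEIGHT_FIELDS = tuple(f"b{i}" for i in range(6))

DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "g": (0.05, 20.0),
    "mu_prior": (0.5, 5.0),
    "sigma_prior": (0.2, 3.0),
    "alpha": (0.0, 10.0),
    "sigma_e1": (0.05, 3.0),
    "sigma_e2": (0.05, 3.0),
    "sigma_i1": (0.05, 3.0),
    "sigma_i2": (0.05, 3.0),
    **{f"b{i}": (-50.0, 50.0) for i in range(6)},
}


@dataclass(frozen=True)
class ModelDataset:
    """Cached per-stimulus channel drives plus observed window velocities.

    ``velocities[sid]`` has shape (n_windows, n_trials): per-trial mean eye
    velocities (deg/s) for the fitted windows (omega = 1..n_windows).
    """

    drives: dict[str, np.ndarray]
    contrasts: dict[str, float]
    velocities: dict[str, np.ndarray]
    n_windows: int = 3

    @property
    def data_hash(self) -> str:
        h = hashlib.sha1()
        for sid in sorted(self.velocities):
            h.update(sid.encode())
            h.update(np.ascontiguousarray(self.velocities[sid]).tobytes())
        return h.hexdigest()

    @property
    def n_trials_total(self) -> int:
        return sum(v.size for v in self.velocities.values())


def build_dataset(
    bank: ChannelBank,
    stimuli: dict,
    velocities: dict[str, np.ndarray],
    components=None,
    n_windows: int = 3,
) -> ModelDataset:
    """Precompute raw channel drives for each stimulus in ``velocities``."""
    drives, contrasts = {}, {}
    for sid, arr in velocities.items():
        stim = stimuli[sid]
        drives[sid] = stimulus_drive(bank, stim, components=components)
        contrasts[sid] = getattr(stim, "contrast", 0.6)
        arr = np.asarray(arr, dtype=float)
        if arr.ndim != 2 or arr.shape[0] != n_windows:
            raise ValueError(f"{sid}: velocities must be (n_windows, n_trials)")
    return ModelDataset(drives, contrasts, dict(velocities), n_windows)


def data_loglik(
    dataset: ModelDataset,
    bank: ChannelBank,
    participant: ParticipantParams,
    interactions: InteractionParams | None,
    interaction_mode: str = "gain",
    speed_grid: np.ndarray | None = None,
    min_speed: float = 0.25,
    density_floor: float = 1e-12,
) -> tuple[float, int, int]:
    """Summed log-density of observed velocities under per-window posteriors.

    Returns (loglik, n_floored, n_excluded): trials at or below ``min_speed``
    deg/s are excluded from the log mapping; posterior densities below
    ``density_floor`` are floored and counted.
    """
    if speed_grid is None:
        speed_grid = default_speed_grid()
    kernel_matrix = None
    if interactions is not None:
        from .channels import interaction_kernel

        kernel_matrix = interaction_kernel(interactions).matrix(bank)
    total = 0.0
    n_floored = 0
    n_excluded = 0
    for sid, vel in dataset.velocities.items():
        seq = run_windows(
            stimulus=None,
            participant=participant,
            interactions=interactions,
            bank=bank,
            n_windows=dataset.n_windows,
            interaction_mode=interaction_mode,
            speed_grid=speed_grid,
            contrast=dataset.contrasts[sid],
            drive=dataset.drives[sid],
            kernel_matrix=kernel_matrix,
        )
        for omega in range(1, dataset.n_windows + 1):
            v = np.asarray(vel[omega - 1], dtype=float)
            keep = v > min_speed
            n_excluded += int((~keep).sum())
            v = v[keep]
            if v.size == 0:
                continue
            s = np.log2(v)
            dens_log2 = seq.density_at(omega, s)
            dens_v = dens_log2 / (v * LN2)  # change of variables to deg/s
            low = dens_v < density_floor
            n_floored += int(low.sum())
            total += float(np.sum(np.log(np.maximum(dens_v, density_floor))))
    return total, n_floored, n_excluded


@dataclass(frozen=True)
class FitSpec:
    """Free-parameter set, bounds and optimizer settings."""

    free: tuple[str, ...] = PARTICIPANT_FIELDS
    with_interactions: bool = False
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    n_starts: int = 8
    seed: int = 0
    maxfev: int | None = None
    interaction_mode: str = "gain"

    def __post_init__(self) -> None:
        known = PARTICIPANT_FIELDS + INTERACTION_FIELDS + WEIGHT_FIELDS
        bad = [f for f in self.free if f not in known]
        if bad:
            raise ValueError(f"unknown free parameters: {bad}")
        if not self.with_interactions and any(
            f in INTERACTION_FIELDS for f in self.free
        ):
            raise ValueError("interaction parameters free but interactions off")

    def bound(self, name: str) -> tuple[float, float]:
        return self.bounds.get(name, DEFAULT_BOUNDS[name])


@dataclass(frozen=True)
class FitResult:
    params: dict[str, float]
    free: tuple[str, ...]
    loglik: float
    k: int
    aic: float
    n_floored: int
    n_excluded: int
    starts: tuple
    success: bool
    data_hash: str
    with_interactions: bool

    def to_json(self) -> str:
        import json
        from dataclasses import asdict

        return json.dumps(asdict(self), indent=2, default=float)


def _assemble(
    spec: FitSpec,
    values: dict[str, float],
    base_participant: ParticipantParams,
    base_interactions: InteractionParams | None,
    bank: ChannelBank,
) -> tuple[ParticipantParams, InteractionParams | None, ChannelBank]:
    part = replace(
        base_participant,
        **{f: values[f] for f in PARTICIPANT_FIELDS if f in values},
    )
    inter = None
    if spec.with_interactions:
        inter = base_interactions or InteractionParams()
        upd = {f: values[f] for f in INTERACTION_FIELDS if f in values}
        if upd:
            inter = replace(inter, **upd)
    wb = {f: values[f] for f in WEIGHT_FIELDS if f in values}
    if wb:
        b = list(bank.weight_poly.b)
        for name, val in wb.items():
            b[int(name[1])] = val
        poly = WeightPolynomial(tuple(b))
        raw = poly(bank.log2_fx, bank.log2_ft)
        bank = replace(bank, weights=np.exp(raw - raw.max()), weight_poly=poly)
    return part, inter, bank


def fit(
    dataset: ModelDataset,
    bank: ChannelBank,
    spec: FitSpec,
    base_participant: ParticipantParams | None = None,
    base_interactions: InteractionParams | None = None,
) -> FitResult:
    """Bounded multi-start Powell maximization of :func:`data_loglik`."""
    base_participant = base_participant or ParticipantParams()
    if spec.with_interactions and base_interactions is None:
        base_interactions = InteractionParams()
    rng = np.random.default_rng(spec.seed)
    names = spec.free
    bounds = [spec.bound(n) for n in names]
    defaults = {
        **{f: getattr(base_participant, f) for f in PARTICIPANT_FIELDS},
        **(
            {f: getattr(base_interactions, f) for f in INTERACTION_FIELDS}
            if base_interactions is not None
            else {}
        ),
        **{f"b{i}": bank.weight_poly.b[i] for i in range(6)},
    }
    speed_grid = default_speed_grid()

    def objective(x: np.ndarray) -> float:
        values = dict(zip(names, x))
        part, inter, bk = _assemble(
            spec, values, base_participant, base_interactions, bank
        )
        ll, _, _ = data_loglik(
            dataset,
            bk,
            part,
            inter,
            interaction_mode=spec.interaction_mode,
            speed_grid=speed_grid,
        )
        return -ll

    starts = []
    x0_default = np.array(
        [np.clip(defaults[n], *spec.bound(n)) for n in names], dtype=float
    )
    start_points = [x0_default]
    for _ in range(max(0, spec.n_starts - 1)):
        pt = []
        for n in names:
            lo, hi = spec.bound(n)
            if n in ("g", "alpha") and lo > 0:
                pt.append(math.exp(rng.uniform(math.log(lo), math.log(hi))))
            else:
                pt.append(rng.uniform(lo, hi))
        start_points.append(np.array(pt))

    options = {"xtol": 1e-3, "ftol": 1e-4}
    if spec.maxfev:
        options["maxfev"] = spec.maxfev
    best = None
    for x0 in start_points:
        res = minimize(objective, x0, method="Powell", bounds=bounds, options=options)
        starts.append((tuple(res.x), float(res.fun), bool(res.success)))
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError(f"no converged start; trace: {starts}")

    values = dict(zip(names, best.x))
    part, inter, bk = _assemble(spec, values, base_participant, base_interactions, bank)
    ll, n_floored, n_excluded = data_loglik(
        dataset, bk, part, inter, interaction_mode=spec.interaction_mode,
        speed_grid=speed_grid,
    )
    k = len(names)
    params = {f: getattr(part, f) for f in PARTICIPANT_FIELDS}
    if inter is not None:
        params.update({f: getattr(inter, f) for f in INTERACTION_FIELDS})
    return FitResult(
        params=params,
        free=names,
        loglik=ll,
        k=k,
        aic=2.0 * k - 2.0 * ll,
        n_floored=n_floored,
        n_excluded=n_excluded,
        starts=tuple(starts),
        success=any(s[2] for s in starts),
        data_hash=dataset.data_hash,
        with_interactions=spec.with_interactions,
    )


def fit_joint(
    datasets: dict[object, ModelDataset],
    bank: ChannelBank,
    participant_free: tuple[str, ...] = PARTICIPANT_FIELDS,
    shared_free: tuple[str, ...] = (),
    with_interactions: bool = False,
    base_participants: dict[object, ParticipantParams] | None = None,
    base_interactions: InteractionParams | None = None,
    bounds: dict[str, tuple[float, float]] | None = None,
    n_starts: int = 4,
    seed: int = 0,
    maxfev: int | None = None,
) -> dict:
    """Joint fit over several participants: per-participant gain/prior
    parameters plus interaction-kernel parameters shared across the cohort.

    Returns {"participants": {pid: params}, "shared": params, "loglik": ...,
    "k": ..., "aic": ...}.
    """
    if with_interactions and base_interactions is None:
        base_interactions = InteractionParams()
    pids = sorted(datasets, key=str)
    base_participants = base_participants or {p: ParticipantParams() for p in pids}
    bounds = bounds or {}
    names = [(pid, f) for pid in pids for f in participant_free]
    names += [(None, f) for f in shared_free]
    bnds = [bounds.get(f, DEFAULT_BOUNDS[f]) for _, f in names]
    speed_grid = default_speed_grid()

    def unpack(x):
        per = {pid: {} for pid in pids}
        shared = {}
        for (pid, f), v in zip(names, x):
            (shared if pid is None else per[pid])[f] = float(v)
        parts = {
            pid: replace(base_participants[pid], **per[pid]) for pid in pids
        }
        inter = base_interactions
        if with_interactions and shared:
            inter = replace(
                base_interactions,
                **{f: v for f, v in shared.items() if f in INTERACTION_FIELDS},
            )
        return parts, (inter if with_interactions else None)

    def objective(x):
        parts, inter = unpack(x)
        return -sum(
            data_loglik(datasets[pid], bank, parts[pid], inter,
                        speed_grid=speed_grid)[0]
            for pid in pids
        )

    rng = np.random.default_rng(seed)
    x0 = np.array(
        [
            np.clip(
                getattr(base_participants[pid], f)
                if pid is not None
                else getattr(base_interactions, f),
                *b,
            )
            for (pid, f), b in zip(names, bnds)
        ]
    )
    best = None
    for start in range(n_starts):
        xs = x0 if start == 0 else np.array(
            [rng.uniform(*b) for b in bnds]
        )
        options = {"xtol": 1e-3, "ftol": 1e-4}
        if maxfev:
            options["maxfev"] = maxfev
        res = minimize(objective, xs, method="Powell", bounds=bnds, options=options)
        if best is None or res.fun < best.fun:
            best = res
    parts, inter = unpack(best.x)
    k = len(names)
    ll = -float(best.fun)
    return {
        "participants": {
            pid: {f: getattr(parts[pid], f) for f in PARTICIPANT_FIELDS}
            for pid in pids
        },
        "shared": (
            {f: getattr(inter, f) for f in INTERACTION_FIELDS} if inter else {}
        ),
        "loglik": ll,
        "k": k,
        "aic": 2.0 * k - 2.0 * ll,
    }


def aic_compare(fit_with: FitResult, fit_without: FitResult) -> float:
    """AIC_with - AIC_without; negative favours the interaction model."""
    if fit_with.data_hash != fit_without.data_hash:
        raise ValueError("fits were computed on different data sets")
    return fit_with.aic - fit_without.aic


class ChannelModelFit(BaseEstimator):
    """Sklearn-style wrapper: fit the channel model to a :class:`ModelDataset`.

    Fitted attributes: ``params_``, ``loglik_``, ``aic_``, ``result_``.
    """

    def __init__(
        self,
        free: tuple[str, ...] = PARTICIPANT_FIELDS,
        with_interactions: bool = False,
        n_starts: int = 8,
        seed: int = 0,
        maxfev: int | None = None,
        bank: ChannelBank | None = None,
    ):
        self.free = free
        self.with_interactions = with_interactions
        self.n_starts = n_starts
        self.seed = seed
        self.maxfev = maxfev
        self.bank = bank

    def fit(self, X: ModelDataset, y=None):
        from .channels import build_bank

        bank = self.bank if self.bank is not None else build_bank()
        spec = FitSpec(
            free=tuple(self.free),
            with_interactions=self.with_interactions,
            n_starts=self.n_starts,
            seed=self.seed,
            maxfev=self.maxfev,
        )
        self.result_ = fit(X, bank, spec)
        self.params_ = self.result_.params
        self.loglik_ = self.result_.loglik
        self.aic_ = self.result_.aic
        return self

    def score(self, X: ModelDataset, y=None) -> float:
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "result_")
        bank = self.bank if self.bank is not None else None
        from .channels import build_bank

        bank = bank or build_bank()
        part = ParticipantParams(
            **{f: self.params_[f] for f in PARTICIPANT_FIELDS}
        )
        inter = (
            InteractionParams(
                **{f: self.params_[f] for f in INTERACTION_FIELDS if f in self.params_}
            )
            if self.with_interactions
            else None
        )
        return data_loglik(X, bank, part, inter)[0]
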