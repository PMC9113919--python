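"""Probabilistic channel model of speed estimation for ocular tracking.

A bank of N=722 spatiotemporal-frequency channels (bivariate Gaussians over
(log2 sf, log2 tf), correlation rho = 0.6 concentrating them along the
iso-velocity diagonal) filters the stimulus envelope, producing feedforward
activity m_i = g^2 w_i <phi_i, stimulus> * contrast.  Channel weights follow
a quadratic polynomial of the channel's log2 frequencies (maximal near
0.21 c/deg).  Channels then interact through a difference-of-Gaussians
kernel in speed-scale coordinates — excitation elongated along the
iso-velocity line, inhibition along the orthogonal scale axis — and the
post-interaction activity drives a population log-likelihood over log speed.
A recursive Bayesian update combines that likelihood with a slow-speed
log-normal prior across successive 50-ms windows.

Weight rule.  The fitted polynomial coefficients are negative everywhere on
the channel lattice (peak value about -19), so the package reads them as the
LOG of the channel weight: w = exp(poly - max poly), a Gaussian-like profile
with peak weight 1 whose arg-max (0.21 c/deg) pins the log2 convention.  The
literal floored polynomial is available as ``weight_transform="linear_floor"``.
With peak-normalized weights the participant gain g is O(1), not the O(100)
value quoted for the original unnormalized weighting.

Interaction kernel axes.  With theta = 3*pi/4 the first rotated axis lies
along the scale direction and the second along the speed (iso-velocity)
direction.  The default parameter set assigns the excitation SDs
(0.2542, 0.7718) to (scale, speed) — excitation elongated along speed — and
the inhibition SDs (0.7711, 0.2501) to (scale, speed) — inhibition elongated
along scale — producing the crossed excitation/inhibition pattern that makes
speed-axis patterns supralinear and scale-axis patterns sublinear.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .catalog import ComponentSpec, PatternSpec, component_map
from .envelope import SpectralEnvelope, mc_envelope

__all__ = [
    "LN2",
    "DEFAULT_WEIGHT_COEFFS",
    "WeightPolynomial",
    "ChannelBankSpec",
    "ChannelBank",
    "ParticipantParams",
    "InteractionParams",
    "InteractionKernel",
    "PosteriorSequence",
    "FIT_WINDOWS_MS",
    "OMEGA0_WINDOW_MS",
    "build_bank",
    "stimulus_drive",
    "channel_response",
    "interaction_kernel",
    "apply_interactions",
    "speed_likelihood",
    "posterior_update",
    "default_speed_grid",
    "normalize_density",
    "run_windows",
]

LN2 = math.log(2.0)

#: Fitted channel-weight polynomial coefficients b0..b5 over
#: (log2 sf, log2 tf).
DEFAULT_WEIGHT_COEFFS = (-23.88, -3.63, 1.95, -0.72, 0.61, -0.45)

#: Model protocol: the 100-150 ms window is omega=0 (prior only); the model
#: is evaluated on the following three 50-ms windows.
OMEGA0_WINDOW_MS = (101, 150)
FIT_WINDOWS_MS = ((151, 200), (201, 250), (251, 300))


@dataclass(frozen=True)
class WeightPolynomial:
    """Quadratic bivariate polynomial over (x, t) = (log2 sf, log2 tf)."""

    b: tuple[float, float, float, float, float, float] = DEFAULT_WEIGHT_COEFFS

    def __call__(self, x, t):
        b = self.b
        x = np.asarray(x, dtype=float)
        t = np.asarray(t, dtype=float)
        return b[0] + b[1] * x + b[2] * t + b[3] * x**2 + b[4] * x * t + b[5] * t**2

    def stationary_point(self) -> tuple[float, float]:
        """(log2 sf, log2 tf) where the gradient vanishes."""
        b = self.b
        H = np.array([[2 * b[3], b[4]], [b[4], 2 * b[5]]])
        sol = np.linalg.solve(H, [-b[1], -b[2]])
        return float(sol[0]), float(sol[1])

    def peak_sf(self) -> float:
        """Spatial frequency (c/deg) of the weight maximum."""
        x, _ = self.stationary_point()
        return 2.0**x


@dataclass(frozen=True)
class ChannelBankSpec:
    """Lattice geometry and receptive-field shape of the channel bank.

    The default 19 x 38 rectangle over log2 sf in [-3, 1] and log2 tf in
    [1, 6] holds exactly 722 channels whose preferred speeds tf/sf all lie
    in [1, 512] deg/s.
    """

    n_sf: int = 19
    n_tf: int = 38
    log2_sf_range: tuple[float, float] = (-3.0, 1.0)
    log2_tf_range: tuple[float, float] = (1.0, 6.0)
    speed_range: tuple[float, float] = (1.0, 512.0)
    sigma_x: float = 0.5
    sigma_t: float = 0.5
    rho: float = 0.6

    def __post_init__(self) -> None:
        if not (-1.0 < self.rho < 1.0):
            raise ValueError("rho must lie in (-1, 1)")
        if self.sigma_x <= 0 or self.sigma_t <= 0:
            raise ValueError("channel SDs must be positive")

    @property
    def n_channels(self) -> int:
        return self.n_sf * self.n_tf


@dataclass(frozen=True)
class ChannelBank:
    spec: ChannelBankSpec
    log2_fx: np.ndarray  # (N,)
    log2_ft: np.ndarray  # (N,)
    weights: np.ndarray  # (N,), >= 0
    weight_poly: WeightPolynomial

    @property
    def n_channels(self) -> int:
        return len(self.log2_fx)

    @property
    def log2_speed(self) -> np.ndarray:
        return self.log2_ft - self.log2_fx

    @property
    def peak_density(self) -> float:
        s = self.spec
        return 1.0 / (2 * math.pi * s.sigma_x * s.sigma_t * math.sqrt(1 - s.rho**2))

    def density_at(self, points: np.ndarray) -> np.ndarray:
        """Channel tuning densities phi_i at points (M, 2) -> (N, M)."""
        s = self.spec
        pts = np.atleast_2d(points)
        dx = pts[None, :, 0] - self.log2_fx[:, None]
        dt = pts[None, :, 1] - self.log2_ft[:, None]
        omr = 1.0 - s.rho**2
        quad = (
            (dx / s.sigma_x) ** 2
            - 2 * s.rho * (dx / s.sigma_x) * (dt / s.sigma_t)
            + (dt / s.sigma_t) ** 2
        ) / omr
        return np.exp(-0.5 * quad) / (
            2 * math.pi * s.sigma_x * s.sigma_t * math.sqrt(omr)
        )


def build_bank(
    spec: ChannelBankSpec | None = None,
    weights: WeightPolynomial | None = None,
    weight_transform: str = "exp_peak",
) -> ChannelBank:
    """Regular channel lattice with per-channel weights.

    ``weight_transform``: "exp_peak" reads the polynomial as log-weights,
    w = exp(poly - max poly) (default); "linear_floor" is the literal
    polynomial floored at zero.
    """
    spec = spec or ChannelBankSpec()
    weights = weights or WeightPolynomial()
    fx = np.linspace(*spec.log2_sf_range, spec.n_sf)
    ft = np.linspace(*spec.log2_tf_range, spec.n_tf)
    FX, FT = np.meshgrid(fx, ft, indexing="ij")
    log2_fx = FX.ravel()
    log2_ft = FT.ravel()
    speeds = 2.0 ** (log2_ft - log2_fx)
    lo, hi = spec.speed_range
    tol = 1e-9
    if speeds.min() < lo - tol or speeds.max() > hi + tol:
        raise ValueError(
            f"lattice places channels outside the preferred-speed range "
            f"[{lo}, {hi}] deg/s (found [{speeds.min():.3g}, {speeds.max():.3g}]); "
            f"shrink log2_tf_range to "
            f"[{spec.log2_sf_range[1] + math.log2(lo):.2f}, "
            f"{spec.log2_sf_range[0] + math.log2(hi):.2f}]"
        )
    raw = weights(log2_fx, log2_ft)
    if weight_transform == "exp_peak":
        w = np.exp(raw - raw.max())
    elif weight_transform == "linear_floor":
        w = np.maximum(raw, 0.0)
    else:
        raise ValueError(f"unknown weight_transform {weight_transform!r}")
    return ChannelBank(spec, log2_fx, log2_ft, w, weights)


@dataclass(frozen=True)
class ParticipantParams:
    """Per-participant gain and prior over log speed.

    ``mu_prior``/``sigma_prior`` parameterize the log-normal slow-speed prior
    in natural-log speed units (mu_prior = 2.51 puts the prior mode near
    12 deg/s); the gain applies under peak-normalized channel weights.
    """

    g: float = 1.0
    mu_prior: float = 2.51
    sigma_prior: float = 0.86

    def __post_init__(self) -> None:
        if self.g <= 0 or self.sigma_prior <= 0:
            raise ValueError("g and sigma_prior must be positive")

    @property
    def prior_log2_mean(self) -> float:
        return self.mu_prior / LN2

    @property
    def prior_log2_sd(self) -> float:
        return self.sigma_prior / LN2

    def prior_density(self, speed_grid: np.ndarray) -> np.ndarray:
        z = (speed_grid - self.prior_log2_mean) / self.prior_log2_sd
        p = np.exp(-0.5 * z**2)
        return normalize_density(p, speed_grid)


@dataclass(frozen=True)
class InteractionParams:
    """Difference-of-Gaussians interaction kernel in speed-scale coordinates.

    With ``theta_rot = 3*pi/4`` the first rotated axis is the scale axis and
    the second the speed axis; sigmas are SDs in octaves.  Defaults give
    excitation elongated along speed and inhibition along scale.
    """

    alpha: float = 2.16
    sigma_e1: float = 0.2542  # excitation SD along the scale axis
    sigma_e2: float = 0.7718  # excitation SD along the speed axis
    sigma_i1: float = 0.7711  # inhibition SD along the scale axis
    sigma_i2: float = 0.2501  # inhibition SD along the speed axis
    theta_rot: float = 3.0 * math.pi / 4.0

    def __post_init__(self) -> None:
        for s in (self.sigma_e1, self.sigma_e2, self.sigma_i1, self.sigma_i2):
            if s <= 0:
                raise ValueError("kernel SDs must be positive")

    @classmethod
    def crossed_preset(cls) -> "InteractionParams":
        return cls()

    @classmethod
    def same_axis_order(cls) -> "InteractionParams":
        """Inhibition SDs assigned in the same axis order as excitation.

        With both Gaussians nearly identical per axis the difference is
        non-negative everywhere — a (vanishingly weak) excitation-only
        kernel with no inhibitory lobe; kept for comparison with the
        crossed default."""
        return cls(sigma_i1=0.2501, sigma_i2=0.7711)


class InteractionKernel:
    """Callable d(dx, dt) over log2-frequency displacements."""

    def __init__(self, params: InteractionParams):
        self.params = params
        th = params.theta_rot
        self._axis1 = np.array([math.cos(th), math.sin(th)])
        self._axis2 = np.array([-math.sin(th), math.cos(th)])

    def __call__(self, dx, dt):
        p = self.params
        dx = np.asarray(dx, dtype=float)
        dt = np.asarray(dt, dtype=float)
        d1 = dx * self._axis1[0] + dt * self._axis1[1]
        d2 = dx * self._axis2[0] + dt * self._axis2[1]
        exc = np.exp(-0.5 * ((d1 / p.sigma_e1) ** 2 + (d2 / p.sigma_e2) ** 2))
        inh = np.exp(-0.5 * ((d1 / p.sigma_i1) ** 2 + (d2 / p.sigma_i2) ** 2))
        return p.alpha * (exc - inh)

    def matrix(self, bank: ChannelBank) -> np.ndarray:
        """Pairwise (N, N) kernel over the bank's channel displacements."""
        dx = bank.log2_fx[:, None] - bank.log2_fx[None, :]
        dt = bank.log2_ft[:, None] - bank.log2_ft[None, :]
        return self(dx, dt)


def interaction_kernel(params: InteractionParams) -> InteractionKernel:
    return InteractionKernel(params)


def stimulus_drive(
    bank: ChannelBank,
    stimulus: ComponentSpec | PatternSpec | SpectralEnvelope,
    components=None,
) -> np.ndarray:
    """Raw per-channel drive <phi_i, stimulus>, before weights/gain/contrast.

    Gratings are evaluated at their exact frequency point; motion clouds are
    integrated over their discretized envelope; patterns are the average of
    their component drives.
    """
    if isinstance(stimulus, SpectralEnvelope):
        mass = stimulus.mass.ravel()
        if not math.isclose(float(mass.sum()), 1.0, abs_tol=1e-6):
            raise ValueError("envelope is not normalized")
        nodes = stimulus.grid.nodes()
        out = np.zeros(bank.n_channels)
        # chunk over grid nodes to bound the (N_channels x N_nodes) buffer
        step = 16384
        for k in range(0, len(nodes), step):
            out += bank.density_at(nodes[k : k + step]) @ mass[k : k + step]
        return out
    if isinstance(stimulus, PatternSpec):
        if components is None:
            raise ValueError("pattern drive needs the component catalog")
        cmap = components if isinstance(components, dict) else component_map(components)
        drives = [
            stimulus_drive(bank, cmap[c], components=components)
            for c in stimulus.component_ids
        ]
        return np.mean(drives, axis=0)
    if stimulus.stimulus_type == "DG":
        pt = np.array([[stimulus.log2_sf, stimulus.log2_tf]])
        return bank.density_at(pt)[:, 0]
    return stimulus_drive(bank, mc_envelope(stimulus))


def channel_response(
    bank: ChannelBank,
    stimulus,
    contrast: float | None = None,
    g: float = 1.0,
    components=None,
) -> np.ndarray:
    """Feedforward channel activity m_i = g^2 * w_i * <phi_i, s> * contrast."""
    if contrast is None:
        contrast = getattr(stimulus, "contrast", None) or getattr(
            stimulus, "total_contrast", None
        )
        if contrast is None:
            raise ValueError("contrast not specified and not carried by stimulus")
    base = stimulus_drive(bank, stimulus, components=components)
    return g**2 * bank.weights * base * contrast


def apply_interactions(
    m: np.ndarray,
    bank: ChannelBank,
    kernel: InteractionKernel | np.ndarray | None,
    mode: str = "gain",
    normalize: str = "peak",
) -> np.ndarray:
    """Network activity after channel interactions.

    The interaction field is I_i = sum_j mhat_j d(Delta_ij) where, by
    default, mhat is the population activity divided by its peak
    (``normalize="peak"``).  This divisive form makes the interaction
    invariant to the overall gain — so the excitation/inhibition balance a
    pattern receives depends on the *shape* of the population activity, not
    its magnitude — and is what lets cross-component excitation along the
    iso-velocity line produce supralinear pattern responses; with the raw
    activity (``normalize="none"``) a pattern's within-component interaction
    dilutes quadratically under envelope averaging and every pattern becomes
    sublinear.  ``mode="gain"`` (default): n = m * (1 + I), rectified at
    zero, which reduces to n = m for a null kernel; ``mode="literal"``:
    n = m * I; ``kernel=None`` disables interactions (n = m).
    """
    m = np.asarray(m, dtype=float)
    if not np.all(np.isfinite(m)):
        raise ValueError("non-finite channel activity")
    if kernel is None:
        return m.copy()
    D = kernel.matrix(bank) if isinstance(kernel, InteractionKernel) else kernel
    if normalize == "peak":
        peak = m.max()
        mhat = m / peak if peak > 0 else m
    elif normalize == "none":
        mhat = m
    else:
        raise ValueError(f"unknown normalize {normalize!r}")
    I = D @ mhat
    if mode == "gain":
        return np.maximum(m * (1.0 + I), 0.0)
    if mode == "literal":
        return m * I
    raise ValueError(f"unknown interaction mode {mode!r}")


def default_speed_grid(n: int = 512, lo: float = -2.0, hi: float = 10.0) -> np.ndarray:
    """log2-speed axis covering 0.25-1024 deg/s."""
    return np.linspace(lo, hi, n)


def normalize_density(p: np.ndarray, grid: np.ndarray) -> np.ndarray:
    z = np.trapezoid(p, grid)
    if z <= 0 or not np.isfinite(z):
        raise FloatingPointError("density normalization failed (underflow?)")
    return p / z


def speed_likelihood(
    n: np.ndarray,
    bank: ChannelBank,
    speed_grid: np.ndarray,
    variance_mode: str = "literal",
) -> np.ndarray:
    """Population log-likelihood over log2 speed.

    Each channel's speed tuning is a unit-peak Gaussian over log2 speed at
    its preferred speed with variance sigma^2 (1 - rho) (``"literal"``; the
    cross-section reading ``"cross_section"`` doubles it); the population
    log-likelihood is the activity-weighted sum of log tunings.
    """
    s = bank.spec
    if not math.isclose(s.sigma_x, s.sigma_t):
        raise ValueError("speed tuning assumes sigma_x == sigma_t")
    var = s.sigma_x**2 * (1.0 - s.rho)
    if variance_mode == "cross_section":
        var *= 2.0
    elif variance_mode != "literal":
        raise ValueError(f"unknown variance_mode {variance_mode!r}")
    v = bank.log2_speed
    if speed_grid[0] > v.min() or speed_grid[-1] < v.max():
        raise ValueError("speed grid does not cover the bank's preferred speeds")
    n = np.asarray(n, dtype=float)
    A = float(n.sum())
    B = float(n @ v)
    C = float(n @ v**2)
    return -(A * speed_grid**2 - 2.0 * B * speed_grid + C) / (2.0 * var)


def posterior_update(
    prior: np.ndarray,
    log_likelihood: np.ndarray,
    speed_grid: np.ndarray,
) -> np.ndarray:
    """Pointwise product of prior and (max-shifted) likelihood, renormalized."""
    post = prior * np.exp(log_likelihood - np.max(log_likelihood))
    return normalize_density(post, speed_grid)


@dataclass(frozen=True)
class PosteriorSequence:
    """Per-window posterior over log2 speed; index 0 is the prior window."""

    speed_grid: np.ndarray
    posteriors: np.ndarray  # (n_windows + 1, n_grid)
    log_likelihood: np.ndarray  # (n_grid,), shared across windows
    windows_ms: tuple = FIT_WINDOWS_MS

    @property
    def n_windows(self) -> int:
        return len(self.posteriors) - 1

    def mean_log2(self, omega: int) -> float:
        p = self.posteriors[omega]
        return float(np.trapezoid(self.speed_grid * p, self.speed_grid))

    def var_log2(self, omega: int) -> float:
        mu = self.mean_log2(omega)
        p = self.posteriors[omega]
        return float(np.trapezoid((self.speed_grid - mu) ** 2 * p, self.speed_grid))

    def mode_log2(self, omega: int) -> float:
        return float(self.speed_grid[int(np.argmax(self.posteriors[omega]))])

    def density_at(self, omega: int, log2_speed: np.ndarray) -> np.ndarray:
        return np.interp(
            log2_speed, self.speed_grid, self.posteriors[omega], left=0.0, right=0.0
        )

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("speed_grid_log2", data=self.speed_grid)
            f.create_dataset("posteriors", data=self.posteriors)
            f.create_dataset("log_likelihood", data=self.log_likelihood)
            f.attrs["windows_ms"] = np.asarray(self.windows_ms)

    def sample_speeds(
        self, omega: int, n: int, rng: np.random.Generator
    ) -> np.ndarray:
        """Draw speeds (deg/s) from the window-omega posterior."""
        p = self.posteriors[omega]
        cdf = np.concatenate([[0.0], np.cumsum((p[1:] + p[:-1]) / 2.0 * np.diff(self.speed_grid))])
        cdf /= cdf[-1]
        u = rng.uniform(0.0, 1.0, n)
        s = np.interp(u, cdf, self.speed_grid)
        return 2.0**s


def run_windows(
    stimulus,
    participant: ParticipantParams,
    interactions: InteractionParams | None,
    bank: ChannelBank,
    components=None,
    n_windows: int = len(FIT_WINDOWS_MS),
    interaction_mode: str = "gain",
    speed_grid: np.ndarray | None = None,
    contrast: float | None = None,
    drive: np.ndarray | None = None,
    kernel_matrix: np.ndarray | None = None,
) -> PosteriorSequence:
    """Forward-run the model: prior at omega=0, then one Bayesian update per
    50-ms window with a likelihood held fixed across windows (the feedforward
    drive carries no window dependence; all temporal dynamics come from the
    recursion)."""
    if speed_grid is None:
        speed_grid = default_speed_grid()
    if drive is None:
        m = channel_response(bank, stimulus, contrast=contrast, components=components)
    else:
        c = contrast if contrast is not None else getattr(stimulus, "contrast", 0.6)
        m = bank.weights * drive * c
    m = participant.g**2 * m
    if kernel_matrix is not None:
        kernel = kernel_matrix
    else:
        kernel = interaction_kernel(interactions) if interactions is not None else None
    n = apply_interactions(m, bank, kernel, mode=interaction_mode)
    logL = speed_likelihood(n, bank, speed_grid)
    posts = [participant.prior_density(speed_grid)]
    for _ in range(n_windows):
        posts.append(posterior_update(posts[-1], logL, speed_grid))
    return PosteriorSequence(speed_grid, np.array(posts), logL)
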