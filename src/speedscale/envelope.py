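"""Discretized motion-energy envelopes over the log-frequency plane.

A motion cloud's energy is a product of log-normal distributions in spatial
frequency and speed (the orientation dimension is marginalized out: the
channel model is two-dimensional in (fx, ft)).  In (log2 sf, log2 tf)
coordinates the density is a product of two Gaussians in (log2 sf, log2 v),
sheared by log2 tf = log2 sf + log2 v.  A grating is a Dirac point.  The
envelope is the common currency between stimuli and the channel bank.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .catalog import ComponentSpec, PatternSpec, component_map

__all__ = [
    "FWHM_TO_SIGMA",
    "FrequencyGrid",
    "SpectralEnvelope",
    "default_grid",
    "union_grid",
    "mc_envelope",
    "dg_envelope",
    "pattern_envelope",
    "measure_fwhm",
]

#: Gaussian sigma per unit FWHM: sigma = FWHM / (2 sqrt(2 ln 2)).
FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


@dataclass(frozen=True)
class FrequencyGrid:
    """Rectangular lattice over (log2 sf, log2 tf), both in octaves."""

    log2_sf: np.ndarray  # (n_sf,)
    log2_tf: np.ndarray  # (n_tf,)

    def __post_init__(self) -> None:
        for ax in (self.log2_sf, self.log2_tf):
            if not np.all(np.isfinite(ax)):
                raise ValueError("grid axes must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return len(self.log2_sf), len(self.log2_tf)

    def mesh(self) -> tuple[np.ndarray, np.ndarray]:
        return np.meshgrid(self.log2_sf, self.log2_tf, indexing="ij")

    def nodes(self) -> np.ndarray:
        """All grid nodes as an (n_sf*n_tf, 2) array of (log2 sf, log2 tf)."""
        xx, tt = self.mesh()
        return np.column_stack([xx.ravel(), tt.ravel()])

    def cell_area(self) -> float:
        dx = float(np.mean(np.diff(self.log2_sf)))
        dt = float(np.mean(np.diff(self.log2_tf)))
        return dx * dt

    def contains(self, log2_sf: float, log2_tf: float) -> bool:
        return bool(
            self.log2_sf[0] <= log2_sf <= self.log2_sf[-1]
            and self.log2_tf[0] <= log2_tf <= self.log2_tf[-1]
        )


@dataclass(frozen=True)
class SpectralEnvelope:
    """Non-negative mass per grid node, summing to one before contrast."""

    grid: FrequencyGrid
    mass: np.ndarray  # (n_sf, n_tf)
    total_contrast: float = 0.60

    def __post_init__(self) -> None:
        if self.mass.shape != self.grid.shape:
            raise ValueError("mass shape does not match grid")
        if np.any(self.mass < 0):
            raise ValueError("envelope mass must be non-negative")
        if not math.isclose(float(self.mass.sum()), 1.0, abs_tol=1e-8):
            raise ValueError("envelope mass must sum to 1")

    def marginal_sf(self) -> np.ndarray:
        return self.mass.sum(axis=1)

    def marginal_tf(self) -> np.ndarray:
        return self.mass.sum(axis=0)

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("log2_sf", data=self.grid.log2_sf)
            f.create_dataset("log2_tf", data=self.grid.log2_tf)
            f.create_dataset("mass", data=self.mass)
            f.attrs["total_contrast"] = self.total_contrast

    @classmethod
    def from_hdf5(cls, path) -> "SpectralEnvelope":
        import h5py

        with h5py.File(path, "r") as f:
            grid = FrequencyGrid(f["log2_sf"][:], f["log2_tf"][:])
            return cls(grid, f["mass"][:], float(f.attrs["total_contrast"]))


def default_grid(
    center_log2_sf: float,
    center_log2_tf: float,
    half_span: float = 3.0,
    n: int = 64,
) -> FrequencyGrid:
    """Default 64x64 lattice spanning +-3 octaves around a centre."""
    return FrequencyGrid(
        np.linspace(center_log2_sf - half_span, center_log2_sf + half_span, n),
        np.linspace(center_log2_tf - half_span, center_log2_tf + half_span, n),
    )


def union_grid(specs, half_span: float = 3.0, n: int = 64) -> FrequencyGrid:
    """Box covering +-half_span octaves around every component centre."""
    xs = [s.log2_sf for s in specs]
    ts = [s.log2_tf for s in specs]
    return FrequencyGrid(
        np.linspace(min(xs) - half_span, max(xs) + half_span, n),
        np.linspace(min(ts) - half_span, max(ts) + half_span, n),
    )


def mc_envelope(
    spec: ComponentSpec,
    grid: FrequencyGrid | None = None,
    truncation_tol: float = 0.01,
) -> SpectralEnvelope:
    """Motion-cloud envelope: sheared product of log2-sf and log2-speed
    Gaussians with FWHMs ``b_sf`` and ``b_v`` octaves.

    The (log2 sf) marginal keeps FWHM ``b_sf`` exactly because the shear acts
    only on the temporal axis.  Warns if the grid truncates more than
    ``truncation_tol`` of the analytic mass.
    """
    if spec.stimulus_type != "MC":
        raise ValueError(f"{spec.id} is not an MC")
    if grid is None:
        grid = default_grid(spec.log2_sf, spec.log2_tf)
    sigma_sf = spec.b_sf * FWHM_TO_SIGMA
    sigma_v = spec.b_v * FWHM_TO_SIGMA
    xx, tt = grid.mesh()
    z_sf = (xx - spec.log2_sf) / sigma_sf
    z_v = ((tt - xx) - spec.log2_v) / sigma_v
    density = np.exp(-0.5 * (z_sf**2 + z_v**2))
    total = float(density.sum())
    if total <= 0:
        raise ValueError(f"{spec.id}: grid does not cover the envelope support")
    analytic = 2.0 * math.pi * sigma_sf * sigma_v
    covered = total * grid.cell_area() / analytic
    if covered < 1.0 - truncation_tol:
        warnings.warn(
            f"{spec.id}: grid truncates {1.0 - covered:.1%} of the envelope mass",
            stacklevel=2,
        )
    return SpectralEnvelope(grid, density / total, spec.contrast)


def dg_envelope(spec: ComponentSpec, grid: FrequencyGrid | None = None) -> SpectralEnvelope:
    """Grating envelope: all mass on the node nearest (log2 sf0, log2 tf0).

    The channel-model path may bypass the grid entirely and evaluate channel
    tuning at the exact stimulus point; this gridded form exists so gratings
    and clouds share one envelope currency.
    """
    if spec.stimulus_type != "DG":
        raise ValueError(f"{spec.id} is not a DG")
    if grid is None:
        grid = default_grid(spec.log2_sf, spec.log2_tf)
    if not grid.contains(spec.log2_sf, spec.log2_tf):
        raise ValueError(f"{spec.id}: stimulus point lies outside the grid")
    i = int(np.argmin(np.abs(grid.log2_sf - spec.log2_sf)))
    j = int(np.argmin(np.abs(grid.log2_tf - spec.log2_tf)))
    mass = np.zeros(grid.shape)
    mass[i, j] = 1.0
    return SpectralEnvelope(grid, mass, spec.contrast)


def pattern_envelope(
    pattern: PatternSpec,
    components,
    grid: FrequencyGrid | None = None,
) -> SpectralEnvelope:
    """Node-wise average of the pattern's component envelopes."""
    cmap = components if isinstance(components, dict) else component_map(components)
    specs = [cmap[i] for i in pattern.component_ids]
    types = {s.stimulus_type for s in specs}
    if len(types) > 1:
        raise ValueError(f"pattern {pattern.id}: mixed MC/DG components")
    if grid is None:
        grid = union_grid(specs)
    build = mc_envelope if types == {"MC"} else dg_envelope
    masses = [build(s, grid).mass for s in specs]
    return SpectralEnvelope(grid, np.mean(masses, axis=0), pattern.contrast)


def measure_fwhm(axis: np.ndarray, values: np.ndarray) -> float:
    """Full width at half maximum of a sampled unimodal curve.

    Half-max crossings are located by linear interpolation between samples.
    """
    values = np.asarray(values, dtype=float)
    peak = values.max()
    if peak <= 0:
        raise ValueError("curve has no positive peak")
    half = peak / 2.0
    above = values >= half
    idx = np.flatnonzero(above)
    if idx.size == 0:
        raise ValueError("no samples above half maximum")
    lo, hi = idx[0], idx[-1]

    def _cross(i0: int, i1: int) -> float:
        y0, y1 = values[i0], values[i1]
        if y1 == y0:
            return float(axis[i0])
        frac = (half - y0) / (y1 - y0)
        return float(axis[i0] + frac * (axis[i1] - axis[i0]))

    left = _cross(lo - 1, lo) if lo > 0 else float(axis[0])
    right = _cross(hi + 1, hi) if hi < len(values) - 1 else float(axis[-1])
    return abs(right - left)
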