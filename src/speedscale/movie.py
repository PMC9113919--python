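"""Desk-scale stimulus movie synthesis.

Motion clouds are synthesized directly as a sum of N drifting Gabor elements
whose orientation, spatial frequency and speed are sampled from the cloud's
envelope distributions and whose phases are uniform random; gratings are
analytic sinusoids.  Patterns are the scaled sum of their components.  The
final movie is rescaled to the requested RMS contrast.  Streaming
autoregressive synthesis of long movies is deliberately out of scope.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .catalog import ComponentSpec, PatternSpec, component_map
from .envelope import FWHM_TO_SIGMA

__all__ = ["MovieConfig", "synthesize_movie", "dg_frame_analytic", "rms_contrast"]


@dataclass(frozen=True)
class MovieConfig:
    """Synthesis geometry: N Gabor elements on a square frame.

    ``pixel_pitch`` is deg/pixel and ``frame_rate`` Hz; the defaults give a
    small patch suitable for spectral checks rather than display.
    """

    n_elements: int = 300
    frame_size: int = 64
    duration: int = 64
    pixel_pitch: float = 0.125
    frame_rate: float = 100.0
    seed: int = 0
    min_elements: int = 50

    def __post_init__(self) -> None:
        if min(self.n_elements, self.frame_size, self.duration) <= 0:
            raise ValueError("movie dimensions must be positive")
        if self.pixel_pitch <= 0 or self.frame_rate <= 0:
            raise ValueError("pixel pitch and frame rate must be positive")


def rms_contrast(movie: np.ndarray) -> float:
    return float(np.std(movie))


def _axes(cfg: MovieConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    x = (np.arange(cfg.frame_size) - cfg.frame_size / 2) * cfg.pixel_pitch
    t = np.arange(cfg.duration) / cfg.frame_rate
    return x, x.copy(), t


def dg_frame_analytic(spec: ComponentSpec, cfg: MovieConfig, frame: int) -> np.ndarray:
    """Single drifting-grating frame: unit-amplitude vertical sinusoid
    moving at v0 (phase 2*pi*(sf0*x - tf0*t))."""
    x, y, t = _axes(cfg)
    phase = 2 * math.pi * (spec.sf0 * x - spec.tf0 * t[frame])
    return np.broadcast_to(np.sin(phase)[None, :], (cfg.frame_size, cfg.frame_size)).copy()


def _dg_movie(spec: ComponentSpec, cfg: MovieConfig, rng: np.random.Generator) -> np.ndarray:
    x, _, t = _axes(cfg)
    phi0 = rng.uniform(0, 2 * math.pi)
    phase = 2 * math.pi * (spec.sf0 * x[None, None, :] - spec.tf0 * t[:, None, None]) + phi0
    return np.broadcast_to(np.sin(phase), (cfg.duration, cfg.frame_size, cfg.frame_size)).copy()


def _mc_movie(spec: ComponentSpec, cfg: MovieConfig, rng: np.random.Generator) -> np.ndarray:
    if cfg.n_elements < cfg.min_elements:
        warnings.warn(
            f"n_elements={cfg.n_elements} may undersample the envelope "
            f"(floor {cfg.min_elements})",
            stacklevel=3,
        )
    n = cfg.n_elements
    # Element characteristics sampled from the envelope distributions.
    theta = np.deg2rad(rng.normal(spec.theta0, spec.dtheta, n))
    sf = spec.sf0 * 2.0 ** rng.normal(0.0, spec.b_sf * FWHM_TO_SIGMA, n)
    v = spec.v0 * 2.0 ** rng.normal(0.0, spec.b_v * FWHM_TO_SIGMA, n)
    tf = sf * v
    phases = rng.uniform(0, 2 * math.pi, n)
    extent = cfg.frame_size * cfg.pixel_pitch
    px = rng.uniform(-extent / 2, extent / 2, n)
    py = rng.uniform(-extent / 2, extent / 2, n)
    # Gabor spatial envelope: one wavelength SD keeps each element narrowband
    # while remaining localized within the patch.
    sigma_g = 1.0 / sf

    x, y, t = _axes(cfg)
    xx, yy = np.meshgrid(x, y, indexing="xy")
    movie = np.zeros((cfg.duration, cfg.frame_size, cfg.frame_size))
    for i in range(n):
        # Vertical-ish orientation: carrier varies along the direction
        # perpendicular to the element's orientation.
        ux, uy = math.sin(theta[i]), -math.cos(theta[i])
        proj = ux * (xx - px[i]) + uy * (yy - py[i])
        env = np.exp(
            -((xx - px[i]) ** 2 + (yy - py[i]) ** 2) / (2 * sigma_g[i] ** 2)
        )
        carrier_space = 2 * math.pi * sf[i] * proj + phases[i]
        # (duration, fs, fs) via broadcasting over time.
        carrier = np.sin(
            carrier_space[None, :, :] - 2 * math.pi * tf[i] * t[:, None, None]
        )
        movie += env[None, :, :] * carrier
    return movie


def synthesize_movie(
    spec: ComponentSpec | PatternSpec,
    cfg: MovieConfig,
    components=None,
) -> np.ndarray:
    """Synthesize a (duration, frame_size, frame_size) luminance-contrast
    movie, rescaled so its RMS contrast equals the spec's contrast."""
    rng = np.random.default_rng(cfg.seed)
    if isinstance(spec, PatternSpec):
        if components is None:
            raise ValueError("pattern synthesis needs the component catalog")
        cmap = components if isinstance(components, dict) else component_map(components)
        parts = [cmap[i] for i in spec.component_ids]
        raw = np.zeros((cfg.duration, cfg.frame_size, cfg.frame_size))
        for part in parts:
            builder = _mc_movie if part.stimulus_type == "MC" else _dg_movie
            raw += builder(part, cfg, rng)
        target = spec.contrast
    else:
        builder = _mc_movie if spec.stimulus_type == "MC" else _dg_movie
        raw = builder(spec, cfg, rng)
        target = spec.contrast
    sd = raw.std()
    if sd == 0:
        raise ValueError("degenerate movie with zero variance")
    return raw * (target / sd)
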