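"""Stimulus catalog and speed/scale geometry in log-frequency coordinates.

The experiment probes ocular following with two families of motion stimuli:
drifting gratings (DG; a single point in the spatiotemporal-frequency plane)
and motion clouds (MC; broadband random textures whose motion energy forms an
oriented ellipse along an iso-velocity line).  Fifteen components tile the
plane along five iso-speed lines, and nine patterns superimpose two or three
of them.  All geometry here lives in log-frequency coordinates, where the
speed axis is the iso-velocity direction (log tf - log sf constant) and the
scale axis is orthogonal to it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ComponentSpec",
    "PatternSpec",
    "CatalogError",
    "MC_FIXED",
    "load_catalog",
    "catalog_frames",
    "component_map",
    "grid_unit",
    "relative_geometry",
    "pattern_geometry",
    "scale_rank",
]

#: Fixed motion-cloud parameters shared by every component MC: vertical
#: orientation, 15 deg orientation spread, one-octave FWHM bandwidths in
#: spatial frequency and speed, 60% RMS contrast.
MC_FIXED = {
    "theta0": 90.0,
    "dtheta": 15.0,
    "b_sf": 1.0,
    "b_v": 1.0,
    "contrast": 0.60,
}


class CatalogError(ValueError):
    """Raised when the packaged stimulus catalog fails validation."""


@dataclass(frozen=True)
class ComponentSpec:
    """A single motion component: a grating (DG) or a motion cloud (MC).

    Parameters are the centre frequencies ``sf0`` (cycles/deg), ``tf0`` (Hz)
    and speed ``v0 = tf0/sf0`` (deg/s), plus the distribution spreads that are
    zero for a grating and fixed at the packaged values for a cloud.
    """

    id: str
    stimulus_type: str  # "MC" or "DG"
    sf0: float
    tf0: float
    v0: float
    theta0: float = 90.0
    dtheta: float = 0.0
    b_sf: float = 0.0
    b_v: float = 0.0
    contrast: float = 0.60

    def __post_init__(self) -> None:
        if self.stimulus_type not in ("MC", "DG"):
            raise CatalogError(f"unknown stimulus type {self.stimulus_type!r}")
        if not (self.sf0 > 0 and self.tf0 > 0):
            raise CatalogError(f"{self.id}: frequencies must be positive")
        if not (0 < self.contrast <= 1):
            raise CatalogError(f"{self.id}: contrast must lie in (0, 1]")
        # v0 = tf0/sf0 up to printed rounding (last printed decimal).
        if abs(self.v0 - self.tf0 / self.sf0) > 0.05 * self.v0:
            raise CatalogError(
                f"{self.id}: v0={self.v0} inconsistent with tf0/sf0="
                f"{self.tf0 / self.sf0:.3f}"
            )
        if self.stimulus_type == "DG" and (self.dtheta or self.b_sf or self.b_v):
            raise CatalogError(f"{self.id}: DG must have zero-valued spreads")

    @property
    def log2_sf(self) -> float:
        return math.log2(self.sf0)

    @property
    def log2_tf(self) -> float:
        return math.log2(self.tf0)

    @property
    def log2_v(self) -> float:
        return math.log2(self.tf0 / self.sf0)


@dataclass(frozen=True)
class PatternSpec:
    """A pattern built by superimposing 2-3 components of the catalog."""

    id: str
    component_ids: tuple[str, ...]
    contrast: float = 0.60

    def __post_init__(self) -> None:
        if not 2 <= len(self.component_ids) <= 3:
            raise CatalogError(f"pattern {self.id}: needs 2 or 3 components")


def _data_frame(name: str) -> pd.DataFrame:
    with resources.files("speedscale.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def catalog_frames() -> tuple[pd.DataFrame, pd.DataFrame]:
    """Raw packaged catalog tables (including printed distances/angles)."""
    return _data_frame("components.csv"), _data_frame("patterns.csv")


def load_catalog(
    stimulus_type: str = "MC",
) -> tuple[list[ComponentSpec], list[PatternSpec]]:
    """Load the packaged 15-component / 9-pattern stimulus catalog.

    ``stimulus_type`` selects the MC or DG realisation of the same frequency
    coordinates; the MC realisation carries the fixed cloud parameters
    (vertical orientation, 1-octave bandwidths, 60% contrast).
    """
    if stimulus_type not in ("MC", "DG"):
        raise CatalogError(f"unknown stimulus type {stimulus_type!r}")
    comp_df, pat_df = catalog_frames()
    if len(comp_df) != 15 or len(pat_df) != 9:
        raise CatalogError(
            f"corrupted catalog: expected 15 components and 9 patterns, "
            f"found {len(comp_df)} and {len(pat_df)}"
        )
    spreads = MC_FIXED if stimulus_type == "MC" else {
        "theta0": 90.0, "dtheta": 0.0, "b_sf": 0.0, "b_v": 0.0,
        "contrast": MC_FIXED["contrast"],
    }
    components = [
        ComponentSpec(
            id=row.id, stimulus_type=stimulus_type,
            sf0=row.sf0, tf0=row.tf0, v0=row.v0, **spreads,
        )
        for row in comp_df.itertuples()
    ]
    known = {c.id for c in components}
    patterns = []
    for row in pat_df.itertuples():
        ids = tuple(f"c{tok}" for tok in str(row.components).split())
        missing = [i for i in ids if i not in known]
        if missing:
            raise CatalogError(f"pattern {row.id}: unknown components {missing}")
        patterns.append(PatternSpec(id=row.id, component_ids=ids))
    return components, patterns


def component_map(components: Iterable[ComponentSpec]) -> dict[str, ComponentSpec]:
    return {c.id: c for c in components}


def _log_coords(spec: ComponentSpec) -> np.ndarray:
    return np.array([spec.log2_sf, spec.log2_tf])


def grid_unit(components: Sequence[ComponentSpec] | Mapping[str, ComponentSpec] | None = None) -> float:
    """Length of one catalog grid unit in octaves.

    Relative distances in the catalog are normalised by the c1->c5 log
    distance (printed as exactly 1.00), the spacing of the innermost ring
    of the stimulus lattice.
    """
    if components is None:
        components = load_catalog()[0]
    cmap = components if isinstance(components, Mapping) else component_map(components)
    d = _log_coords(cmap["c5"]) - _log_coords(cmap["c1"])
    return float(np.hypot(*d))


class Geometry(NamedTuple):
    distance: float
    angle: float
    defined: bool = True


def relative_geometry(
    target: ComponentSpec,
    reference: ComponentSpec,
    unit: float | None = None,
) -> Geometry:
    """Distance (grid units) and polar angle (deg) of ``target`` from
    ``reference`` in the log-frequency plane.

    The angle is atan2(dlog tf, dlog sf) in (-180, 180]; it is invariant to
    the log base because both axes share it.  Coincident points have zero
    distance and an undefined angle, reported as 0 with ``defined=False``.
    """
    if unit is None:
        unit = grid_unit()
    dx = target.log2_sf - reference.log2_sf
    dt = target.log2_tf - reference.log2_tf
    dist = math.hypot(dx, dt) / unit
    if dist == 0.0:
        return Geometry(0.0, 0.0, defined=False)
    return Geometry(dist, math.degrees(math.atan2(dt, dx)), defined=True)


class PatternGeometry(NamedTuple):
    mean_speed: float
    span: float
    orientation: float
    residual: float = 0.0


def pattern_geometry(
    pattern: PatternSpec,
    components: Sequence[ComponentSpec] | Mapping[str, ComponentSpec],
    unit: float | None = None,
    collinearity_tol: float = 0.05,
) -> PatternGeometry:
    """Nominal speed (deg/s), end-to-end span (grid units) and orientation
    (deg in [0, 180)) of a pattern's component line.

    ``mean_speed`` is the median of the component speeds: for the symmetric
    triplets this is the central component's speed (24 deg/s), and for pairs
    the midpoint of the two speeds — exactly the catalog's printed values
    (a plain arithmetic mean would not reproduce the triplet rows).
    Orientation is the principal axis of the component coordinates; for a
    non-collinear triplet the best-fit line is reported together with the
    RMS perpendicular residual (grid units).
    """
    if unit is None:
        unit = grid_unit(components)
    cmap = components if isinstance(components, Mapping) else component_map(components)
    specs = [cmap[i] for i in pattern.component_ids]
    pts = np.array([_log_coords(s) for s in specs])
    mean_speed = float(np.median([s.v0 for s in specs]))

    # Span: distance between the two mutually most distant components.
    diffs = pts[:, None, :] - pts[None, :, :]
    span = float(np.sqrt((diffs**2).sum(-1)).max()) / unit

    centred = pts - pts.mean(axis=0)
    if np.allclose(centred, 0.0):
        return PatternGeometry(mean_speed, 0.0, 0.0, 0.0)
    # Principal axis via SVD; first right singular vector is the line.
    _, svals, vt = np.linalg.svd(centred, full_matrices=False)
    direction = vt[0]
    orientation = math.degrees(math.atan2(direction[1], direction[0])) % 180.0
    residual = float(svals[1] / math.sqrt(len(specs))) / unit if len(svals) > 1 else 0.0
    if residual > collinearity_tol:
        import warnings

        warnings.warn(
            f"pattern {pattern.id}: components deviate from a line "
            f"(RMS residual {residual:.3f} grid units); reporting best-fit "
            "orientation",
            stacklevel=2,
        )
    return PatternGeometry(mean_speed, span, orientation, residual)


def scale_rank(components: Sequence[ComponentSpec]) -> dict[str, str]:
    """Classify components into low/medium/high scale ranges.

    Scale is indexed by the product sf*tf; the 15 catalog components split
    into three groups of five along the scale axis.
    """
    order = sorted(components, key=lambda c: c.sf0 * c.tf0)
    n = len(order)
    labels: dict[str, str] = {}
    for k, comp in enumerate(order):
        if k < n // 3:
            labels[comp.id] = "low"
        elif k < 2 * n // 3:
            labels[comp.id] = "medium"
        else:
            labels[comp.id] = "high"
    return labels
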