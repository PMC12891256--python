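"""Projection of 24-2 locations onto widefield GCIPL thickness rasters.

Thickness maps are 160 x 160 grids of 100 um squares (16 x 16 mm), fovea at
the grid centre.  Retinal coordinates are fovea-centred millimetres with x
positive temporal and y positive superior *on the retina*; because the
retinal image is inverted, the field-to-retina projection flips both axes of
the (right-eye-normalised) visual-field coordinates.

Stimulus sampling regions are ellipses with angular radius
0.43/2 + 0.5 = 0.715 degrees (Goldmann III plus a microsaccade allowance on
the radius), converted to millimetres with a Bennett-style linear
magnification model q = 0.01306 * (AL - 1.82) mm/deg by default.  For the 16
central 24-2 locations the region margins are displaced radially outward
according to a Henle-fibre (Drasdo-style) displacement curve that falls to
zero at the edge of the maximum displacement zone (3.4 mm).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .vf import ANALYZABLE, VfLocation

__all__ = [
    "GRID_N", "SQUARE_MM",
    "EyeBiometry", "ThicknessMap", "RetinalRegion", "ClusterAssignment",
    "degrees_to_mm", "project_stimulus", "apply_henle_displacement",
    "henle_displacement_mm", "sample_mean_thickness", "build_cluster_assignment",
    "grid_coords_mm", "read_raster", "write_raster",
    "GROUP_ORDER",
]

GRID_N = 160
SQUARE_MM = 0.1
#: Cluster groups ordered central -> peripheral (naming follows the
#: eccentricity-dependent cluster groups: 6-8 central ... 1 peripheral).
GROUP_ORDER = ("6-8", "4-5", "3", "2", "1")
#: Per-hemifield analyzable VF location counts for the schematic ring template.
RING_SIZES = (2, 4, 7, 9, 4)

STIMULUS_DIAMETER_DEG = 0.43    # Goldmann III
MICROSACCADE_DEG = 0.5          # allowance added to the stimulus radius


@dataclass(frozen=True)
class EyeBiometry:
    """Per-eye covariates needed for projection and normative adjustment."""

    axial_length_mm: float
    age_years: float
    fovea_disc_tilt_deg: float = 0.0

    def __post_init__(self):
        if self.axial_length_mm is None or not np.isfinite(self.axial_length_mm):
            raise ValueError("axial length is required (no emmetropic default)")


@dataclass
class ThicknessMap:
    """A 160x160 GCIPL thickness raster on 100 um squares.

    ``values`` are micrometres; invalid squares are carried both in
    ``valid_mask`` and as NaN.  ``fovea_rc`` is the fractional (row, col)
    index of the fovea; with the default (79.5, 79.5) square centres sit at
    (i - 79.5) * 0.1 mm offsets from the fovea.  Row index increases toward
    the inferior retina.
    """

    values: np.ndarray
    valid_mask: np.ndarray = None
    square_size_mm: float = SQUARE_MM
    fovea_rc: tuple[float, float] = (79.5, 79.5)
    laterality: str = "OD"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (GRID_N, GRID_N):
            raise ValueError(f"thickness grid must be {GRID_N}x{GRID_N}")
        if self.valid_mask is None:
            self.valid_mask = np.isfinite(self.values)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        with np.errstate(invalid="ignore"):
            if np.any(self.values[self.valid_mask] < 0):
                raise ValueError("valid thickness values must be >= 0")


def grid_coords_mm(tmap: ThicknessMap | None = None) -> tuple[np.ndarray, np.ndarray]:
    """(x_mm, y_mm) coordinate vectors of square centres (cols, rows)."""
    fr, fc = tmap.fovea_rc if tmap is not None else (79.5, 79.5)
    s = tmap.square_size_mm if tmap is not None else SQUARE_MM
    cols = (np.arange(GRID_N) - fc) * s
    rows = (fr - np.arange(GRID_N)) * s   # row 0 = superior retina
    return cols, rows


# ---------------------------------------------------------------------------
# angle -> retinal distance
# ---------------------------------------------------------------------------

def _linear_scale(biometry: EyeBiometry) -> float:
    return 0.01306 * (biometry.axial_length_mm - 1.82)


def _model_linear(angle_deg, biometry):
    return np.asarray(angle_deg, dtype=float) * _linear_scale(biometry)


def _model_tangential(angle_deg, biometry):
    """Mildly nonlinear tangential-plane model (projection onto a plane)."""
    a = np.radians(np.asarray(angle_deg, dtype=float))
    return _linear_scale(biometry) * np.degrees(np.tan(a))


MAGNIFICATION_MODELS: dict[str, Callable] = {
    "linear": _model_linear,
    "tangential": _model_tangential,
}


def degrees_to_mm(angle_deg, biometry: EyeBiometry, model: str | Callable = "linear"):
    """Convert visual angle (deg) to signed retinal distance (mm)."""
    fn = MAGNIFICATION_MODELS[model] if isinstance(model, str) else model
    out = fn(angle_deg, biometry)
    return float(out) if np.isscalar(angle_deg) else out


# ---------------------------------------------------------------------------
# stimulus projection
# ---------------------------------------------------------------------------

@dataclass
class RetinalRegion:
    """Elliptical sampling region on the retina, fovea-centred mm."""

    center_mm: tuple[float, float]
    radii_mm: tuple[float, float]
    vf_location: VfLocation = None
    out_of_bounds: bool = field(default=False)

    def __post_init__(self):
        if not all(np.isfinite(self.center_mm)):
            raise ValueError("region centre must be finite")
        if min(self.radii_mm) <= 0:
            raise ValueError("region radii must be positive")

    @property
    def area_mm2(self) -> float:
        return math.pi * self.radii_mm[0] * self.radii_mm[1]

    @property
    def eccentricity_mm(self) -> float:
        return math.hypot(*self.center_mm)


def project_stimulus(
    loc: VfLocation,
    biometry: EyeBiometry,
    model: str | Callable = "linear",
    allowance_deg: float = MICROSACCADE_DEG,
    stimulus_diameter_deg: float = STIMULUS_DIAMETER_DEG,
    half_grid_mm: float = GRID_N * SQUARE_MM / 2,
) -> RetinalRegion:
    """Project an analyzable 24-2 location to its retinal sampling ellipse.

    The angular radius is stimulus radius + allowance; it is converted to mm
    at the local eccentricity (exact for the linear model).  Superior field
    maps to inferior retina and temporal field to nasal retina (both axes
    flip).
    """
    if loc.is_blind_spot:
        raise ValueError("blind-spot locations are not analyzable")
    cx = -degrees_to_mm(loc.x_deg, biometry, model)
    cy = -degrees_to_mm(loc.y_deg, biometry, model)
    r_deg = stimulus_diameter_deg / 2 + allowance_deg
    ecc_deg = loc.eccentricity_deg
    # local scale: symmetric difference about the eccentricity
    r_mm = 0.5 * (degrees_to_mm(ecc_deg + r_deg, biometry, model)
                  - degrees_to_mm(ecc_deg - r_deg, biometry, model))
    oob = (abs(cx) + r_mm > half_grid_mm) or (abs(cy) + r_mm > half_grid_mm)
    return RetinalRegion((cx, cy), (r_mm, r_mm), vf_location=loc, out_of_bounds=oob)


# ---------------------------------------------------------------------------
# Henle-fibre displacement
# ---------------------------------------------------------------------------

MAX_DISPLACEMENT_ZONE_MM = 3.4


def henle_displacement_mm(ecc_mm, peak_mm: float = 0.37, peak_at_mm: float = 0.8,
                          zone_mm: float = MAX_DISPLACEMENT_ZONE_MM):
    """Radial ganglion-cell displacement D(ecc) in mm (Drasdo-style stand-in).

    A smooth unimodal curve peaking near the foveal rim and tapered to zero at
    the edge of the maximum displacement zone.  The exact published curve is
    not reproduced; any callable with the same signature can be substituted.
    """
    r = np.asarray(ecc_mm, dtype=float)
    base = peak_mm * (r / peak_at_mm) * np.exp(1.0 - r / peak_at_mm)
    # smoothstep taper to zero over the outer 20% of the zone
    t = np.clip((zone_mm - r) / (0.2 * zone_mm), 0.0, 1.0)
    taper = t * t * (3 - 2 * t)
    return base * taper


def _is_central_16(loc: VfLocation) -> bool:
    return abs(loc.x_deg) <= 9 and abs(loc.y_deg) <= 9


def apply_henle_displacement(
    region: RetinalRegion,
    displacement: Callable = henle_displacement_mm,
) -> RetinalRegion:
    """Displace the margins of central-16 regions radially outward.

    The inner and outer radial margins are each displaced by D(margin); the
    centre and radial radius are recomputed from the displaced margins.  The
    region is returned unchanged for non-central locations, for zero
    displacement and for a region centred exactly on the fovea.
    """
    if region.vf_location is None:
        raise ValueError("region carries no VF location tag")
    if not _is_central_16(region.vf_location):
        return region
    ecc = region.eccentricity_mm
    if ecc == 0.0:
        return region
    r_rad = region.radii_mm[0]
    m_in, m_out = ecc - r_rad, ecc + r_rad
    m_in2 = m_in + float(displacement(max(m_in, 0.0)))
    m_out2 = m_out + float(displacement(m_out))
    if m_in2 == m_in and m_out2 == m_out:
        return region
    ecc2 = 0.5 * (m_in2 + m_out2)
    r2 = 0.5 * (m_out2 - m_in2)
    ux, uy = region.center_mm[0] / ecc, region.center_mm[1] / ecc
    return replace(region, center_mm=(ux * ecc2, uy * ecc2),
                   radii_mm=(r2, region.radii_mm[1]))


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def _region_index_mask(tmap: ThicknessMap, region: RetinalRegion):
    """Boolean mask over the raster of square centres inside the ellipse."""
    xs, ys = grid_coords_mm(tmap)
    cx, cy = region.center_mm
    rx, ry = region.radii_mm
    dx = (xs[None, :] - cx) / rx
    dy = (ys[:, None] - cy) / ry
    return dx * dx + dy * dy <= 1.0


def sample_mean_thickness(
    tmap: ThicknessMap, region: RetinalRegion
) -> tuple[float, float]:
    """Mean GCIPL (um) over valid squares inside the region, plus coverage.

    Coverage is the valid overlapped area divided by the region area (clamped
    to 1).  Returns (nan, coverage) when no valid square is overlapped: a
    missing value is propagated, never silently zero.
    """
    inside = _region_index_mask(tmap, region)
    valid = inside & tmap.valid_mask
    n_valid = int(valid.sum())
    area = region.area_mm2
    coverage = min(1.0, n_valid * tmap.square_size_mm ** 2 / area)
    if n_valid == 0:
        return float("nan"), 0.0
    return float(np.nanmean(tmap.values[valid])), coverage


# ---------------------------------------------------------------------------
# hemi-cluster maps
# ---------------------------------------------------------------------------

@dataclass
class ClusterAssignment:
    """Hemi-cluster labels for grid squares and VF locations.

    Labels are integer ids; ``legend`` maps id -> (cluster group, hemifield)
    where hemifield names follow the *visual field* convention and groups are
    ordered central -> peripheral as in :data:`GROUP_ORDER`.  Grid label 0
    means unassigned (outside the 24-2 span).
    """

    grid_labels: np.ndarray
    vf_labels: dict[VfLocation, int]
    legend: dict[int, tuple[str, str]]

    def __post_init__(self):
        missing = [p for p in ANALYZABLE if p not in self.vf_labels]
        if missing:
            raise ValueError(f"{len(missing)} VF locations unlabelled")

    def id_for(self, group: str, hemifield: str) -> int:
        for cid, (g, h) in self.legend.items():
            if g == group and h == hemifield:
                return cid
        raise KeyError((group, hemifield))

    def mirror_id(self, cid: int) -> int:
        g, h = self.legend[cid]
        other = "inferior" if h == "superior" else "superior"
        return self.id_for(g, other)


def build_cluster_assignment(
    template: str | Path = "rings",
    laterality: str = "OD",
    tilt_deg: float = 0.0,
    biometry: EyeBiometry | None = None,
) -> ClusterAssignment:
    """Build the default schematic hemi-cluster map or load a user map.

    The shipped template is a synthetic eccentricity-ring partition: each
    hemifield's 26 analyzable VF locations are split central -> peripheral
    into groups of 2/4/7/9/4 points.  True cluster boundaries from the
    normative-database literature are not reproduced; real analyses should
    pass a labelled raster + JSON legend path instead.
    """
    if template != "rings":
        return _load_cluster_map(Path(template))
    if biometry is None:
        biometry = EyeBiometry(axial_length_mm=24.0, age_years=50.0)

    legend: dict[int, tuple[str, str]] = {}
    vf_labels: dict[VfLocation, int] = {}
    cid = 0
    for hemi in ("superior", "inferior"):
        pts = sorted(
            (p for p in ANALYZABLE if p.hemifield == hemi),
            key=lambda p: (p.eccentricity_deg, abs(p.x_deg), p.x_deg, p.y_deg),
        )
        start = 0
        for group, size in zip(GROUP_ORDER, RING_SIZES):
            cid += 1
            legend[cid] = (group, hemi)
            for p in pts[start:start + size]:
                vf_labels[p] = cid
            start += size

    # grid labels: nearest projected analyzable location within the retinal
    # hemifield matching the square's own side of the horizontal midline
    xs, ys = grid_coords_mm(None)
    X, Y = np.meshgrid(xs, ys)
    grid_labels = np.zeros((GRID_N, GRID_N), dtype=int)
    proj = {p: project_stimulus(p, biometry).center_mm for p in ANALYZABLE}
    max_ecc = max(math.hypot(*c) for c in proj.values())
    for hemi_vf, retina_sup in (("superior", False), ("inferior", True)):
        pts = [p for p in ANALYZABLE if p.hemifield == hemi_vf]
        centers = np.array([proj[p] for p in pts])
        labels = np.array([vf_labels[p] for p in pts])
        sel = Y > 0 if retina_sup else Y < 0
        d2 = ((X[sel][:, None] - centers[None, :, 0]) ** 2
              + (Y[sel][:, None] - centers[None, :, 1]) ** 2)
        nearest = np.argmin(d2, axis=1)
        lab = labels[nearest]
        # outside the 24-2 span (beyond the outermost projection + margin)
        ecc = np.hypot(X[sel], Y[sel])
        lab[ecc > max_ecc + 0.6] = 0
        grid_labels[sel] = lab
    if str(laterality).upper() == "OS":
        grid_labels = grid_labels[:, ::-1].copy()
    return ClusterAssignment(grid_labels, vf_labels, legend)


def _load_cluster_map(path: Path) -> ClusterAssignment:
    if path.suffix == ".csv":
        grid = np.loadtxt(path, delimiter=",", dtype=int)
    else:
        import tifffile
        grid = tifffile.imread(path).astype(int)
    meta = json.loads(path.with_suffix(".json").read_text())
    legend = {int(k): tuple(v) for k, v in meta["legend"].items()}
    vf_labels = {}
    for item in meta["vf_labels"]:
        vf_labels[VfLocation(int(item["x_deg"]), int(item["y_deg"]))] = int(item["label"])
    return ClusterAssignment(grid, vf_labels, legend)


def save_cluster_map(assignment: ClusterAssignment, path: str | Path) -> None:
    path = Path(path)
    np.savetxt(path, assignment.grid_labels, fmt="%d", delimiter=",")
    meta = {
        "legend": {str(k): list(v) for k, v in assignment.legend.items()},
        "vf_labels": [
            {"x_deg": p.x_deg, "y_deg": p.y_deg, "label": int(l)}
            for p, l in assignment.vf_labels.items()
        ],
    }
    path.with_suffix(".json").write_text(json.dumps(meta))


# ---------------------------------------------------------------------------
# raster I/O (CSV and single-channel float TIFF; NaN marks invalid squares)
# ---------------------------------------------------------------------------

def write_raster(values: np.ndarray, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile
        tifffile.imwrite(path, np.asarray(values, dtype=np.float32))
    else:
        np.savetxt(path, values, delimiter=",", fmt="%.4f")


def read_raster(path: str | Path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile
        return tifffile.imread(path).astype(float)
    return np.loadtxt(path, delimiter=",")


def read_thickness_map(path: str | Path, laterality: str = "OD") -> ThicknessMap:
    values = read_raster(path)
    if str(laterality).upper() == "OS":
        values = values[:, ::-1].copy()
    return ThicknessMap(values, laterality="OD")
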