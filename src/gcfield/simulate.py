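"""Synthetic cohort generator: thickness maps, biometry, diagnoses and
coupled 24-2 visual fields.

The generator emulates the statistical structure the analysis assumes, so
every stage of the pipeline is testable without clinical data:

* healthy GCIPL surfaces are smooth, eccentricity-dependent (thin fovea,
  ~100 um perifoveal ridge, thin periphery), with an individual thickness
  offset, linear age and fovea-disc-tilt effects and i.i.d. measurement
  noise;
* glaucomatous eyes receive arcuate / hemifield / paracentral thinning of
  configurable depth with smooth margins, clipped at a residual non-neural
  floor and confined to one retinal hemifield (defects respect the
  horizontal midline);
* visual-field thresholds are produced by a segmented forward model of the
  eye's own noiseless ganglion-cell counts, with state-dependent Gaussian
  noise (small at non-defective, large at defective locations), and
  total/pattern deviations and their probability categories are referenced
  to an internally simulated healthy normative ensemble, mirroring how
  perimeters derive them.

Each eye's noiseless thickness is a continuous function of retinal position,
so ground-truth ganglion-cell counts exist even for peripheral field
locations whose projection falls off the scanned raster (which happens for
the 27-degree nasal points in long eyes).  Ground truth (noiseless maps,
defect masks, per-location GC counts and defect states) is stored alongside
the observables for recovery tests.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import vf as vfmod
from .gc import DensityField, default_density_field, gcipl_to_gcl, mean_density
from .mapping import (GRID_N, SQUARE_MM, EyeBiometry, RetinalRegion,
                      ThicknessMap, _region_index_mask,
                      apply_henle_displacement, grid_coords_mm,
                      project_stimulus, write_raster)
from .vf import ANALYZABLE, ProbCategory, VfLocation, VisualFieldResult

__all__ = [
    "SegmentedForward", "DefectModel", "GeneratorConfig", "SyntheticEye",
    "Cohort", "TruthSurface", "generate_healthy_map", "inject_defect",
    "vf_from_structure", "generate_cohort", "write_cohort", "eye_regions",
    "gc_counts_for_truth",
]


@dataclass(frozen=True)
class SegmentedForward:
    """Forward structure-function model: threshold (dB) from GC count (dB)."""

    intercept: float
    slope1: float
    breakpoint: float
    slope2: float

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        return (self.intercept + self.slope1 * x
                + (self.slope2 - self.slope1) * np.maximum(x - self.breakpoint, 0.0))


@dataclass(frozen=True)
class DefectModel:
    """Geometry and depth of simulated glaucomatous thinning."""

    pattern: str = "arcuate"            # arcuate | hemifield | paracentral
    depth_um: float = 25.0
    hemifield: str = "superior"         # retinal hemifield
    ecc_range_mm: tuple[float, float] = (0.6, 7.0)
    angle_range_frac: tuple[float, float] = (0.15, 0.85)  # fraction of pi
    floor_um: float = 30.0              # residual non-neural thickness
    #: optional (start_mm, scale_mm): thinning depth decays as
    #: exp(-(ecc - start)/scale) beyond ``start`` while the defect *extent*
    #: (and hence the functional state) is unchanged -- yields defects whose
    #: structural signature fades peripherally
    depth_taper: tuple[float, float] | None = None

    def weight(self, x_mm, y_mm) -> np.ndarray:
        """Smooth defect weight w in [0, 1] at retinal positions (mm)."""
        X = np.asarray(x_mm, float)
        Y = np.asarray(y_mm, float)
        R = np.hypot(X, Y)
        sign = 1.0 if self.hemifield == "superior" else -1.0
        yh = sign * Y
        hemi = np.clip(yh / 0.3, 0.0, 1.0)          # ramp across the midline
        r0, r1 = self.ecc_range_mm
        ramp = 0.3
        if self.pattern == "hemifield":
            w = np.clip((R - 0.3) / ramp, 0, 1)
        elif self.pattern == "arcuate":
            wr = np.clip((R - r0) / ramp, 0, 1) * np.clip((r1 - R) / ramp, 0, 1)
            theta = np.arctan2(yh, X) / np.pi       # 0..1 within the hemifield
            a0, a1 = self.angle_range_frac
            wa = np.clip((theta - a0) / 0.08, 0, 1) \
                * np.clip((a1 - theta) / 0.08, 0, 1)
            w = wr * wa
        elif self.pattern == "paracentral":
            d = np.hypot(X, Y - sign * 1.5)
            w = np.clip((1.2 - d) / 0.4, 0, 1)
        else:
            raise ValueError(f"unknown defect pattern {self.pattern!r}")
        return w * hemi

    def depth_at(self, x_mm, y_mm) -> np.ndarray:
        """Local thinning depth (um), including the optional eccentric taper."""
        depth = np.full_like(np.asarray(x_mm, float), self.depth_um)
        if self.depth_taper is not None:
            start, scale = self.depth_taper
            r = np.hypot(np.asarray(x_mm, float), np.asarray(y_mm, float))
            depth = depth * np.exp(-np.maximum(r - start, 0.0) / scale)
        return depth


@dataclass
class GeneratorConfig:
    """All dials of the synthetic cohort; defaults echo the study conditions.

    Cohort sizes default to the clinical composition (311 healthy, 268
    suspects, 269 glaucoma); the segmented forward models default to the
    pooled non-defective / defective structure-function parameter sets and
    the visual-field noise to 2 dB at non-defective and 9 dB at defective
    locations, reproducing the qualitative error contrast between states.
    """

    n_healthy: int = 311
    n_suspect: int = 268
    n_glaucoma: int = 269
    seed: int = 0
    # healthy surface (um)
    surface_base_um: float = 45.0
    surface_ridge_um: float = 55.0
    surface_ridge_ecc_mm: float = 1.2
    inter_eye_sd_um: float = 6.0
    noise_sd_um: float = 2.0
    age_effect_um_per_year: float = -0.1
    tilt_effect_um_per_deg: float = 0.2
    reference_age_years: float = 55.0
    # defect model
    defect_floor_um: float = 30.0
    suspect_depth_range_um: tuple[float, float] = (4.0, 10.0)
    suspect_defect_prob: float = 0.5
    glaucoma_depth_range_um: tuple[float, float] = (12.0, 50.0)
    defect_pattern_probs: tuple[float, float, float] = (0.6, 0.2, 0.2)
    defect_inner_ecc_mm: tuple[float, float] = (0.5, 1.5)
    defect_outer_ecc_mm: tuple[float, float] = (5.0, 7.5)
    defect_angle_lo_frac: tuple[float, float] = (0.08, 0.25)
    defect_angle_hi_frac: tuple[float, float] = (0.75, 0.92)
    defect_depth_taper: tuple[float, float] | None = None
    # structure-function forward model per state
    sf_nondefective: SegmentedForward = field(
        default_factory=lambda: SegmentedForward(24.26, 0.41, 17.8, 0.14))
    sf_defective: SegmentedForward = field(
        default_factory=lambda: SegmentedForward(10.85, 0.51, 17.31, 1.00))
    vf_noise_nondefective_dB: float = 2.0
    vf_noise_defective_dB: float = 9.0
    two_vf_per_eye: bool = False
    # internal healthy reference ensemble for TD/PD derivation
    n_reference_vf: int = 150
    threshold_ceiling_dB: float = 45.0

    def __post_init__(self):
        if min(self.n_healthy, self.n_suspect, self.n_glaucoma) < 0:
            raise ValueError("cohort sizes must be >= 0")
        for name in ("inter_eye_sd_um", "noise_sd_um",
                     "vf_noise_nondefective_dB", "vf_noise_defective_dB"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def high_coupling_config(seed: int = 0, n_healthy: int = 120,
                         n_suspect: int = 0, n_glaucoma: int = 120,
                         n_reference_vf: int = 60) -> GeneratorConfig:
    """The low-noise, high-coupling study condition.

    Structural damage translates into clearly depressed thresholds (the
    defective forward model sits well below the healthy one at every count),
    all noise sources are small, and defect geometry is restricted to deep
    arcuate or hemifield patterns whose inner edge sits inside the central
    zone -- so structural features and hemi-cluster visual-field status are
    tightly coupled at every ring (geometry straddling the central sector
    would otherwise decouple them there regardless of noise).  Used to probe
    the classification ceiling of the pipeline.
    """
    return GeneratorConfig(
        n_healthy=n_healthy, n_suspect=n_suspect, n_glaucoma=n_glaucoma,
        seed=seed, noise_sd_um=1.0, inter_eye_sd_um=4.0,
        glaucoma_depth_range_um=(30.0, 55.0),
        defect_pattern_probs=(0.6, 0.4, 0.0),
        defect_inner_ecc_mm=(0.3, 0.5),
        defect_angle_lo_frac=(0.04, 0.10),
        defect_angle_hi_frac=(0.90, 0.96),
        # thinning fades with eccentricity while defect extent (and hence VF
        # status) persists: weak peripheral structural signal, strong
        # central-peripheral status correlation
        defect_depth_taper=(3.0, 0.7),
        sf_defective=SegmentedForward(-1.0, 0.5, 17.3, 0.2),
        vf_noise_nondefective_dB=1.0, vf_noise_defective_dB=2.0,
        n_reference_vf=n_reference_vf,
    )


# ---------------------------------------------------------------------------
# continuous truth surfaces and raster rendering
# ---------------------------------------------------------------------------

def _lattice():
    xs, ys = grid_coords_mm(None)
    return np.meshgrid(xs, ys)


_X, _Y = _lattice()
#: elliptical widefield scan area (about 55 x 45 degrees at AL 24 mm)
FOV_MASK = (_X / 7.95) ** 2 + (_Y / 6.45) ** 2 <= 1.0


@dataclass
class TruthSurface:
    """Noiseless GCIPL thickness as a continuous function of position (mm)."""

    config: GeneratorConfig
    biometry: EyeBiometry
    offset_um: float = 0.0
    defect: DefectModel | None = None

    def __call__(self, x_mm, y_mm) -> np.ndarray:
        c = self.config
        X = np.asarray(x_mm, float)
        Y = np.asarray(y_mm, float)
        u = np.hypot(X, Y) / c.surface_ridge_ecc_mm
        t = (c.surface_base_um
             + c.surface_ridge_um * u ** 2 * np.exp(2.0 * (1.0 - u))
             + self.offset_um
             + c.age_effect_um_per_year
             * (self.biometry.age_years - c.reference_age_years)
             + c.tilt_effect_um_per_deg
             * self.biometry.fovea_disc_tilt_deg * (Y / 8.0))
        if self.defect is not None:
            thinned = t - self.defect.depth_at(X, Y) * self.defect.weight(X, Y)
            t = np.maximum(thinned, np.minimum(t, self.defect.floor_um))
        return np.clip(t, 0.0, 150.0)

    def render(self, rng: np.random.Generator | None = None,
               noise_sd_um: float = 0.0) -> ThicknessMap:
        """Evaluate on the 160x160 lattice, masked to the scanned area."""
        vals = self(_X, _Y)
        if noise_sd_um > 0:
            vals = vals + rng.normal(0.0, noise_sd_um, vals.shape)
        vals = np.clip(vals, 0.0, 150.0)
        return ThicknessMap(np.where(FOV_MASK, vals, np.nan), FOV_MASK.copy())


def generate_healthy_map(
    config: GeneratorConfig,
    rng: np.random.Generator,
    biometry: EyeBiometry,
    offset_um: float | None = None,
) -> tuple[ThicknessMap, ThicknessMap, TruthSurface]:
    """One healthy eye: (observed map, noiseless truth map, truth surface)."""
    if offset_um is None:
        offset_um = rng.normal(0.0, config.inter_eye_sd_um)
    ts = TruthSurface(config, biometry, offset_um)
    truth = ts.render()
    observed = ts.render(rng, config.noise_sd_um)
    return observed, truth, ts


def inject_defect(
    tmap: ThicknessMap,
    model: DefectModel,
    rng: np.random.Generator | None = None,
) -> tuple[ThicknessMap, np.ndarray]:
    """Thin a rendered map inside the defect region; (map, boolean mask).

    The map-level counterpart of attaching a :class:`DefectModel` to a
    :class:`TruthSurface`; useful for testing the defect geometry alone.
    """
    w = model.weight(_X, _Y)
    thinned = tmap.values - model.depth_at(_X, _Y) * w
    thinned = np.maximum(thinned, np.minimum(tmap.values, model.floor_um))
    mask = (w >= 0.5) & tmap.valid_mask & (model.depth_um > 0)
    out = ThicknessMap(np.where(tmap.valid_mask, thinned, np.nan),
                       tmap.valid_mask.copy(), fovea_rc=tmap.fovea_rc)
    return out, mask


# ---------------------------------------------------------------------------
# ganglion-cell counts and visual fields
# ---------------------------------------------------------------------------

def eye_regions(biometry: EyeBiometry) -> dict[VfLocation, RetinalRegion]:
    """Henle-displaced stimulus regions for all analyzable locations."""
    return {p: apply_henle_displacement(project_stimulus(p, biometry))
            for p in ANALYZABLE}


def _region_lattice_points(region: RetinalRegion):
    """Centres of the (unbounded) 100 um lattice falling inside the ellipse."""
    cx, cy = region.center_mm
    rx, ry = region.radii_mm
    j0 = math.floor((cx - rx) / SQUARE_MM + 79.5)
    j1 = math.ceil((cx + rx) / SQUARE_MM + 79.5)
    i0 = math.floor(79.5 - (cy + ry) / SQUARE_MM)
    i1 = math.ceil(79.5 - (cy - ry) / SQUARE_MM)
    js = np.arange(j0, j1 + 1)
    is_ = np.arange(i0, i1 + 1)
    xs = (js - 79.5) * SQUARE_MM
    ys = (79.5 - is_) * SQUARE_MM
    X, Y = np.meshgrid(xs, ys)
    inside = ((X - cx) / rx) ** 2 + ((Y - cy) / ry) ** 2 <= 1.0
    return X[inside], Y[inside]


def gc_counts_for_truth(
    ts: TruthSurface,
    regions: dict[VfLocation, RetinalRegion],
    density: DensityField,
):
    """Ground-truth per-location GC counts from the continuous truth surface.

    Uses the same 100 um lattice geometry as raster sampling, so counts
    coincide exactly with the raster pipeline wherever a region lies fully
    inside the scanned area.  Returns (count_dB, floored, defect_fraction)
    dicts; count_dB is floored at 0 dB below one cell.
    """
    counts, floored, dfrac = {}, {}, {}
    for p, region in regions.items():
        X, Y = _region_lattice_points(region)
        gcl = gcipl_to_gcl(float(np.mean(ts(X, Y))))
        dens = mean_density(density, region)
        count = (gcl / 1000.0) * region.area_mm2 * dens
        if count < 1.0:
            counts[p], floored[p] = 0.0, True
        else:
            counts[p], floored[p] = 10.0 * math.log10(count), False
        if ts.defect is None or ts.defect.depth_um <= 0:
            dfrac[p] = 0.0
        else:
            dfrac[p] = float(np.mean(ts.defect.weight(X, Y) >= 0.5))
    return counts, floored, dfrac


@dataclass
class VfReference:
    """Healthy reference distributions used to derive TD/PD categories."""

    mean_threshold: dict[VfLocation, float]
    td_cuts: dict[VfLocation, np.ndarray]   # quantiles at 0.5/1/2/5%
    pd_cuts: dict[VfLocation, np.ndarray]

    @staticmethod
    def _categorise(value: float, cuts: np.ndarray) -> ProbCategory:
        # cuts ascending: [q0.005, q0.01, q0.02, q0.05]
        for cat, cut in zip((ProbCategory.P_HALF, ProbCategory.P1,
                             ProbCategory.P2, ProbCategory.P5), cuts):
            if value < cut:
                return cat
        return ProbCategory.NS


GH_PERCENTILE = 0.85   # "general height" reference for pattern deviation


def _pattern_deviation(td: np.ndarray) -> np.ndarray:
    return td - np.quantile(td, GH_PERCENTILE)


def build_vf_reference(
    config: GeneratorConfig,
    rng: np.random.Generator,
    density: DensityField,
) -> VfReference:
    """Simulate an internal healthy ensemble and freeze its TD/PD quantiles."""
    locs = list(ANALYZABLE)
    n = config.n_reference_vf
    thr = np.empty((n, len(locs)))
    for i in range(n):
        bio = _draw_biometry(rng, "healthy")
        ts = TruthSurface(config, bio, rng.normal(0.0, config.inter_eye_sd_um))
        counts, _, _ = gc_counts_for_truth(ts, eye_regions(bio), density)
        x = np.array([counts[p] for p in locs])
        noise = rng.normal(0.0, config.vf_noise_nondefective_dB, len(locs))
        thr[i] = np.clip(config.sf_nondefective(x) + noise,
                         0.0, config.threshold_ceiling_dB)
    mean_thr = thr.mean(axis=0)
    td = thr - mean_thr
    pdv = np.apply_along_axis(_pattern_deviation, 1, td)
    qs = (0.005, 0.01, 0.02, 0.05)
    td_cuts = np.quantile(td, qs, axis=0)
    pd_cuts = np.quantile(pdv, qs, axis=0)
    return VfReference(
        mean_threshold={p: float(mean_thr[j]) for j, p in enumerate(locs)},
        td_cuts={p: td_cuts[:, j].copy() for j, p in enumerate(locs)},
        pd_cuts={p: pd_cuts[:, j].copy() for j, p in enumerate(locs)},
    )


def vf_from_structure(
    gc_count_dB: dict[VfLocation, float],
    defect_state: dict[VfLocation, bool],
    config: GeneratorConfig,
    reference: VfReference,
    rng: np.random.Generator,
    eye_id: str = "",
    fp_rate: float | None = None,
) -> VisualFieldResult:
    """Thresholds from the state-dependent segmented forward model + noise."""
    locs = list(ANALYZABLE)
    x = np.array([gc_count_dB[p] for p in locs])
    if np.any(~np.isfinite(x)):
        raise ValueError("GC counts must be finite for all locations")
    state = np.array([defect_state[p] for p in locs])
    mean = np.where(state, config.sf_defective(x), config.sf_nondefective(x))
    sd = np.where(state, config.vf_noise_defective_dB,
                  config.vf_noise_nondefective_dB)
    thr = np.clip(mean + sd * rng.standard_normal(len(locs)),
                  0.0, config.threshold_ceiling_dB)
    mean_ref = np.array([reference.mean_threshold[p] for p in locs])
    td = thr - mean_ref
    pdv = _pattern_deviation(td)
    md = float(td.mean())
    psd = float(np.sqrt(np.mean((td - md) ** 2)))
    td_prob = {p: reference._categorise(td[j], reference.td_cuts[p])
               for j, p in enumerate(locs)}
    pd_prob = {p: reference._categorise(pdv[j], reference.pd_cuts[p])
               for j, p in enumerate(locs)}
    if fp_rate is None:
        fp_rate = float(rng.uniform(0.0, 0.12))
    return VisualFieldResult(
        thresholds_dB={p: float(thr[j]) for j, p in enumerate(locs)},
        total_deviation_dB={p: float(td[j]) for j, p in enumerate(locs)},
        pattern_deviation_dB={p: float(pdv[j]) for j, p in enumerate(locs)},
        td_prob=td_prob, pd_prob=pd_prob,
        md_dB=md, psd_dB=psd, false_positive_rate=fp_rate,
        pd_map_available=md > -22.0, eye_id=eye_id,
    )


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

@dataclass
class SyntheticEye:
    eye_id: str
    diagnosis: str                       # healthy | suspect | glaucoma
    biometry: EyeBiometry
    observed: ThicknessMap
    truth: ThicknessMap                  # noiseless raster, same mask
    surface: TruthSurface                # continuous noiseless thickness
    defect_mask: np.ndarray              # boolean grid (w >= 0.5)
    defect_depth_um: float
    vfs: list[VisualFieldResult]
    gc_count_dB: dict[VfLocation, float] # from the truth surface
    gc_floored: dict[VfLocation, bool]
    defect_state: dict[VfLocation, bool] # generating state per location
    coverage: dict[VfLocation, float]    # raster coverage of each region

    @property
    def vf(self) -> VisualFieldResult:
        return self.vfs[-1]


@dataclass
class Cohort:
    eyes: list[SyntheticEye]
    rocc_ids: frozenset
    test_ids: frozenset
    config: GeneratorConfig
    reference: VfReference
    density: DensityField


_AGE_BY_DX = {"healthy": (55.0, 14.5), "suspect": (62.0, 12.5),
              "glaucoma": (65.0, 11.5)}


def _draw_biometry(rng: np.random.Generator, diagnosis: str) -> EyeBiometry:
    mu, sd = _AGE_BY_DX[diagnosis]
    age = float(np.clip(rng.normal(mu, sd), 20.0, 95.0))
    al = float(np.clip(rng.normal(24.0, 1.15), 21.0, 28.0))
    tilt = float(np.clip(rng.normal(6.8, 3.8), 0.0, 20.0))
    return EyeBiometry(axial_length_mm=al, age_years=age, fovea_disc_tilt_deg=tilt)


def _draw_defect(rng: np.random.Generator, diagnosis: str,
                 config: GeneratorConfig) -> DefectModel | None:
    if diagnosis == "healthy":
        return None
    if diagnosis == "suspect":
        if rng.random() >= config.suspect_defect_prob:
            return None
        depth = rng.uniform(*config.suspect_depth_range_um)
    else:
        depth = rng.uniform(*config.glaucoma_depth_range_um)
    pattern = rng.choice(["arcuate", "hemifield", "paracentral"],
                         p=list(config.defect_pattern_probs))
    hemifield = rng.choice(["superior", "inferior"])
    r0 = rng.uniform(*config.defect_inner_ecc_mm)
    r1 = rng.uniform(*config.defect_outer_ecc_mm)
    a0 = rng.uniform(*config.defect_angle_lo_frac)
    a1 = rng.uniform(*config.defect_angle_hi_frac)
    return DefectModel(pattern=str(pattern), depth_um=float(depth),
                       hemifield=str(hemifield), ecc_range_mm=(r0, r1),
                       angle_range_frac=(a0, a1),
                       floor_um=config.defect_floor_um,
                       depth_taper=config.defect_depth_taper)


def _make_eye(
    eye_id: str,
    diagnosis: str,
    config: GeneratorConfig,
    rng: np.random.Generator,
    density: DensityField,
    reference: VfReference,
) -> SyntheticEye:
    bio = _draw_biometry(rng, diagnosis)
    defect = _draw_defect(rng, diagnosis, config)
    ts = TruthSurface(config, bio, rng.normal(0.0, config.inter_eye_sd_um),
                      defect)
    truth = ts.render()
    observed = ts.render(rng, config.noise_sd_um)
    mask = np.zeros((GRID_N, GRID_N), dtype=bool)
    if defect is not None and defect.depth_um > 0:
        mask = (defect.weight(_X, _Y) >= 0.5) & truth.valid_mask
    regions = eye_regions(bio)
    counts, floored, dfrac = gc_counts_for_truth(ts, regions, density)
    state = {p: bool(dfrac[p] >= 0.5) for p in regions}
    coverage = {}
    for p, region in regions.items():
        inside = _region_index_mask(truth, region) & truth.valid_mask
        coverage[p] = min(1.0, int(inside.sum()) * SQUARE_MM ** 2
                          / region.area_mm2)
    n_vf = 2 if config.two_vf_per_eye else 1
    vfs = [vf_from_structure(counts, state, config, reference, rng, eye_id)
           for _ in range(n_vf)]
    return SyntheticEye(
        eye_id=eye_id, diagnosis=diagnosis, biometry=bio,
        observed=observed, truth=truth, surface=ts, defect_mask=mask,
        defect_depth_um=0.0 if defect is None else defect.depth_um,
        vfs=vfs, gc_count_dB=counts, gc_floored=floored,
        defect_state=state, coverage=coverage,
    )


def generate_cohort(config: GeneratorConfig,
                    density: DensityField | None = None) -> Cohort:
    """Generate the full cohort, reproducibly from ``config.seed``.

    The ROCC cohort comprises about 38% of healthy eyes plus about half of
    the perimetric glaucoma eyes (those with a pointwise defect on the
    generated field); all remaining eyes form the test cohort.
    """
    rng = np.random.default_rng(config.seed)
    if density is None:
        density = default_density_field()
    reference = build_vf_reference(config, rng, density)
    eyes: list[SyntheticEye] = []
    plan = ([("healthy", i) for i in range(config.n_healthy)]
            + [("suspect", i) for i in range(config.n_suspect)]
            + [("glaucoma", i) for i in range(config.n_glaucoma)])
    for dx, i in plan:
        eyes.append(_make_eye(f"{dx[0].upper()}{i:04d}", dx, config, rng,
                              density, reference))
    healthy_ids = [e.eye_id for e in eyes if e.diagnosis == "healthy"]
    perimetric = [e.eye_id for e in eyes if e.diagnosis == "glaucoma"
                  and vfmod.classify_defect_locations(e.vf).count() > 0]
    rocc: set = set()
    n_h = int(round(0.38 * len(healthy_ids)))
    if n_h:
        rocc.update(rng.choice(healthy_ids, size=n_h, replace=False).tolist())
    n_g = max(1, len(perimetric) // 2) if perimetric else 0
    if n_g:
        rocc.update(rng.choice(perimetric, size=n_g, replace=False).tolist())
    all_ids = {e.eye_id for e in eyes}
    return Cohort(eyes=eyes, rocc_ids=frozenset(rocc),
                  test_ids=frozenset(all_ids - rocc),
                  config=config, reference=reference, density=density)


def write_cohort(cohort: Cohort, out_dir: str | Path,
                 raster_format: str = "csv") -> None:
    """Serialize a cohort directory: rasters, VF CSVs and a manifest."""
    out_dir = Path(out_dir)
    (out_dir / "maps").mkdir(parents=True, exist_ok=True)
    (out_dir / "vf").mkdir(exist_ok=True)
    manifest = {
        "seed": cohort.config.seed,
        "config": {k: repr(v) for k, v in asdict(cohort.config).items()},
        "rocc_ids": sorted(cohort.rocc_ids),
        "test_ids": sorted(cohort.test_ids),
        "eyes": [],
    }
    for e in cohort.eyes:
        map_path = out_dir / "maps" / f"{e.eye_id}.{raster_format}"
        write_raster(e.observed.values, map_path)
        for k, vfr in enumerate(e.vfs):
            vfmod.write_vf_csv(vfr, out_dir / "vf" / f"{e.eye_id}_{k}.csv")
        manifest["eyes"].append({
            "eye_id": e.eye_id, "diagnosis": e.diagnosis,
            "age": e.biometry.age_years,
            "axial_length": e.biometry.axial_length_mm,
            "tilt": e.biometry.fovea_disc_tilt_deg,
            "defect_depth_um": e.defect_depth_um,
            "n_vf": len(e.vfs),
            "gc_count_dB": {f"{p.x_deg},{p.y_deg}": e.gc_count_dB[p]
                            for p in ANALYZABLE},
            "defect_state": {f"{p.x_deg},{p.y_deg}": bool(e.defect_state[p])
                             for p in ANALYZABLE},
        })
    (out_dir / "manifest.json").write_text(json.dumps(manifest, default=str))
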