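"""Grid-square normative model, percentile flags and relative thickness maps.

For every 100 um grid square a linear adjustment of GCIPL thickness on age
and fovea-disc tilt is fitted across reference (healthy) eyes and the
empirical residual distribution is retained.  An individual square is
flagged defective when its deviation from the age/tilt-adjusted normative
mean falls strictly below the requested residual percentile (5% by default,
linearly interpolated quantiles).

The relative ("pattern-deviation"-style) map re-references each eye's total
deviation to its own 85th percentile, so generalised thickness offsets cancel
and at most 15% of valid squares can be positive.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .mapping import GRID_N, EyeBiometry, ThicknessMap, ClusterAssignment

__all__ = [
    "NormativeModel", "DeviationResult",
    "build_normative_db", "percentile_flag_map", "relative_thickness_map",
    "proportion_flagged",
]

MIN_REFERENCE_EYES = 20


@dataclass
class NormativeModel:
    """Per-square age/tilt adjustment with empirical residual distributions.

    ``coef`` has shape (3, 160, 160): intercept, age and tilt coefficients.
    ``residuals`` has shape (n_ref, 160, 160) with NaN where a reference eye
    was invalid; squares with fewer than ``min_reference`` references are
    masked out of all downstream flagging.
    """

    coef: np.ndarray
    residuals: np.ndarray
    n_reference: np.ndarray
    valid: np.ndarray
    min_reference: int = MIN_REFERENCE_EYES

    def __post_init__(self):
        self._quantile_cache: dict[float, np.ndarray] = {}

    def adjusted_mean(self, biometry: EyeBiometry) -> np.ndarray:
        return (self.coef[0] + self.coef[1] * biometry.age_years
                + self.coef[2] * biometry.fovea_disc_tilt_deg)

    def residual_quantile(self, pct: float) -> np.ndarray:
        """Linearly interpolated residual quantile per square (NaN if masked)."""
        pct = float(pct)
        if pct in self._quantile_cache:
            return self._quantile_cache[pct]
        flat = self.residuals.reshape(self.residuals.shape[0], -1)
        q = np.full(flat.shape[1], np.nan)
        complete = ~np.isnan(flat).any(axis=0) & self.valid.ravel()
        if complete.any():
            q[complete] = np.quantile(flat[:, complete], pct, axis=0)
        partial = ~complete & self.valid.ravel()
        if partial.any():
            with np.errstate(all="ignore"):
                q[partial] = np.nanquantile(flat[:, partial], pct, axis=0)
        q = q.reshape(self.valid.shape)
        self._quantile_cache[pct] = q
        return q

    def save(self, path: str | Path) -> None:
        np.savez_compressed(
            path, coef=self.coef, residuals=self.residuals,
            n_reference=self.n_reference, valid=self.valid,
            min_reference=self.min_reference,
        )

    @classmethod
    def load(cls, path: str | Path) -> "NormativeModel":
        z = np.load(path)
        return cls(z["coef"], z["residuals"], z["n_reference"], z["valid"],
                   int(z["min_reference"]))


@dataclass
class DeviationResult:
    flag_map: np.ndarray
    total_deviation_map: np.ndarray
    relative_map: np.ndarray
    available: np.ndarray


def build_normative_db(
    reference_maps: Sequence[ThicknessMap],
    reference_biometry: Sequence[EyeBiometry],
    min_reference: int = MIN_REFERENCE_EYES,
) -> NormativeModel:
    """Fit per-square thickness ~ age + tilt across reference eyes."""
    n = len(reference_maps)
    if n < min_reference:
        raise ValueError(f"need at least {min_reference} reference eyes, got {n}")
    if len(reference_biometry) != n:
        raise ValueError("one biometry record per reference map required")
    Y = np.stack([m.values for m in reference_maps]).reshape(n, -1)
    M = np.stack([m.valid_mask for m in reference_maps]).reshape(n, -1)
    Y = np.where(M, Y, np.nan)
    Z = np.column_stack([
        np.ones(n),
        [b.age_years for b in reference_biometry],
        [b.fovea_disc_tilt_deg for b in reference_biometry],
    ])
    coef = np.full((3, GRID_N * GRID_N), np.nan)
    resid = np.full((n, GRID_N * GRID_N), np.nan)
    complete = M.all(axis=0)
    if complete.any():
        beta, *_ = np.linalg.lstsq(Z, Y[:, complete], rcond=None)
        coef[:, complete] = beta
        resid[:, complete] = Y[:, complete] - Z @ beta
    # squares with some missing references: per-square fit on available eyes
    partial = ~complete & (M.sum(axis=0) >= min_reference)
    for j in np.flatnonzero(partial):
        ok = M[:, j]
        beta, *_ = np.linalg.lstsq(Z[ok], Y[ok, j], rcond=None)
        coef[:, j] = beta
        resid[ok, j] = Y[ok, j] - Z[ok] @ beta
    n_ref = M.sum(axis=0)
    valid = n_ref >= min_reference
    shape = (GRID_N, GRID_N)
    return NormativeModel(
        coef=coef.reshape(3, *shape),
        residuals=resid.reshape(n, *shape),
        n_reference=n_ref.reshape(shape),
        valid=valid.reshape(shape),
        min_reference=min_reference,
    )


def percentile_flag_map(
    tmap: ThicknessMap,
    biometry: EyeBiometry,
    norm: NormativeModel,
    pct: float = 0.05,
) -> DeviationResult:
    """Flag squares whose deviation falls strictly below the pct residual quantile.

    Masked model squares and invalid observation squares are unflagged and
    reported unavailable.  The returned result also carries the total
    deviation and relative maps for feature computation.
    """
    if tmap.values.shape != norm.coef.shape[1:]:
        raise ValueError("thickness map and normative model lattices differ")
    available = tmap.valid_mask & norm.valid
    td = tmap.values - norm.adjusted_mean(biometry)
    td[~available] = np.nan
    q = norm.residual_quantile(pct)
    with np.errstate(invalid="ignore"):
        flags = available & (td < q)
    rel = _relative_from_td(td, available)
    return DeviationResult(flag_map=flags, total_deviation_map=td,
                           relative_map=rel, available=available)


def _relative_from_td(td: np.ndarray, available: np.ndarray,
                      pct: float = 0.85) -> np.ndarray:
    vals = td[available]
    if vals.size == 0:
        raise ValueError("no valid squares in map")
    ref = np.quantile(vals, pct)
    rel = td - ref
    rel[~available] = np.nan
    return rel


def relative_thickness_map(
    tmap: ThicknessMap,
    biometry: EyeBiometry,
    norm: NormativeModel,
    pct: float = 0.85,
) -> np.ndarray:
    """Total deviation re-referenced to the eye's own ``pct`` quantile."""
    available = tmap.valid_mask & norm.valid
    td = tmap.values - norm.adjusted_mean(biometry)
    td[~available] = np.nan
    return _relative_from_td(td, available, pct)


def proportion_flagged(
    flags: np.ndarray,
    assignment: ClusterAssignment,
    available: np.ndarray | None = None,
) -> dict[int, float]:
    """Fraction of valid squares flagged, per hemi-cluster id.

    Hemi-clusters without any valid square map to NaN.
    """
    if available is None:
        available = np.isfinite(flags) if flags.dtype != bool else np.ones_like(flags, bool)
    out = {}
    for cid in assignment.legend:
        sel = (assignment.grid_labels == cid) & available
        n = int(sel.sum())
        out[cid] = float(flags[sel].sum()) / n if n else float("nan")
    return out
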