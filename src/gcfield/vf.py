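"""24-2 visual-field representation, defect classification and disease staging.

The 24-2 test pattern has 54 locations on a 6 degree lattice; two of them sit
on the physiological blind spot and are excluded from analysis, leaving 52
analyzable locations.  All coordinates are kept in a right-eye-normalised
field convention: x positive temporal, y positive superior *in visual-field
space*.  Left-eye records are mirrored on read.

Pointwise defects follow the Hodapp-Parrish-Anderson (HPA) rule applied to
the pattern-deviation probability map: a location is defective when it belongs
to a contiguous group of at least three locations flagged at p < 5%, at least
one of which is flagged at p < 1%.  Contiguity defaults to 8-neighbour
adjacency restricted to a single hemifield, reflecting the tendency of
glaucomatous defects to respect the horizontal midline; both choices are
configurable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ProbCategory",
    "VfLocation",
    "VF_GRID",
    "ANALYZABLE",
    "BLIND_SPOT",
    "VisualFieldResult",
    "DefectMap",
    "GlaucomaStage",
    "check_reliability",
    "classify_defect_locations",
    "label_hemiclusters",
    "stage_glaucoma",
    "require_repeatable_defect",
    "read_vf_csv",
    "write_vf_csv",
]


class ProbCategory(Enum):
    """Ordinal perimetric probability categories, most abnormal first.

    The integer value encodes the ordering so that ``cat.value <= P5.value``
    means "p < 5% or worse".
    """

    P_HALF = 0   # p < 0.5%
    P1 = 1       # p < 1%
    P2 = 2       # p < 2%
    P5 = 3       # p < 5%
    NS = 4       # not significant

    def __le__(self, other: "ProbCategory") -> bool:
        return self.value <= other.value

    def __lt__(self, other: "ProbCategory") -> bool:
        return self.value < other.value

    @classmethod
    def from_string(cls, s: str) -> "ProbCategory":
        key = s.strip().lower().replace(" ", "")
        table = {
            "<0.5%": cls.P_HALF, "p<0.5%": cls.P_HALF, "0.005": cls.P_HALF,
            "<1%": cls.P1, "p<1%": cls.P1, "0.01": cls.P1,
            "<2%": cls.P2, "p<2%": cls.P2, "0.02": cls.P2,
            "<5%": cls.P5, "p<5%": cls.P5, "0.05": cls.P5,
            "ns": cls.NS, "notsignificant": cls.NS,
        }
        if key not in table:
            raise ValueError(f"unknown probability category {s!r}")
        return table[key]

    def to_string(self) -> str:
        return {0: "<0.5%", 1: "<1%", 2: "<2%", 3: "<5%", 4: "ns"}[self.value]


@dataclass(frozen=True, order=True)
class VfLocation:
    """A 24-2 test location in right-eye-normalised field coordinates."""

    x_deg: int
    y_deg: int
    is_blind_spot: bool = field(default=False, compare=False)

    @property
    def hemifield(self) -> str:
        """'superior' or 'inferior' in visual-field space."""
        return "superior" if self.y_deg > 0 else "inferior"

    @property
    def eccentricity_deg(self) -> float:
        return float(np.hypot(self.x_deg, self.y_deg))


def _build_grid() -> tuple[VfLocation, ...]:
    rows = {
        21: (-9, -3, 3, 9),
        15: (-15, -9, -3, 3, 9, 15),
        9: (-21, -15, -9, -3, 3, 9, 15, 21),
        # the two 27-degree points extend nasally only
        3: (-27, -21, -15, -9, -3, 3, 9, 15, 21),
    }
    locs = []
    for ay, xs in rows.items():
        for y in (ay, -ay):
            for x in xs:
                blind = (x == 15 and abs(y) == 3)
                locs.append(VfLocation(x, y, blind))
    return tuple(sorted(locs, key=lambda p: (-p.y_deg, p.x_deg)))


#: All 54 grid locations, sorted superior-to-inferior then nasal-to-temporal.
VF_GRID: tuple[VfLocation, ...] = _build_grid()
#: The 52 analyzable (non-blind-spot) locations.
ANALYZABLE: tuple[VfLocation, ...] = tuple(p for p in VF_GRID if not p.is_blind_spot)
#: The two blind-spot locations at (+15, +/-3).
BLIND_SPOT: tuple[VfLocation, ...] = tuple(p for p in VF_GRID if p.is_blind_spot)

assert len(VF_GRID) == 54 and len(ANALYZABLE) == 52


@dataclass
class VisualFieldResult:
    """One 24-2 test: pointwise data keyed by analyzable location.

    ``pd_map_available`` is False for severely depressed fields where the
    perimeter cannot produce a pattern-deviation map; in that case every
    analyzable location is treated as defective downstream.
    """

    thresholds_dB: dict[VfLocation, float]
    total_deviation_dB: dict[VfLocation, float]
    pattern_deviation_dB: dict[VfLocation, float]
    td_prob: dict[VfLocation, ProbCategory]
    pd_prob: dict[VfLocation, ProbCategory]
    md_dB: float
    psd_dB: float
    false_positive_rate: float
    pd_map_available: bool = True
    eye_id: str = ""
    laterality: str = "OD"

    def __post_init__(self) -> None:
        missing = [p for p in ANALYZABLE if p not in self.thresholds_dB]
        if missing:
            raise ValueError(f"{len(missing)} analyzable locations missing thresholds")
        if not (0.0 <= self.false_positive_rate <= 1.0):
            raise ValueError("false_positive_rate must lie in [0, 1]")


@dataclass
class DefectMap:
    """Boolean defect status per analyzable location."""

    defective: dict[VfLocation, bool]

    def __post_init__(self) -> None:
        bad = [p for p in self.defective if p.is_blind_spot]
        if bad:
            raise ValueError("defect map defined on blind-spot locations")

    def count(self) -> int:
        return sum(self.defective.values())

    def locations(self) -> list[VfLocation]:
        return [p for p, d in self.defective.items() if d]


class GlaucomaStage(Enum):
    PRE_PERIMETRIC = "pre-perimetric"
    EARLY = "early"
    MODERATE = "moderate"
    ADVANCED = "advanced"


def check_reliability(vf: VisualFieldResult, fp_cutoff: float = 0.15) -> bool:
    """True iff the false-positive rate is strictly below the cutoff."""
    if vf.false_positive_rate is None or np.isnan(vf.false_positive_rate):
        raise ValueError("false_positive_rate is missing")
    return vf.false_positive_rate < fp_cutoff


def _adjacent(a: VfLocation, b: VfLocation, neighbourhood: int) -> bool:
    dx, dy = abs(a.x_deg - b.x_deg), abs(a.y_deg - b.y_deg)
    if neighbourhood == 8:
        return max(dx, dy) == 6 and dx <= 6 and dy <= 6
    if neighbourhood == 4:
        return dx + dy == 6
    raise ValueError("neighbourhood must be 4 or 8")


def classify_defect_locations(
    vf: VisualFieldResult,
    hemifield_restricted: bool = True,
    neighbourhood: int = 8,
) -> DefectMap:
    """Apply the HPA pointwise rule to the pattern-deviation probability map.

    A location is defective iff it lies in a contiguous group of >= 3
    locations at p < 5% or worse, the group containing >= 1 location at
    p < 1% or worse.  If no pattern-deviation map is available every
    analyzable location is defective.
    """
    if not vf.pd_map_available:
        return DefectMap({p: True for p in ANALYZABLE})
    flagged = [p for p in ANALYZABLE if vf.pd_prob[p] <= ProbCategory.P5]
    defective = {p: False for p in ANALYZABLE}
    # connected components among flagged locations
    remaining = set(flagged)
    while remaining:
        seed = remaining.pop()
        comp = {seed}
        frontier = [seed]
        while frontier:
            cur = frontier.pop()
            for q in list(remaining):
                if hemifield_restricted and q.hemifield != cur.hemifield:
                    continue
                if _adjacent(cur, q, neighbourhood):
                    remaining.discard(q)
                    comp.add(q)
                    frontier.append(q)
        if len(comp) >= 3 and any(vf.pd_prob[p] <= ProbCategory.P1 for p in comp):
            for p in comp:
                defective[p] = True
    return DefectMap(defective)


def label_hemiclusters(
    defects: DefectMap,
    assignment: Mapping[VfLocation, object],
    criterion: float = 0.25,
) -> dict[object, bool]:
    """Label each hemi-cluster defective iff its defective fraction >= criterion.

    The criterion is inclusive so that the two-point central hemi-cluster with
    one defective point (50%) is classified defective.
    """
    unassigned = [p for p in ANALYZABLE if p not in assignment]
    if unassigned:
        raise ValueError(f"{len(unassigned)} analyzable locations unassigned")
    counts: dict[object, list[int]] = {}
    for p in ANALYZABLE:
        cid = assignment[p]
        n_def, n_tot = counts.setdefault(cid, [0, 0])
        counts[cid][1] += 1
        if defects.defective.get(p, False):
            counts[cid][0] += 1
    out = {}
    for cid, (n_def, n_tot) in counts.items():
        if n_tot == 0:
            raise ValueError(f"hemi-cluster {cid} is empty")
        out[cid] = (n_def / n_tot) >= criterion
    return out


def stage_glaucoma(
    vf: VisualFieldResult,
    defects: DefectMap,
    md_bands: tuple[float, float] = (-6.0, -12.0),
) -> GlaucomaStage:
    """Stage severity: pre-perimetric without a defect, else by MD bands.

    Early: MD > -6 dB; moderate: -12 < MD <= -6; advanced: MD <= -12.
    The bands stand in for conventional perimetric staging criteria.
    """
    if defects.count() == 0:
        return GlaucomaStage.PRE_PERIMETRIC
    early_cut, adv_cut = md_bands
    if vf.md_dB > early_cut:
        return GlaucomaStage.EARLY
    if vf.md_dB > adv_cut:
        return GlaucomaStage.MODERATE
    return GlaucomaStage.ADVANCED


def require_repeatable_defect(
    map1: DefectMap | VisualFieldResult,
    map2: DefectMap | VisualFieldResult,
    **hpa_kwargs,
) -> DefectMap:
    """Intersect defect maps from two same-day attempts at the same eye."""
    d1 = map1 if isinstance(map1, DefectMap) else classify_defect_locations(map1, **hpa_kwargs)
    d2 = map2 if isinstance(map2, DefectMap) else classify_defect_locations(map2, **hpa_kwargs)
    if set(d1.defective) != set(d2.defective):
        raise ValueError("defect maps are on mismatched grids")
    return DefectMap({p: d1.defective[p] and d2.defective[p] for p in d1.defective})


# ---------------------------------------------------------------------------
# I/O: one CSV row per location, JSON sidecar for the global indices
# ---------------------------------------------------------------------------

def write_vf_csv(vf: VisualFieldResult, csv_path: str | Path) -> None:
    csv_path = Path(csv_path)
    rows = []
    for p in ANALYZABLE:
        rows.append({
            "x_deg": p.x_deg, "y_deg": p.y_deg,
            "threshold": vf.thresholds_dB[p],
            "td": vf.total_deviation_dB[p],
            "pd": vf.pattern_deviation_dB[p],
            "td_prob": vf.td_prob[p].to_string(),
            "pd_prob": vf.pd_prob[p].to_string(),
        })
    pd.DataFrame(rows).to_csv(csv_path, index=False)
    sidecar = {
        "md": vf.md_dB, "psd": vf.psd_dB, "fp_rate": vf.false_positive_rate,
        "eye": vf.eye_id, "laterality": vf.laterality,
        "pd_map_available": vf.pd_map_available,
    }
    csv_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_vf_csv(csv_path: str | Path) -> VisualFieldResult:
    """Read a VF record; left-eye coordinates are mirrored to right-eye form."""
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    required = {"x_deg", "y_deg", "threshold", "td", "pd", "td_prob", "pd_prob"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise ValueError(
            f"{csv_path.name}: missing column(s) {sorted(missing_cols)}")
    meta = json.loads(csv_path.with_suffix(".json").read_text())
    flip = -1 if str(meta.get("laterality", "OD")).upper() == "OS" else 1
    by_loc = {VfLocation(x, y): p for (x, y), p in
              zip(zip((flip * df.x_deg).astype(int), df.y_deg.astype(int)), df.index)}
    lookup = {}
    for p in ANALYZABLE:
        key = VfLocation(p.x_deg, p.y_deg)
        if key not in by_loc:
            raise ValueError(f"{csv_path.name}: location ({p.x_deg},{p.y_deg}) absent")
        lookup[p] = df.loc[by_loc[key]]
    for i, row in df.iterrows():
        for col in ("td_prob", "pd_prob"):
            if not isinstance(row[col], str):
                raise ValueError(
                    f"{csv_path.name} line {i + 2}: field {col!r} is not a category")
    return VisualFieldResult(
        thresholds_dB={p: float(r["threshold"]) for p, r in lookup.items()},
        total_deviation_dB={p: float(r["td"]) for p, r in lookup.items()},
        pattern_deviation_dB={p: float(r["pd"]) for p, r in lookup.items()},
        td_prob={p: ProbCategory.from_string(r["td_prob"]) for p, r in lookup.items()},
        pd_prob={p: ProbCategory.from_string(r["pd_prob"]) for p, r in lookup.items()},
        md_dB=float(meta["md"]), psd_dB=float(meta["psd"]),
        false_positive_rate=float(meta["fp_rate"]),
        pd_map_available=bool(meta.get("pd_map_available", True)),
        eye_id=str(meta.get("eye", "")), laterality="OD",
    )
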