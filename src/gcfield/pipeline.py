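"""End-to-end orchestration: simulate -> VF analysis -> GC estimation ->
structure-function regression -> normative deviation -> features ->
classification -> evaluation.

Each stage consumes and produces plain tables (pandas) and standard-format
files, so any stage can be rerun from serialized artefacts.  Every run
directory records the effective configuration and seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import vf as vfmod
from .classify import (CENTRAL_PREDICTION, FEATURE_NAMES, CascadeModel,
                       compute_features, features_frame, fit_cascade,
                       fit_pca_logistic, predict)
from .evaluate import CohortSplit, EvalReport, select_method_and_report
from .gc import DensityField, default_density_field, estimate_gc_count, gcipl_to_gcl
from .mapping import (EyeBiometry, ThicknessMap, build_cluster_assignment,
                      sample_mean_thickness)
from .normative import (NormativeModel, build_normative_db, percentile_flag_map,
                        proportion_flagged)
from .sf import (SFDataset, SegmentedModel, compare_nested_f, fit_segmented,
                 max_model_divergence)
from .simulate import (Cohort, GeneratorConfig, eye_regions, generate_cohort)
from .vf import ANALYZABLE

log = logging.getLogger("gcfield")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Every dial of the pipeline, serialisable to YAML/JSON losslessly."""

    seed: int = 0
    generator: GeneratorConfig = None
    n_reference_eyes: int = 200
    fp_cutoff: float = 0.15
    hemicluster_criterion: float = 0.25
    flag_percentile: float = 0.05
    relative_percentile: float = 0.85
    init_breakpoint_dB: float = 15.5
    alpha: float = 0.05
    min_coverage: float = 0.5
    include_floored: bool = False
    ci_method: str = "cluster-bootstrap"
    n_boot: int = 500
    stages: tuple[str, ...] = ("vf", "sf", "normative", "features",
                               "classify", "evaluate")

    def __post_init__(self):
        if self.generator is None:
            self.generator = GeneratorConfig(seed=self.seed)
        elif isinstance(self.generator, Mapping):
            self.generator = GeneratorConfig(**self.generator)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        gen = d.get("generator")
        if isinstance(gen, dict):
            from .simulate import SegmentedForward
            for key in ("sf_nondefective", "sf_defective"):
                if isinstance(gen.get(key), (list, tuple)):
                    gen[key] = SegmentedForward(*gen[key])
                elif isinstance(gen.get(key), dict):
                    gen[key] = SegmentedForward(**gen[key])
            for key, val in gen.items():
                if isinstance(val, list):
                    gen[key] = tuple(val)
        return cls(**d)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        d = self.to_dict()
        for key in ("sf_nondefective", "sf_defective"):
            d["generator"][key] = dataclasses.asdict(
                getattr(self.generator, key))
        text = yaml.safe_dump(json.loads(json.dumps(d)), sort_keys=True)
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class PipelineResult:
    config: PipelineConfig
    cohort: Cohort
    vf_table: pd.DataFrame = None
    sf_models: dict = None
    sf_table: pd.DataFrame = None
    normative: NormativeModel = None
    features: pd.DataFrame = None
    scores: pd.DataFrame = None
    cascade: CascadeModel = None
    pca_models: dict = None
    report: EvalReport = None


def _stage_vf(cohort: Cohort, cfg: PipelineConfig):
    """Reliability, pointwise HPA defects, hemi-cluster labels, staging."""
    assignment = build_cluster_assignment()
    rows = []
    defect_maps = {}
    hemi_labels = {}
    for e in cohort.eyes:
        reliable = vfmod.check_reliability(e.vf, cfg.fp_cutoff)
        dm = vfmod.classify_defect_locations(e.vf)
        defect_maps[e.eye_id] = dm
        labels = vfmod.label_hemiclusters(dm, assignment.vf_labels,
                                          cfg.hemicluster_criterion)
        hemi_labels[e.eye_id] = labels
        stage = vfmod.stage_glaucoma(e.vf, dm)
        rows.append({"eye": e.eye_id, "diagnosis": e.diagnosis,
                     "reliable": reliable, "md": e.vf.md_dB,
                     "psd": e.vf.psd_dB, "n_defective": dm.count(),
                     "stage": stage.value if e.diagnosis == "glaucoma" else ""})
    return pd.DataFrame(rows), defect_maps, hemi_labels, assignment


def _stage_sf(cohort: Cohort, cfg: PipelineConfig, defect_maps):
    """Assemble (count_dB, threshold) pairs and fit the stratified models."""
    recs = []
    for e in cohort.eyes:
        regions = eye_regions(e.biometry)
        dm = defect_maps[e.eye_id]
        for p in ANALYZABLE:
            mean_um, cov = sample_mean_thickness(e.observed, regions[p])
            if not np.isfinite(mean_um) or cov < cfg.min_coverage:
                continue
            est = estimate_gc_count(gcipl_to_gcl(mean_um), regions[p],
                                    cohort.density)
            if est.floored and not cfg.include_floored:
                continue
            recs.append({
                "eye": e.eye_id, "x_deg": p.x_deg, "y_deg": p.y_deg,
                "gcl_mean_um": est.gcl_mean_um, "area_mm2": est.area_mm2,
                "density_mm3": est.mean_density_mm3, "count": est.count,
                "count_dB": est.count_dB,
                "threshold_dB": e.vf.thresholds_dB[p],
                "stratum": e.diagnosis,
                "defect_status": "defective" if dm.defective[p]
                                 else "non-defective",
                "coverage": cov,
            })
    tidy = pd.DataFrame(recs)
    cells = [("healthy", None), ("suspect", "non-defective"),
             ("suspect", "defective"), ("glaucoma", "non-defective"),
             ("glaucoma", "defective")]
    models: dict[str, SegmentedModel] = {}
    rows = []
    per_cell = []
    for stratum, status in cells:
        m = tidy.stratum == stratum
        if status is not None:
            m &= tidy.defect_status == status
        sub = tidy[m]
        name = stratum if status is None else f"{stratum}:{status}"
        if len(sub) < 20:
            log.warning("stratum %s has %d points; skipped", name, len(sub))
            continue
        fit = fit_segmented(SFDataset(sub.count_dB, sub.threshold_dB),
                            cfg.init_breakpoint_dB)
        models[name] = fit
        per_cell.append(fit)
        rows.append({"model": name, "n": fit.n, "intercept": fit.intercept,
                     "slope1": fit.slope1, "breakpoint": fit.breakpoint,
                     "slope2": fit.slope2, "adj_r2": fit.adj_r2,
                     "F_vs_linear": fit.f_stat, "p_vs_linear": fit.p_value,
                     "davies_p": fit.davies_p, "mae_dB": fit.mae_dB,
                     "rmse_dB": fit.rmse_dB})
    pooled = fit_segmented(SFDataset(tidy.count_dB, tidy.threshold_dB),
                           cfg.init_breakpoint_dB)
    models["pooled"] = pooled
    rows.append({"model": "pooled", "n": pooled.n,
                 "intercept": pooled.intercept, "slope1": pooled.slope1,
                 "breakpoint": pooled.breakpoint, "slope2": pooled.slope2,
                 "adj_r2": pooled.adj_r2, "F_vs_linear": pooled.f_stat,
                 "p_vs_linear": pooled.p_value, "davies_p": pooled.davies_p,
                 "mae_dB": pooled.mae_dB, "rmse_dB": pooled.rmse_dB})
    table = pd.DataFrame(rows)
    extra = {}
    if len(per_cell) == len(cells) and sum(f.n for f in per_cell) == pooled.n:
        f, p = compare_nested_f(per_cell, pooled)
        extra["F_cells_vs_pooled"] = f
        extra["p_cells_vs_pooled"] = p
    # pooled by defect status, and maximum model divergence among cells
    for status in ("non-defective", "defective"):
        sub = tidy[tidy.defect_status == status]
        if len(sub) >= 20:
            models[f"all:{status}"] = fit_segmented(
                SFDataset(sub.count_dB, sub.threshold_dB), cfg.init_breakpoint_dB)
    if len(per_cell) >= 2:
        extra["max_divergence_dB"] = max_model_divergence(
            per_cell, (tidy.count_dB.min(), tidy.count_dB.max()), step=0.01)
    return tidy, models, table, extra


def _stage_features(cohort: Cohort, cfg: PipelineConfig, normative,
                    assignment, hemi_labels):
    """Percentile flags, relative maps and hemi-cluster feature table."""
    frames = []
    for e in cohort.eyes:
        dev = percentile_flag_map(e.observed, e.biometry, normative,
                                  cfg.flag_percentile)
        feats = compute_features(e.observed, dev.relative_map, dev.flag_map,
                                 assignment)
        props = proportion_flagged(dev.flag_map, assignment, dev.available)
        for f in feats:
            f.flagged_proportion = props[f.cluster_id]
        df = features_frame(feats, e.eye_id)
        df["vf_label"] = [hemi_labels[e.eye_id][cid] for cid in df.cluster_id]
        df["diagnosis"] = e.diagnosis
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def _stage_classify(features: pd.DataFrame, cohort: Cohort, cfg: PipelineConfig):
    """Train PCA and cascade models on the ROCC cohort; score every eye."""
    rocc_rows = features[features.eye.isin(cohort.rocc_ids)]
    pca_models = {}
    score_rows = []
    for (hemi, group), sub in features.groupby(["hemifield", "group"],
                                               sort=False):
        train = rocc_rows[(rocc_rows.hemifield == hemi)
                          & (rocc_rows.group == group)]
        model = fit_pca_logistic(train, train.vf_label.to_numpy(),
                                 FEATURE_NAMES, alpha=cfg.alpha,
                                 allow_insignificant=True)
        pca_models[(hemi, group)] = model
        prob = model.predict_proba(sub)
        for (eye, lab, flg), p in zip(
                sub[["eye", "vf_label", "flagged_proportion"]].itertuples(
                    index=False), prob):
            score_rows.append({"eye": eye, "hemifield": hemi, "group": group,
                               "vf_label": bool(lab), "percentile": flg,
                               "pca": p})
    scores = pd.DataFrame(score_rows)
    cascade = fit_cascade(rocc_rows, alpha=cfg.alpha, allow_insignificant=True)
    casc_pred = predict(cascade, features)
    casc_pred = casc_pred.rename(columns={"probability": "cascade"})
    scores = scores.merge(casc_pred, on=["eye", "hemifield", "group"],
                          how="left")
    # the cascade is only defined beyond the central group
    scores.loc[scores.group == cascade.ordering[0], "cascade"] = np.nan
    return scores, pca_models, cascade


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None,
                 cohort: Cohort | None = None) -> PipelineResult:
    """Execute the configured stages on a synthetic (or provided) cohort."""
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        logging.basicConfig(level=logging.INFO)
        config.save(out_dir / "config.yaml")
    if cohort is None:
        log.info("simulating cohort (seed %d)", config.generator.seed)
        cohort = generate_cohort(config.generator)
    res = PipelineResult(config=config, cohort=cohort)

    vf_table, defect_maps, hemi_labels, assignment = _stage_vf(cohort, config)
    res.vf_table = vf_table
    if out_dir is not None and "vf" in config.stages:
        vf_table.to_csv(out_dir / "vf_classification.csv", index=False)
    if "sf" in config.stages:
        tidy, models, table, extra = _stage_sf(cohort, config, defect_maps)
        res.sf_models = models
        res.sf_table = table
        if out_dir is not None:
            tidy.to_csv(out_dir / "sf_observations.csv", index=False)
            table.to_csv(out_dir / "sf_models.csv", index=False)
            (out_dir / "sf_extra.json").write_text(json.dumps(extra))
    need_norm = {"normative", "features", "classify", "evaluate"} \
        & set(config.stages)
    if need_norm:
        ref_cfg = dataclasses.replace(
            config.generator, n_healthy=config.n_reference_eyes,
            n_suspect=0, n_glaucoma=0, seed=config.generator.seed + 1000,
            n_reference_vf=5)
        ref_cohort = generate_cohort(ref_cfg, density=cohort.density)
        res.normative = build_normative_db(
            [e.observed for e in ref_cohort.eyes],
            [e.biometry for e in ref_cohort.eyes])
    if {"features", "classify", "evaluate"} & set(config.stages):
        res.features = _stage_features(cohort, config, res.normative,
                                       assignment, hemi_labels)
        if out_dir is not None:
            res.features.to_csv(out_dir / "features.csv", index=False)
    if {"classify", "evaluate"} & set(config.stages):
        res.scores, res.pca_models, res.cascade = _stage_classify(
            res.features, cohort, config)
        if out_dir is not None:
            res.scores.to_csv(out_dir / "scores.csv", index=False)
            res.cascade.to_json(out_dir / "cascade_model.json")
    if "evaluate" in config.stages:
        split = CohortSplit(cohort.rocc_ids, cohort.test_ids)
        strata = {e.eye_id: e.diagnosis for e in cohort.eyes}
        rng = np.random.default_rng(config.seed + 7)
        res.report = select_method_and_report(
            res.scores, split, strata, alpha=config.alpha,
            ci_method=config.ci_method, n_boot=config.n_boot, rng=rng)
        if out_dir is not None:
            res.report.to_dir(out_dir)
    return res
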