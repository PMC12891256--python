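"""ROC analysis: AUC with DeLong variance, paired DeLong tests, Youden
thresholds, and sensitivity/specificity with participant-clustered bootstrap
confidence intervals.

AUC is the Mann-Whitney concordance with tie correction, its standard error
comes from the DeLong structural components, and correlated AUCs from two
scoring methods on the same cases are compared with the paired DeLong test.
Operating thresholds maximise Youden's J = sensitivity + specificity - 1 on
the ROC-construction ("ROCC") cohort only and are applied unchanged to the
held-out test cohort; a score >= threshold predicts "defective".

Because hemi-clusters within an eye are correlated, default confidence
intervals resample participants (nonparametric cluster bootstrap, percentile
method); the Wilson interval is the fallback for independent observations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "RocCurve", "CohortSplit", "EvalReport",
    "roc_and_auc", "delong_components", "delong_compare",
    "youden_threshold", "sens_spec_ci", "select_method_and_report",
    "plot_roc",
]


@dataclass
class RocCurve:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    one_minus_specificity: np.ndarray
    auc: float
    auc_se: float

    def youden(self) -> tuple[float, float, float]:
        return youden_threshold(self)


@dataclass
class CohortSplit:
    """Participant ids for the ROCC (threshold-deriving) and test cohorts."""

    rocc_ids: frozenset
    test_ids: frozenset

    def __post_init__(self):
        self.rocc_ids = frozenset(self.rocc_ids)
        self.test_ids = frozenset(self.test_ids)
        if self.rocc_ids & self.test_ids:
            raise ValueError("ROCC and test cohorts must be disjoint")


def _midrank(v: np.ndarray) -> np.ndarray:
    return stats.rankdata(v, method="average")


def delong_components(scores: np.ndarray, labels: np.ndarray):
    """DeLong structural components (V10, V01) and the AUC.

    ``labels`` are boolean (True = positive).  Ties contribute 1/2, so the
    AUC equals the tie-corrected Mann-Whitney concordance.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    if np.any(~np.isfinite(scores)):
        raise ValueError("scores must be finite")
    pos, neg = scores[labels], scores[~labels]
    m, n = pos.size, neg.size
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")
    all_ranks = _midrank(np.concatenate([pos, neg]))
    pos_ranks = _midrank(pos)
    neg_ranks = _midrank(neg)
    auc = (all_ranks[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    return auc, v10, v01


def roc_and_auc(scores, labels) -> RocCurve:
    """Empirical ROC over unique score thresholds with DeLong SE."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    auc, v10, v01 = delong_components(scores, labels)
    m, n = v10.size, v01.size
    var = np.var(v10, ddof=1) / m + np.var(v01, ddof=1) / n \
        if m > 1 and n > 1 else float("nan")
    thr = np.concatenate([[np.inf], np.unique(scores)[::-1]])
    sens = np.array([(scores[labels] >= t).mean() for t in thr])
    fpr = np.array([(scores[~labels] >= t).mean() for t in thr])
    return RocCurve(thresholds=thr, sensitivity=sens,
                    one_minus_specificity=fpr,
                    auc=float(auc), auc_se=float(np.sqrt(var)))


def delong_compare(scores_a, scores_b, labels) -> tuple[float, float]:
    """Two-sided paired DeLong test for the AUC difference of two methods."""
    scores_a = np.asarray(scores_a, float)
    scores_b = np.asarray(scores_b, float)
    labels = np.asarray(labels, bool)
    if scores_a.shape != scores_b.shape or scores_a.shape != labels.shape:
        raise ValueError("paired scores must cover identical cases")
    auc_a, v10_a, v01_a = delong_components(scores_a, labels)
    auc_b, v10_b, v01_b = delong_components(scores_b, labels)
    m, n = v10_a.size, v01_a.size
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1)
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1)
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1]
    if var_diff <= 0 or not np.isfinite(var_diff):
        if np.isclose(auc_a, auc_b):
            return 0.0, 1.0
        var_diff = 1e-300
    z = (auc_a - auc_b) / np.sqrt(var_diff)
    return float(z), float(2.0 * stats.norm.sf(abs(z)))


def youden_threshold(roc: RocCurve) -> tuple[float, float, float]:
    """(threshold, sensitivity, specificity) maximising sens + spec.

    Ties in Youden's J break toward higher specificity (a screening context
    prioritises avoiding false referrals).
    """
    spec = 1.0 - roc.one_minus_specificity
    j = roc.sensitivity + spec
    if np.ptp(j) == 0 and j.size <= 1:
        raise ValueError("degenerate ROC curve")
    best = np.flatnonzero(j == j.max())
    k = best[np.argmax(spec[best])]
    return float(roc.thresholds[k]), float(roc.sensitivity[k]), float(spec[k])


def sens_spec_ci(
    predictions,
    labels,
    participant_ids=None,
    method: str = "cluster-bootstrap",
    n_boot: int = 2000,
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
) -> dict:
    """Sensitivity/specificity point estimates with 95% CIs.

    ``cluster-bootstrap`` resamples participants with replacement (percentile
    intervals), respecting within-eye correlation of hemi-clusters;
    ``wilson`` treats observations as independent.
    """
    pred = np.asarray(predictions, bool)
    lab = np.asarray(labels, bool)
    if pred.shape != lab.shape:
        raise ValueError("predictions and labels must align")

    def point(p, l):
        npos, nneg = l.sum(), (~l).sum()
        se = (p & l).sum() / npos if npos else np.nan
        sp = (~p & ~l).sum() / nneg if nneg else np.nan
        return se, sp

    sens, spec = point(pred, lab)
    out = {"sensitivity": float(sens), "specificity": float(spec),
           "n_pos": int(lab.sum()), "n_neg": int((~lab).sum()),
           "ci_method": method}
    if method == "wilson":
        tp = int((pred & lab).sum())
        tn = int((~pred & ~lab).sum())
        if out["n_pos"]:
            lo, hi = proportion_confint(tp, out["n_pos"], alpha, method="wilson")
            out["sens_ci"] = (float(lo), float(hi))
        if out["n_neg"]:
            lo, hi = proportion_confint(tn, out["n_neg"], alpha, method="wilson")
            out["spec_ci"] = (float(lo), float(hi))
        return out
    if method != "cluster-bootstrap":
        raise ValueError(f"unknown CI method {method!r}")
    if participant_ids is None:
        raise ValueError("cluster-bootstrap requires participant ids")
    pid = np.asarray(participant_ids)
    if rng is None:
        rng = np.random.default_rng(0)
    uniq = np.unique(pid)
    groups = {u: np.flatnonzero(pid == u) for u in uniq}
    se_b = np.full(n_boot, np.nan)
    sp_b = np.full(n_boot, np.nan)
    for b in range(n_boot):
        take = rng.choice(uniq, size=uniq.size, replace=True)
        idx = np.concatenate([groups[u] for u in take])
        se_b[b], sp_b[b] = point(pred[idx], lab[idx])
    qs = (100 * alpha / 2, 100 * (1 - alpha / 2))
    if np.isfinite(se_b).any():
        out["sens_ci"] = tuple(float(v) for v in np.nanpercentile(se_b, qs))
    if np.isfinite(sp_b).any():
        out["spec_ci"] = tuple(float(v) for v in np.nanpercentile(sp_b, qs))
    return out


@dataclass
class EvalReport:
    """Per hemi-cluster evaluation: AUCs, method choice, operating points."""

    auc_table: pd.DataFrame
    operating_table: pd.DataFrame
    threshold_source: str = "rocc"

    def to_dir(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.auc_table.to_csv(out_dir / "auc_comparison.csv", index=False)
        self.operating_table.to_csv(out_dir / "operating_points.csv", index=False)
        bundle = {
            "threshold_source": self.threshold_source,
            "auc_table": self.auc_table.to_dict(orient="records"),
            "operating_table": self.operating_table.to_dict(orient="records"),
        }
        (out_dir / "eval_report.json").write_text(json.dumps(bundle, default=str))


def select_method_and_report(
    scores: pd.DataFrame,
    split: CohortSplit,
    strata: Mapping | None = None,
    alpha: float = 0.05,
    ci_method: str = "cluster-bootstrap",
    n_boot: int = 2000,
    rng: np.random.Generator | None = None,
) -> EvalReport:
    """Choose the simplest adequate method per hemi-cluster and evaluate it.

    ``scores`` is tidy with columns eye, hemifield, group, vf_label and the
    method score columns ``percentile``, ``pca`` and (where defined)
    ``cascade``.  The percentile method is kept unless PCA (or the cascade)
    has a significantly larger AUC on the ROCC cohort (paired DeLong,
    two-sided, unadjusted).  The Youden threshold is derived on the ROCC
    cohort alone and applied unchanged to the test cohort and to each
    diagnostic stratum (``strata``: participant id -> label).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    auc_rows, op_rows = [], []
    in_rocc = scores["eye"].isin(split.rocc_ids).to_numpy()
    for (hemi, group), sub in scores.groupby(["hemifield", "group"], sort=False):
        sub = sub.reset_index(drop=True)
        rocc = sub[sub.eye.isin(split.rocc_ids)]
        lab = rocc.vf_label.to_numpy(bool)
        methods = {"percentile": rocc.percentile.to_numpy(float)}
        if "pca" in sub.columns and np.isfinite(rocc.pca).all():
            methods["pca"] = rocc.pca.to_numpy(float)
        if "cascade" in sub.columns and np.isfinite(rocc.cascade).all():
            methods["cascade"] = rocc.cascade.to_numpy(float)
        aucs = {k: roc_and_auc(v, lab) for k, v in methods.items()}
        row = {"hemifield": hemi, "group": group,
               "auc_percentile": aucs["percentile"].auc,
               "se_percentile": aucs["percentile"].auc_se}
        chosen = "percentile"
        for alt in ("pca", "cascade"):
            if alt not in methods:
                continue
            z, p = delong_compare(methods[alt], methods["percentile"], lab)
            row[f"auc_{alt}"] = aucs[alt].auc
            row[f"se_{alt}"] = aucs[alt].auc_se
            row[f"p_{alt}_vs_percentile"] = p
            improves = aucs[alt].auc > aucs["percentile"].auc
            if p < alpha and improves:
                if chosen == "percentile" or aucs[alt].auc > aucs[chosen].auc:
                    chosen = alt
        row["chosen_method"] = chosen
        auc_rows.append(row)

        thr, _, _ = youden_threshold(aucs[chosen])
        all_scores = sub[chosen].to_numpy(float)
        pred = all_scores >= thr
        lab_all = sub.vf_label.to_numpy(bool)
        cohorts = {
            "rocc": sub.eye.isin(split.rocc_ids).to_numpy(),
            "test": sub.eye.isin(split.test_ids).to_numpy(),
        }
        if strata is not None:
            for name in sorted(set(strata.values())):
                cohorts[f"stratum:{name}"] = np.array(
                    [strata.get(e) == name for e in sub.eye])
        for cname, mask in cohorts.items():
            if mask.sum() == 0:
                continue
            res = sens_spec_ci(pred[mask], lab_all[mask],
                               sub.eye.to_numpy()[mask],
                               method=ci_method, n_boot=n_boot, rng=rng)
            op_rows.append({"hemifield": hemi, "group": group,
                            "cohort": cname, "method": chosen,
                            "threshold": thr, **{
                                k: v for k, v in res.items()}})
    return EvalReport(auc_table=pd.DataFrame(auc_rows),
                      operating_table=pd.DataFrame(op_rows))


def plot_roc(curves: Mapping[str, RocCurve], path: str | Path,
             title: str = "") -> None:
    """Save a basic ROC plot (one curve per labelled method)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(4, 4))
    for name, c in curves.items():
        ax.plot(c.one_minus_specificity, c.sensitivity,
                label=f"{name} (AUC {c.auc:.2f})")
    ax.plot([0, 1], [0, 1], "r:", lw=1)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.set_title(title)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
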