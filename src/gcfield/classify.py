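"""Hemi-cluster GCIPL features and the PCA + logistic classification cascade.

Five thickness parameters summarise each hemi-cluster: mean and standard
deviation of GCIPL thickness, asymmetry (this hemi-cluster's mean minus the
mirror hemi-cluster's mean in the opposite hemifield), and the mean and
asymmetry of the relative ("pattern-deviation"-style) thickness.  The
percentile method's flagged proportion is carried alongside as its own
classifier score.

Classification condenses the (backward-eliminated) parameters into principal
components and fits a logistic regression on the component scores.  The
cascaded "PCA plus central" variant trains hemi-clusters from the centre
outward, offering each model the adjacent more-central model's predicted
probability as an extra candidate parameter subject to the same elimination.

Backward elimination interprets "repeated until all parameters were
significant" as: fit a multiple logistic regression on the standardised raw
parameters, drop the least significant parameter while its Wald p >= alpha,
and refit.  Significance of a raw parameter inside a PC regression is
ill-defined, so this interpretation is applied to the raw parameters before
the PCA step.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .mapping import GROUP_ORDER, ClusterAssignment, ThicknessMap

__all__ = [
    "FEATURE_NAMES", "HemiClusterFeatures",
    "PCALogisticModel", "CascadeModel", "EliminationError",
    "compute_features", "fit_pca_logistic", "fit_cascade", "predict",
    "firth_logistic",
]

FEATURE_NAMES = (
    "mean_um", "sd_um", "asymmetry_um",
    "mean_relative_um", "asymmetry_relative_um",
)
CENTRAL_PREDICTION = "central_prediction"


class EliminationError(ValueError):
    """Raised when backward elimination would remove every parameter."""


@dataclass
class HemiClusterFeatures:
    """The five GCIPL features (plus percentile score) for one hemi-cluster."""

    cluster_id: int
    group: str
    hemifield: str
    mean_um: float
    sd_um: float
    asymmetry_um: float
    mean_relative_um: float
    asymmetry_relative_um: float
    flagged_proportion: float = float("nan")
    central_prediction: float = float("nan")


# ---------------------------------------------------------------------------
# feature computation
# ---------------------------------------------------------------------------

def _agg(vals: np.ndarray) -> tuple[float, float]:
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        return float("nan"), float("nan")
    return float(vals.mean()), float(vals.std(ddof=0))


def compute_features(
    tmap: ThicknessMap,
    relative_map: np.ndarray,
    flags: np.ndarray | None,
    assignment: ClusterAssignment,
    mode: str = "hemicluster",
    regions: Mapping | None = None,
) -> list[HemiClusterFeatures]:
    """Compute per-hemi-cluster features on the common lattice.

    ``mode`` is one of ``hemicluster`` (aggregate over all grid squares of the
    hemi-cluster), ``stimulus-only`` (restrict to squares inside the
    hemi-cluster's projected stimulus regions; requires ``regions`` mapping
    VF locations to boolean lattice masks) or ``pointwise`` (alias of
    stimulus-only with single-square regions).
    """
    if mode not in ("hemicluster", "stimulus-only", "pointwise"):
        raise ValueError(f"unknown mode {mode!r}")
    valid = tmap.valid_mask
    sel_cache: dict[int, np.ndarray] = {}
    for cid in assignment.legend:
        sel = (assignment.grid_labels == cid) & valid
        if mode != "hemicluster":
            if regions is None:
                raise ValueError(f"mode {mode!r} requires stimulus region masks")
            stim = np.zeros_like(sel)
            for loc, m in regions.items():
                if assignment.vf_labels.get(loc) == cid:
                    stim |= np.asarray(m, bool)
            sel &= stim
        sel_cache[cid] = sel

    out = []
    for cid, (group, hemi) in assignment.legend.items():
        sel = sel_cache[cid]
        mir = sel_cache[assignment.mirror_id(cid)]
        mean, sd = _agg(tmap.values[sel])
        mean_mir, _ = _agg(tmap.values[mir])
        mean_rel, _ = _agg(relative_map[sel])
        mean_rel_mir, _ = _agg(relative_map[mir])
        prop = float("nan")
        if flags is not None and sel.sum():
            prop = float(flags[sel].sum()) / int(sel.sum())
        out.append(HemiClusterFeatures(
            cluster_id=cid, group=group, hemifield=hemi,
            mean_um=mean, sd_um=sd, asymmetry_um=mean - mean_mir,
            mean_relative_um=mean_rel,
            asymmetry_relative_um=mean_rel - mean_rel_mir,
            flagged_proportion=prop,
        ))
    return out


def features_frame(rows: Sequence[HemiClusterFeatures], eye_id: str,
                   vf_label: bool | None = None) -> pd.DataFrame:
    """Tidy one eye's features into DataFrame rows."""
    recs = []
    for r in rows:
        rec = {"eye": eye_id, "cluster_id": r.cluster_id, "group": r.group,
               "hemifield": r.hemifield}
        for name in FEATURE_NAMES:
            rec[name] = getattr(r, name)
        rec["flagged_proportion"] = r.flagged_proportion
        if vf_label is not None:
            rec["vf_label"] = bool(vf_label)
        recs.append(rec)
    return pd.DataFrame(recs)


# ---------------------------------------------------------------------------
# logistic fitting (ML with a Firth-penalised fallback)
# ---------------------------------------------------------------------------

def firth_logistic(X: np.ndarray, y: np.ndarray, max_iter: int = 200,
                   tol: float = 1e-8) -> tuple[np.ndarray, np.ndarray]:
    """Jeffreys-prior (Firth) penalised logistic regression.

    Returns (coefficients, standard errors) for a design X that already
    includes the intercept column.  Used when plain maximum likelihood fails
    to converge, typically under complete separation.
    """
    n, p = X.shape
    beta = np.zeros(p)
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        XtWX = X.T @ (X * w[:, None])
        try:
            info_inv = np.linalg.inv(XtWX)
        except np.linalg.LinAlgError:
            info_inv = np.linalg.pinv(XtWX)
        # hat diagonal of W^(1/2) X (X'WX)^-1 X' W^(1/2)
        h = np.einsum("ij,jk,ik->i", X * w[:, None], info_inv, X)
        score = X.T @ (y - mu + h * (0.5 - mu))
        step = info_inv @ score
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    se = np.sqrt(np.diag(info_inv))
    return beta, se


def _fit_logit(X: np.ndarray, y: np.ndarray):
    """(coef, se, used_firth): ML logistic with Firth fallback."""
    Xc = sm.add_constant(X, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
            if res.mle_retvals.get("converged", False) and \
                    np.all(np.isfinite(res.bse)) and np.max(np.abs(res.params)) < 30:
                return np.asarray(res.params), np.asarray(res.bse), False
        except Exception:
            pass
    coef, se = firth_logistic(Xc, y.astype(float))
    return coef, se, True


def _wald_p(coef: np.ndarray, se: np.ndarray) -> np.ndarray:
    from scipy import stats
    z = coef / np.where(se > 0, se, np.inf)
    return 2.0 * stats.norm.sf(np.abs(z))


@dataclass
class PCALogisticModel:
    """Standardisation + PCA + logistic classifier for one hemi-cluster."""

    retained_parameters: list[str]
    feature_mean: np.ndarray
    feature_scale: np.ndarray
    eigenvectors: np.ndarray       # columns are retained PCs
    eigenvalues: np.ndarray
    logit_coef: np.ndarray         # [intercept, per-PC coefficients]
    used_firth: bool = False
    eliminated: list[str] = field(default_factory=list)
    n_train: int = 0

    def transform(self, F: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.retained_parameters if c not in F.columns]
        if missing:
            raise KeyError(f"missing retained feature(s) {missing}")
        Z = (F[self.retained_parameters].to_numpy(float) - self.feature_mean) \
            / self.feature_scale
        return Z @ self.eigenvectors

    def predict_proba(self, F: pd.DataFrame) -> np.ndarray:
        scores = self.transform(F)
        eta = self.logit_coef[0] + scores @ self.logit_coef[1:]
        out = 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))
        bad = ~np.isfinite(F[self.retained_parameters].to_numpy(float)).all(axis=1)
        out[bad] = np.nan
        return out

    def to_dict(self) -> dict:
        return {
            "retained_parameters": self.retained_parameters,
            "feature_mean": self.feature_mean.tolist(),
            "feature_scale": self.feature_scale.tolist(),
            "eigenvectors": self.eigenvectors.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "logit_coef": self.logit_coef.tolist(),
            "used_firth": self.used_firth,
            "eliminated": self.eliminated,
            "n_train": self.n_train,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PCALogisticModel":
        return cls(
            retained_parameters=list(d["retained_parameters"]),
            feature_mean=np.asarray(d["feature_mean"], float),
            feature_scale=np.asarray(d["feature_scale"], float),
            eigenvectors=np.asarray(d["eigenvectors"], float),
            eigenvalues=np.asarray(d["eigenvalues"], float),
            logit_coef=np.asarray(d["logit_coef"], float),
            used_firth=bool(d["used_firth"]),
            eliminated=list(d["eliminated"]),
            n_train=int(d["n_train"]),
        )


def fit_pca_logistic(
    features: pd.DataFrame,
    labels: np.ndarray,
    candidate_parameters: Sequence[str] = FEATURE_NAMES,
    alpha: float = 0.05,
    retention: str = "kaiser",
    allow_insignificant: bool = False,
) -> PCALogisticModel:
    """Backward-eliminate parameters, then PCA, then logistic on PC scores.

    Elimination drops the least significant standardised parameter while its
    Wald p >= alpha.  If the last surviving parameter is itself
    non-significant an :class:`EliminationError` is raised unless
    ``allow_insignificant`` keeps it (with a warning) for pipeline use.
    PC retention follows the Kaiser rule (eigenvalue > 1 of the correlation
    matrix), always keeping at least one component.
    """
    y = np.asarray(labels).astype(float)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    if len(features) < 20:
        raise ValueError("need at least 20 rows to train")
    current = [c for c in candidate_parameters if c in features.columns]
    if not current:
        raise ValueError("no candidate parameters present in the feature table")
    X_all = features[current].to_numpy(float)
    keep_rows = np.isfinite(X_all).all(axis=1) & np.isfinite(y)
    Xf = X_all[keep_rows]
    yf = y[keep_rows]

    mean = Xf.mean(axis=0)
    scale = Xf.std(axis=0, ddof=0)
    scale[scale == 0] = 1.0
    Z = (Xf - mean) / scale

    eliminated: list[str] = []
    idx = list(range(len(current)))
    used_firth = False
    while True:
        coef, se, firth = _fit_logit(Z[:, idx], yf)
        used_firth |= firth
        p = _wald_p(coef[1:], se[1:])
        worst = int(np.argmax(p))
        if p[worst] < alpha:
            break
        if len(idx) == 1:
            if allow_insignificant:
                warnings.warn("last parameter is non-significant; kept")
                break
            raise EliminationError(
                "backward elimination removed every parameter "
                f"(last p = {p[worst]:.3f} for {current[idx[0]]!r})")
        eliminated.append(current[idx[worst]])
        idx.pop(worst)
    retained = [current[i] for i in idx]
    Zr = Z[:, idx]
    mean_r, scale_r = mean[idx], scale[idx]

    corr = np.corrcoef(Zr, rowvar=False)
    corr = np.atleast_2d(corr)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    # deterministic sign: largest-magnitude loading positive
    for j in range(evecs.shape[1]):
        k = np.argmax(np.abs(evecs[:, j]))
        if evecs[k, j] < 0:
            evecs[:, j] *= -1
    if retention == "kaiser":
        n_keep = max(1, int(np.sum(evals > 1.0)))
    elif retention == "all":
        n_keep = len(evals)
    else:
        raise ValueError(f"unknown retention rule {retention!r}")
    evecs_k = evecs[:, :n_keep]
    scores = Zr @ evecs_k
    coef, se, firth = _fit_logit(scores, yf)
    used_firth |= firth
    if firth:
        warnings.warn("logistic on PC scores used the Firth-penalised fallback")
    return PCALogisticModel(
        retained_parameters=retained,
        feature_mean=mean_r, feature_scale=scale_r,
        eigenvectors=evecs_k, eigenvalues=evals[:n_keep],
        logit_coef=coef, used_firth=used_firth,
        eliminated=eliminated, n_train=int(keep_rows.sum()),
    )


# ---------------------------------------------------------------------------
# cascade: central -> peripheral, feeding predictions outward
# ---------------------------------------------------------------------------

@dataclass
class CascadeModel:
    """Per-hemifield chains of PCA+logistic models, central to peripheral."""

    models: dict[tuple[str, str], PCALogisticModel]   # (hemifield, group)
    ordering: tuple[str, ...] = GROUP_ORDER

    def to_json(self, path: str | Path) -> None:
        d = {
            "ordering": list(self.ordering),
            "models": {f"{h}|{g}": m.to_dict() for (h, g), m in self.models.items()},
        }
        Path(path).write_text(json.dumps(d))

    @classmethod
    def from_json(cls, path: str | Path) -> "CascadeModel":
        d = json.loads(Path(path).read_text())
        models = {}
        for key, md in d["models"].items():
            h, g = key.split("|")
            models[(h, g)] = PCALogisticModel.from_dict(md)
        return cls(models=models, ordering=tuple(d["ordering"]))


def fit_cascade(
    features: pd.DataFrame,
    ordering: Sequence[str] = GROUP_ORDER,
    candidate_parameters: Sequence[str] = FEATURE_NAMES,
    alpha: float = 0.05,
    allow_insignificant: bool = True,
    pass_probabilities: bool = True,
) -> CascadeModel:
    """Train the "PCA plus central" cascade on a tidy feature table.

    ``features`` needs columns eye, hemifield, group, the candidate
    parameters and ``vf_label``.  Groups are trained in ``ordering``
    (central first); each non-central model receives the immediately more
    central group's in-sample predicted probability (or hard class when
    ``pass_probabilities`` is False) as the ``central_prediction`` candidate.
    """
    if list(ordering) != list(dict.fromkeys(ordering)):
        raise ValueError("ordering contains repeated groups")
    models: dict[tuple[str, str], PCALogisticModel] = {}
    for hemi in sorted(features["hemifield"].unique()):
        prev_pred: pd.Series | None = None
        for gi, group in enumerate(ordering):
            sub = features[(features.hemifield == hemi) & (features.group == group)]
            if sub.empty:
                raise ValueError(f"no rows for hemifield {hemi!r} group {group!r}")
            sub = sub.set_index("eye")
            cands = list(candidate_parameters)
            if gi > 0 and prev_pred is not None:
                sub = sub.copy()
                pred = prev_pred.reindex(sub.index)
                if not pass_probabilities:
                    pred = (pred >= 0.5).astype(float)
                sub[CENTRAL_PREDICTION] = pred
                cands.append(CENTRAL_PREDICTION)
            model = fit_pca_logistic(
                sub, sub["vf_label"].to_numpy(), cands,
                alpha=alpha, allow_insignificant=allow_insignificant)
            models[(hemi, group)] = model
            prev_pred = pd.Series(model.predict_proba(sub), index=sub.index)
    return CascadeModel(models=models, ordering=tuple(ordering))


def predict(
    model: PCALogisticModel | CascadeModel,
    features: pd.DataFrame,
    pass_probabilities: bool = True,
) -> pd.Series | pd.DataFrame:
    """Probability of VF-defective status per row (or per eye x hemi-cluster).

    For a single :class:`PCALogisticModel` a Series aligned to ``features``
    is returned.  For a :class:`CascadeModel` the feature table must be tidy
    (eye / hemifield / group columns); evaluation proceeds central to
    peripheral so each model can consume the upstream prediction.
    """
    if isinstance(model, PCALogisticModel):
        return pd.Series(model.predict_proba(features), index=features.index)
    out_rows = []
    for hemi in sorted(features["hemifield"].unique()):
        prev_pred = None
        for gi, group in enumerate(model.ordering):
            key = (hemi, group)
            if key not in model.models:
                continue
            sub = features[(features.hemifield == hemi) & (features.group == group)]
            sub = sub.set_index("eye")
            m = model.models[key]
            if CENTRAL_PREDICTION in m.retained_parameters:
                sub = sub.copy()
                pred = prev_pred.reindex(sub.index)
                if not pass_probabilities:
                    pred = (pred >= 0.5).astype(float)
                sub[CENTRAL_PREDICTION] = pred
            prob = m.predict_proba(sub)
            prev_pred = pd.Series(prob, index=sub.index)
            for eye, p in prev_pred.items():
                out_rows.append({"eye": eye, "hemifield": hemi,
                                 "group": group, "probability": p})
    return pd.DataFrame(out_rows)
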