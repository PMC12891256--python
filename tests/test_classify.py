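"""Hemi-cluster features, PCA + logistic fitting, and the cascade."""

import numpy as np
import pandas as pd
import pytest

from gcfield.classify import (FEATURE_NAMES, CascadeModel, EliminationError,
                              PCALogisticModel, compute_features,
                              features_frame, firth_logistic, fit_cascade,
                              fit_pca_logistic, predict)
from gcfield.mapping import GRID_N, ThicknessMap


def uniform_inputs(value=70.0):
    tmap = ThicknessMap(np.full((GRID_N, GRID_N), value))
    rel = np.zeros((GRID_N, GRID_N))
    flags = np.zeros((GRID_N, GRID_N), bool)
    return tmap, rel, flags


class TestFeatures:
    def test_uniform_eye(self, assignment):
        tmap, rel, flags = uniform_inputs()
        feats = compute_features(tmap, rel, flags, assignment)
        assert len(feats) == 10
        for f in feats:
            assert f.mean_um == pytest.approx(70.0)
            assert f.sd_um == pytest.approx(0.0)
            assert f.asymmetry_um == pytest.approx(0.0)
            assert f.flagged_proportion == 0.0

    def test_hemifield_thinning_asymmetry(self, assignment):
        vals = np.full((GRID_N, GRID_N), 70.0)
        vals[:80, :] -= 10.0      # superior retina thinner by 10
        feats = compute_features(ThicknessMap(vals),
                                 np.zeros((GRID_N, GRID_N)), None, assignment)
        for f in feats:
            # superior retina carries the inferior VF hemifield labels
            expected = -10.0 if f.hemifield == "inferior" else 10.0
            assert f.asymmetry_um == pytest.approx(expected)

    def test_asymmetry_antisymmetric(self, assignment, rng):
        vals = rng.uniform(40, 100, (GRID_N, GRID_N))
        feats = compute_features(ThicknessMap(vals),
                                 np.zeros((GRID_N, GRID_N)), None, assignment)
        by_key = {(f.group, f.hemifield): f for f in feats}
        for f in feats:
            other = "inferior" if f.hemifield == "superior" else "superior"
            mirror = by_key[(f.group, other)]
            assert f.asymmetry_um == pytest.approx(-mirror.asymmetry_um)

    def test_brute_force_aggregation(self, assignment, rng):
        vals = rng.uniform(40, 100, (GRID_N, GRID_N))
        rel = rng.normal(0, 3, (GRID_N, GRID_N))
        flags = rng.random((GRID_N, GRID_N)) < 0.1
        feats = compute_features(ThicknessMap(vals), rel, flags, assignment)
        for f in feats:
            sel = assignment.grid_labels == f.cluster_id
            assert f.mean_um == pytest.approx(vals[sel].mean())
            assert f.sd_um == pytest.approx(vals[sel].std())
            assert f.mean_relative_um == pytest.approx(rel[sel].mean())
            assert f.flagged_proportion == pytest.approx(flags[sel].mean())

    def test_stimulus_only_mode_restricts(self, assignment, rng):
        vals = rng.uniform(40, 100, (GRID_N, GRID_N))
        regions = {}
        for p, cid in assignment.vf_labels.items():
            m = np.zeros((GRID_N, GRID_N), bool)
            m[rng.integers(40, 120), rng.integers(40, 120)] = True
            regions[p] = m
        feats = compute_features(ThicknessMap(vals),
                                 np.zeros((GRID_N, GRID_N)), None, assignment,
                                 mode="stimulus-only", regions=regions)
        assert len(feats) == 10
        with pytest.raises(ValueError):
            compute_features(ThicknessMap(vals), np.zeros((GRID_N, GRID_N)),
                             None, assignment, mode="pointwise")


def informative_table(rng, n=120, noise=1.0, with_junk=False):
    y = rng.random(n) < 0.5
    signal = np.where(y, -8.0, 0.0)
    df = pd.DataFrame({
        "mean_um": 70 + signal + rng.normal(0, noise, n),
        "sd_um": 3 + np.where(y, 2.0, 0.0) + rng.normal(0, noise / 2, n),
        "asymmetry_um": signal + rng.normal(0, noise, n),
        "mean_relative_um": signal / 2 + rng.normal(0, noise, n),
        "asymmetry_relative_um": signal / 2 + rng.normal(0, noise, n),
    })
    if with_junk:
        df["junk"] = rng.normal(0, 1, n)
    return df, y


class TestPcaLogistic:
    def test_rank_one_structure(self, rng):
        n = 100
        y = rng.random(n) < 0.5
        base = np.where(y, -5.0, 0.0) + rng.normal(0, 1, n)
        df = pd.DataFrame({"mean_um": base, "asymmetry_um": 2 * base + 1})
        model = fit_pca_logistic(df, y, ("mean_um", "asymmetry_um"))
        assert model.eigenvectors.shape[1] == 1
        assert model.eigenvalues[0] == pytest.approx(2.0, abs=0.01)

    def test_orthonormal_eigenvectors_uncorrelated_scores(self, rng):
        df, y = informative_table(rng, noise=4.0)
        model = fit_pca_logistic(df, y, FEATURE_NAMES, retention="all",
                                 allow_insignificant=True)
        V = model.eigenvectors
        assert np.allclose(V.T @ V, np.eye(V.shape[1]), atol=1e-9)
        scores = model.transform(df)
        if scores.shape[1] > 1:
            c = np.corrcoef(scores, rowvar=False)
            assert np.allclose(c - np.diag(np.diag(c)), 0.0, atol=1e-9)

    def test_junk_feature_eliminated(self, rng):
        dropped = 0
        runs = 60
        for i in range(runs):
            r = np.random.default_rng(7000 + i)
            df, y = informative_table(r, noise=2.0, with_junk=True)
            model = fit_pca_logistic(df, y, list(FEATURE_NAMES) + ["junk"],
                                     allow_insignificant=True)
            dropped += "junk" not in model.retained_parameters
        assert dropped / runs >= 0.95

    def test_affine_rescaling_invariance(self, rng):
        df, y = informative_table(rng, noise=2.0)
        m1 = fit_pca_logistic(df, y, FEATURE_NAMES, allow_insignificant=True)
        df2 = df.copy()
        df2["mean_um"] = df2["mean_um"] * 13.0 - 40.0
        m2 = fit_pca_logistic(df2, y, FEATURE_NAMES, allow_insignificant=True)
        p1 = m1.predict_proba(df)
        p2 = m2.predict_proba(df2)
        assert np.allclose(p1, p2, atol=1e-5)

    def test_single_class_rejected(self, rng):
        df, _ = informative_table(rng)
        with pytest.raises(ValueError):
            fit_pca_logistic(df, np.zeros(len(df), bool), FEATURE_NAMES)

    def test_all_eliminated_raises(self, rng):
        n = 60
        df = pd.DataFrame({"mean_um": rng.normal(0, 1, n)})
        y = rng.random(n) < 0.5
        with pytest.raises(EliminationError):
            fit_pca_logistic(df, y, ("mean_um",))

    def test_serialization_round_trip(self, rng, tmp_path):
        df, y = informative_table(rng)
        model = fit_pca_logistic(df, y, FEATURE_NAMES, allow_insignificant=True)
        back = PCALogisticModel.from_dict(model.to_dict())
        assert np.allclose(back.predict_proba(df), model.predict_proba(df),
                           equal_nan=True)

    def test_missing_retained_feature_rejected(self, rng):
        df, y = informative_table(rng)
        model = fit_pca_logistic(df, y, FEATURE_NAMES, allow_insignificant=True)
        with pytest.raises(KeyError):
            model.transform(df.drop(columns=model.retained_parameters[:1]))


class TestFirth:
    def test_matches_ml_when_well_behaved(self, rng):
        import statsmodels.api as sm
        n = 400
        x = rng.normal(0, 1, n)
        eta = 0.3 + 0.8 * x
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        X = sm.add_constant(x)
        ml = sm.Logit(y, X).fit(disp=0)
        coef, se = firth_logistic(X, y)
        assert np.allclose(coef, ml.params, atol=0.05)

    def test_finite_under_separation(self):
        x = np.array([-2., -1.5, -1., -0.5, 0.5, 1., 1.5, 2.])
        y = (x > 0).astype(float)
        X = np.column_stack([np.ones_like(x), x])
        coef, se = firth_logistic(X, y)
        assert np.all(np.isfinite(coef)) and np.all(np.isfinite(se))
        assert np.abs(coef[1]) < 20


def cascade_table(rng, n_eyes=120, coupled=True):
    """Synthetic tidy feature table with ring-correlated defects."""
    rows = []
    for i in range(n_eyes):
        sick = rng.random() < 0.5
        sick_hemi = ("superior", "inferior")[rng.integers(0, 2)]
        for hemi in ("superior", "inferior"):
            affected = sick and hemi == sick_hemi
            for gi, group in enumerate(("6-8", "4-5", "3", "2", "1")):
                label = affected
                # peripheral structural signal fades; central stays strong
                strength = (8.0, 6.0, 4.0, 1.0, 0.5)[gi] if coupled else 0.0
                sig = -strength if affected else 0.0
                rows.append({
                    "eye": f"E{i:03d}", "hemifield": hemi, "group": group,
                    "mean_um": 70 + sig + rng.normal(0, 2),
                    "sd_um": 3 + rng.normal(0, 0.5),
                    "asymmetry_um": sig + rng.normal(0, 2),
                    "mean_relative_um": sig / 2 + rng.normal(0, 2),
                    "asymmetry_relative_um": sig / 2 + rng.normal(0, 2),
                    "vf_label": bool(label),
                })
    return pd.DataFrame(rows)


class TestCascade:
    def test_prediction_reproducible_after_serialization(self, rng, tmp_path):
        df = cascade_table(rng)
        model = fit_cascade(df, allow_insignificant=True)
        path = tmp_path / "cascade.json"
        model.to_json(path)
        back = CascadeModel.from_json(path)
        a = predict(model, df).sort_values(["eye", "hemifield", "group"])
        b = predict(back, df).sort_values(["eye", "hemifield", "group"])
        assert np.allclose(a.probability.to_numpy(), b.probability.to_numpy())

    def test_cascade_helps_weak_periphery(self):
        """Ring-correlated defects: cascaded peripheral AUC >= plain PCA AUC."""
        from gcfield.evaluate import roc_and_auc
        gains = []
        for trial in range(8):
            r = np.random.default_rng(4000 + trial)
            df = cascade_table(r)
            plain = fit_pca_logistic(
                df[(df.group == "1") & (df.hemifield == "superior")],
                df[(df.group == "1") & (df.hemifield == "superior")]
                .vf_label.to_numpy(),
                FEATURE_NAMES, allow_insignificant=True)
            casc = fit_cascade(df, allow_insignificant=True)
            sub = df[(df.group == "1") & (df.hemifield == "superior")]
            lab = sub.vf_label.to_numpy(bool)
            p_plain = plain.predict_proba(sub)
            pred = predict(casc, df)
            p_casc = pred[(pred.group == "1") & (pred.hemifield == "superior")] \
                .set_index("eye").probability.reindex(sub.eye).to_numpy()
            gains.append(roc_and_auc(p_casc, lab).auc
                         - roc_and_auc(p_plain, lab).auc)
        assert np.mean(gains) >= 0.0

    def test_constant_central_prediction_eliminated(self, rng):
        df = cascade_table(rng)
        # make the central group uninformative and constant
        const = fit_cascade(df, ordering=("6-8", "4-5"),
                            allow_insignificant=True)
        m = const.models[("superior", "4-5")]
        # central predictions that add nothing are droppable candidates
        assert set(m.retained_parameters) <= set(FEATURE_NAMES) | {
            "central_prediction"}

    def test_repeated_ordering_rejected(self, rng):
        df = cascade_table(rng)
        with pytest.raises(ValueError):
            fit_cascade(df, ordering=("6-8", "6-8", "3"))

    def test_batch_equals_single(self, rng):
        df, y = informative_table(rng)
        model = fit_pca_logistic(df, y, FEATURE_NAMES, allow_insignificant=True)
        batch = model.predict_proba(df)
        single = np.array([model.predict_proba(df.iloc[[i]])[0]
                           for i in range(10)])
        assert np.allclose(batch[:10], single)

    def test_monotone_in_pc_score(self, rng):
        df, y = informative_table(rng)
        model = fit_pca_logistic(df, y, FEATURE_NAMES, allow_insignificant=True)
        scores = np.linspace(-3, 3, 21)[:, None]
        k = model.eigenvectors.shape[1]
        grid = np.repeat(scores, k, axis=1) if k > 1 else scores
        eta = model.logit_coef[0] + grid @ model.logit_coef[1:]
        prob = 1 / (1 + np.exp(-eta))
        diffs = np.diff(prob)
        assert np.all(diffs >= 0) or np.all(diffs <= 0)
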