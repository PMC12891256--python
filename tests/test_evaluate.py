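"""ROC/AUC with DeLong machinery, Youden thresholds and clustered CIs."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from gcfield.evaluate import (CohortSplit, delong_compare, roc_and_auc,
                              select_method_and_report, sens_spec_ci,
                              youden_threshold)


def brute_auc(scores, labels):
    pos, neg = scores[labels], scores[~labels]
    return float(np.mean((pos[:, None] > neg[None, :])
                         + 0.5 * (pos[:, None] == neg[None, :])))


class TestAuc:
    def test_perfect_separation(self):
        roc = roc_and_auc([0.9, 0.8, 0.1, 0.2], [True, True, False, False])
        assert roc.auc == 1.0

    def test_all_ties(self):
        roc = roc_and_auc([0.5] * 10, [True] * 5 + [False] * 5)
        assert roc.auc == 0.5

    def test_worked_example(self):
        roc = roc_and_auc([0.8, 0.4, 0.6, 0.2], [True, True, False, False])
        assert roc.auc == 0.75      # 3 of 4 pairs concordant

    def test_matches_brute_force_concordance(self, rng):
        for n in (10, 57, 200, 500):
            scores = np.round(rng.normal(0, 1, n), 1)   # force ties
            labels = rng.random(n) < 0.4
            if labels.all() or not labels.any():
                continue
            roc = roc_and_auc(scores, labels)
            assert roc.auc == pytest.approx(brute_auc(scores, labels),
                                            abs=1e-12)

    def test_curve_monotone(self, rng):
        scores = rng.normal(0, 1, 100)
        labels = rng.random(100) < 0.5
        roc = roc_and_auc(scores, labels)
        assert np.all(np.diff(roc.sensitivity) >= 0)
        assert np.all(np.diff(roc.one_minus_specificity) >= 0)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            roc_and_auc([0.1, 0.2], [True, True])


class TestDeLong:
    def test_self_comparison(self, rng):
        s = rng.normal(0, 1, 60)
        lab = rng.random(60) < 0.5
        z, p = delong_compare(s, s, lab)
        assert z == 0.0 and p == 1.0

    def test_rank_invariance(self, rng):
        s = rng.normal(0, 1, 80)
        lab = rng.random(80) < 0.5
        z, p = delong_compare(s, np.exp(s) * 3, lab)
        assert p == pytest.approx(1.0)

    def test_variance_close_to_bootstrap(self):
        rng = np.random.default_rng(5)
        n = 200
        lab = np.zeros(n, bool)
        lab[:80] = True
        sc = np.where(lab, rng.normal(1.0, 1, n), rng.normal(0, 1, n))
        roc = roc_and_auc(sc, lab)
        boot = np.empty(2000)
        for b in range(2000):
            idx = rng.integers(0, n, n)
            l, s = lab[idx], sc[idx]
            if l.all() or not l.any():
                boot[b] = np.nan
                continue
            r = rankdata(s)
            m = l.sum()
            boot[b] = (r[l].sum() - m * (m + 1) / 2) / (m * (n - m))
        ratio = roc.auc_se ** 2 / np.nanvar(boot, ddof=1)
        assert 0.8 < ratio < 1.2

    def test_unpaired_rejected(self, rng):
        with pytest.raises(ValueError):
            delong_compare(np.ones(5), np.ones(6), np.ones(5, bool))


class TestYouden:
    def test_perfect_classifier(self):
        roc = roc_and_auc([0.9, 0.8, 0.1, 0.2], [True, True, False, False])
        thr, sens, spec = youden_threshold(roc)
        assert sens == 1.0 and spec == 1.0

    def test_matches_exhaustive_scan(self, rng):
        scores = rng.normal(0, 1, 150)
        labels = np.concatenate([rng.normal(0.8, 1, 70) > 0.2,
                                 np.zeros(80, bool)])
        rng.shuffle(labels)
        roc = roc_and_auc(scores, labels)
        thr, sens, spec = youden_threshold(roc)
        best_j = -np.inf
        for t in np.concatenate([[np.inf], np.unique(scores)]):
            pred = scores >= t
            se = (pred & labels).sum() / labels.sum()
            sp = (~pred & ~labels).sum() / (~labels).sum()
            best_j = max(best_j, se + sp)
        assert sens + spec == pytest.approx(best_j, abs=1e-12)

    def test_useless_classifier(self, rng):
        scores = np.round(rng.random(400), 2)
        labels = rng.random(400) < 0.5
        roc = roc_and_auc(scores, labels)
        thr, sens, spec = youden_threshold(roc)
        assert sens + spec - 1 == pytest.approx(0.0, abs=0.15)

    def test_tie_breaks_toward_specificity(self):
        # two thresholds achieve J = 0.5: prefer the more specific one
        roc = roc_and_auc([3.0, 2.0, 2.5, 1.0],
                          [True, True, False, False])
        thr, sens, spec = youden_threshold(roc)
        assert spec == 1.0


class TestSensSpecCI:
    def test_hand_arithmetic(self):
        pred = np.array([True] * 9 + [False] + [False] * 8 + [True] * 2)
        lab = np.array([True] * 10 + [False] * 10)
        out = sens_spec_ci(pred, lab, np.arange(20), method="wilson")
        assert out["sensitivity"] == pytest.approx(0.9)
        assert out["specificity"] == pytest.approx(0.8)
        lo, hi = out["sens_ci"]
        assert lo <= 0.9 <= hi

    def test_perfect_predictions(self, rng):
        lab = rng.random(40) < 0.5
        out = sens_spec_ci(lab, lab, np.arange(40), n_boot=200, rng=rng)
        assert out["sensitivity"] == 1.0 and out["specificity"] == 1.0
        assert out["sens_ci"][1] <= 1.0 and out["spec_ci"][1] <= 1.0

    def test_bootstrap_close_to_wilson_when_independent(self, rng):
        lab = rng.random(150) < 0.5
        pred = lab ^ (rng.random(150) < 0.2)
        w = sens_spec_ci(pred, lab, np.arange(150), method="wilson")
        b = sens_spec_ci(pred, lab, np.arange(150), n_boot=500, rng=rng)
        for key in ("sens_ci", "spec_ci"):
            assert w[key][0] == pytest.approx(b[key][0], abs=0.08)
            assert w[key][1] == pytest.approx(b[key][1], abs=0.08)

    def test_missing_denominator(self, rng):
        lab = np.ones(10, bool)
        out = sens_spec_ci(lab, lab, np.arange(10), method="wilson")
        assert np.isnan(out["specificity"])


def score_table(rng, n_eyes=120):
    rows = []
    rocc = set()
    for i in range(n_eyes):
        eye = f"E{i:03d}"
        if i < n_eyes // 2:
            rocc.add(eye)
        sick = rng.random() < 0.4
        sick_hemi = ("superior", "inferior")[rng.integers(0, 2)]
        for hemi in ("superior", "inferior"):
            for group in ("6-8", "4-5"):
                lab = sick and hemi == sick_hemi
                base = 0.8 if lab else 0.2
                rows.append({
                    "eye": eye, "hemifield": hemi, "group": group,
                    "vf_label": lab,
                    "percentile": np.clip(base + rng.normal(0, 0.15), 0, 1),
                    "pca": np.clip(base + rng.normal(0, 0.15), 0, 1),
                    "cascade": np.clip(base + rng.normal(0, 0.05), 0, 1),
                })
    df = pd.DataFrame(rows)
    split = CohortSplit(rocc, {f"E{i:03d}" for i in range(n_eyes)} - rocc)
    return df, split


class TestReport:
    def test_split_must_be_disjoint(self):
        with pytest.raises(ValueError):
            CohortSplit({"a", "b"}, {"b", "c"})

    def test_threshold_derived_on_rocc_only(self, rng):
        scores, split = score_table(rng)
        report = select_method_and_report(scores, split, n_boot=50, rng=rng)
        assert report.threshold_source == "rocc"
        for (hemi, group), grp in report.operating_table.groupby(
                ["hemifield", "group"]):
            # one threshold per hemi-cluster, shared across cohorts
            assert grp.threshold.nunique() == 1
            method = grp.method.iloc[0]
            sub = scores[(scores.hemifield == hemi) & (scores.group == group)]
            rocc_rows = sub[sub.eye.isin(split.rocc_ids)]
            roc = roc_and_auc(rocc_rows[method], rocc_rows.vf_label)
            thr, _, _ = youden_threshold(roc)
            assert grp.threshold.iloc[0] == pytest.approx(thr)

    def test_reproducible_with_fixed_seed(self, rng):
        scores, split = score_table(rng)
        a = select_method_and_report(scores, split, n_boot=50,
                                     rng=np.random.default_rng(3))
        b = select_method_and_report(scores, split, n_boot=50,
                                     rng=np.random.default_rng(3))
        pd.testing.assert_frame_equal(a.auc_table, b.auc_table)
        pd.testing.assert_frame_equal(a.operating_table, b.operating_table)

    def test_indistinguishable_methods_keep_percentile(self, rng):
        scores, split = score_table(rng)
        # make all methods identical: no significant improvement anywhere
        scores["pca"] = scores["percentile"]
        scores["cascade"] = scores["percentile"]
        report = select_method_and_report(scores, split, n_boot=20, rng=rng)
        assert (report.auc_table.chosen_method == "percentile").all()
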