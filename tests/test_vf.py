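"""Visual-field grid, HPA defect rule, hemi-cluster labels and staging."""

import numpy as np
import pytest

from gcfield.vf import (ANALYZABLE, BLIND_SPOT, VF_GRID, DefectMap,
                        GlaucomaStage, ProbCategory, VfLocation,
                        VisualFieldResult, check_reliability,
                        classify_defect_locations, label_hemiclusters,
                        read_vf_csv, require_repeatable_defect, stage_glaucoma,
                        write_vf_csv)

NS = ProbCategory.NS


def make_vf(pd_prob=None, md=-1.0, fp=0.05, pd_available=True, thr=30.0):
    probs = {p: NS for p in ANALYZABLE}
    if pd_prob:
        probs.update(pd_prob)
    return VisualFieldResult(
        thresholds_dB={p: thr for p in ANALYZABLE},
        total_deviation_dB={p: 0.0 for p in ANALYZABLE},
        pattern_deviation_dB={p: 0.0 for p in ANALYZABLE},
        td_prob={p: NS for p in ANALYZABLE},
        pd_prob=probs,
        md_dB=md, psd_dB=1.5, false_positive_rate=fp,
        pd_map_available=pd_available,
    )


def loc(x, y):
    match = [p for p in ANALYZABLE if p.x_deg == x and p.y_deg == y]
    assert match, f"({x},{y}) not analyzable"
    return match[0]


class TestGrid:
    def test_counts_and_blind_spot(self):
        assert len(VF_GRID) == 54
        assert len(ANALYZABLE) == 52
        assert {(p.x_deg, p.y_deg) for p in BLIND_SPOT} == {(15, 3), (15, -3)}

    def test_lattice_geometry(self):
        for p in VF_GRID:
            assert p.x_deg % 6 == 3 or abs(p.x_deg) == 27
            assert p.y_deg % 6 == 3 and abs(p.y_deg) <= 21
            assert abs(p.x_deg) <= 27


class TestReliability:
    @pytest.mark.parametrize("fp,expected", [(0.10, True), (0.15, False),
                                             (0.0, True), (0.149, True)])
    def test_strict_cutoff(self, fp, expected):
        assert check_reliability(make_vf(fp=fp)) is expected

    def test_missing_rate_rejected(self):
        vf = make_vf()
        vf.false_positive_rate = float("nan")
        with pytest.raises(ValueError):
            check_reliability(vf)


class TestHpaRule:
    def test_three_adjacent_with_p1(self):
        trio = [loc(-9, 9), loc(-3, 9), loc(3, 9)]
        cats = [ProbCategory.P5, ProbCategory.P1, ProbCategory.P5]
        vf = make_vf(dict(zip(trio, cats)))
        dm = classify_defect_locations(vf)
        assert set(dm.locations()) == set(trio)

    def test_pair_not_enough(self):
        pair = {loc(-9, 9): ProbCategory.P_HALF, loc(-3, 9): ProbCategory.P_HALF}
        assert classify_defect_locations(make_vf(pair)).count() == 0

    def test_trio_without_p1(self):
        trio = {loc(-9, 9): ProbCategory.P5, loc(-3, 9): ProbCategory.P5,
                loc(3, 9): ProbCategory.P5}
        assert classify_defect_locations(make_vf(trio)).count() == 0

    def test_hemifield_restriction(self):
        # vertical run across the midline: only 2 points in each hemifield
        run = {loc(-3, 9): ProbCategory.P1, loc(-3, 3): ProbCategory.P5,
               loc(-3, -3): ProbCategory.P5, loc(-3, -9): ProbCategory.P1}
        vf = make_vf(run)
        assert classify_defect_locations(vf, hemifield_restricted=True).count() == 0
        assert classify_defect_locations(vf, hemifield_restricted=False).count() == 4

    def test_diagonal_counts_with_8_not_4_neighbours(self):
        diag = {loc(-9, 15): ProbCategory.P1, loc(-3, 9): ProbCategory.P5,
                loc(3, 3): ProbCategory.P5}
        vf = make_vf(diag)
        assert classify_defect_locations(vf, neighbourhood=8).count() == 3
        assert classify_defect_locations(vf, neighbourhood=4).count() == 0

    def test_no_pd_map_means_all_defective(self):
        dm = classify_defect_locations(make_vf(pd_available=False))
        assert dm.count() == 52

    def test_monotone_in_probability(self, rng):
        """Worsening one location's category never shrinks the defect set."""
        cats = list(ProbCategory)
        for _ in range(25):
            probs = {p: cats[rng.integers(0, 5)] for p in ANALYZABLE}
            base = set(classify_defect_locations(make_vf(probs)).locations())
            p0 = list(ANALYZABLE)[rng.integers(0, 52)]
            if probs[p0].value == 0:
                continue
            worse = dict(probs)
            worse[p0] = ProbCategory(probs[p0].value - 1)
            new = set(classify_defect_locations(make_vf(worse)).locations())
            assert base <= new


class TestHemiclusters:
    def test_central_pair_half_defective(self, assignment):
        central = [p for p, cid in assignment.vf_labels.items()
                   if assignment.legend[cid] == ("6-8", "superior")]
        assert len(central) == 2
        dm = DefectMap({p: p == central[0] for p in ANALYZABLE})
        labels = label_hemiclusters(dm, assignment.vf_labels)
        assert labels[assignment.vf_labels[central[0]]] is True

    def test_below_criterion(self, assignment):
        cid = assignment.id_for("2", "superior")
        members = [p for p, c in assignment.vf_labels.items() if c == cid]
        assert len(members) == 9
        dm = DefectMap({p: p == members[0] for p in ANALYZABLE})
        labels = label_hemiclusters(dm, assignment.vf_labels)
        assert labels[cid] is False  # 1/9 = 11% < 25%

    def test_no_defects_no_labels(self, assignment):
        dm = DefectMap({p: False for p in ANALYZABLE})
        assert not any(label_hemiclusters(dm, assignment.vf_labels).values())

    def test_monotone_and_order_invariant(self, assignment, rng):
        flags = {p: bool(rng.random() < 0.3) for p in ANALYZABLE}
        dm = DefectMap(flags)
        base = label_hemiclusters(dm, assignment.vf_labels)
        # shuffling dict insertion order changes nothing
        items = list(flags.items())
        rng.shuffle(items)
        assert label_hemiclusters(DefectMap(dict(items)),
                                  assignment.vf_labels) == base
        # adding one defective point never turns a cluster off
        off = [p for p, v in flags.items() if not v]
        if off:
            flags2 = dict(flags)
            flags2[off[0]] = True
            more = label_hemiclusters(DefectMap(flags2), assignment.vf_labels)
            assert all(more[c] >= base[c] for c in base)

    def test_incomplete_assignment_rejected(self):
        dm = DefectMap({p: False for p in ANALYZABLE})
        partial = {p: 1 for p in ANALYZABLE}
        del partial[list(ANALYZABLE)[1]]
        with pytest.raises(ValueError, match="unassigned"):
            label_hemiclusters(dm, partial)


class TestStaging:
    def trio_vf(self, md):
        trio = {loc(-9, 9): ProbCategory.P1, loc(-3, 9): ProbCategory.P5,
                loc(3, 9): ProbCategory.P5}
        return make_vf(trio, md=md)

    def test_stages(self):
        no_defect = make_vf(md=-1.0)
        dm0 = classify_defect_locations(no_defect)
        assert stage_glaucoma(no_defect, dm0) is GlaucomaStage.PRE_PERIMETRIC
        for md, stage in [(-2.4, GlaucomaStage.EARLY),
                          (-8.0, GlaucomaStage.MODERATE),
                          (-13.0, GlaucomaStage.ADVANCED)]:
            vf = self.trio_vf(md)
            assert stage_glaucoma(vf, classify_defect_locations(vf)) is stage


class TestRepeatability:
    def test_intersection(self):
        a = DefectMap({p: p.y_deg > 0 for p in ANALYZABLE})
        b = DefectMap({p: p.x_deg > 0 for p in ANALYZABLE})
        inter = require_repeatable_defect(a, b)
        assert set(inter.locations()) == {p for p in ANALYZABLE
                                          if p.y_deg > 0 and p.x_deg > 0}
        same = require_repeatable_defect(a, a)
        assert same.defective == a.defective
        empty = require_repeatable_defect(
            a, DefectMap({p: False for p in ANALYZABLE}))
        assert empty.count() == 0


class TestIO:
    def test_round_trip(self, tmp_path):
        vf = make_vf({loc(-3, 3): ProbCategory.P1}, md=-2.5, fp=0.08)
        path = tmp_path / "eye.csv"
        write_vf_csv(vf, path)
        back = read_vf_csv(path)
        assert back.md_dB == vf.md_dB
        assert back.false_positive_rate == vf.false_positive_rate
        assert back.pd_prob == vf.pd_prob
        assert back.thresholds_dB == vf.thresholds_dB

    def test_left_eye_mirrored(self, tmp_path):
        import json
        import pandas as pd
        vf = make_vf({loc(-3, 3): ProbCategory.P1})
        path = tmp_path / "os.csv"
        write_vf_csv(vf, path)
        # a genuine left-eye export carries chart coordinates mirrored in x
        df = pd.read_csv(path)
        df["x_deg"] = -df["x_deg"]
        df.to_csv(path, index=False)
        meta = json.loads(path.with_suffix(".json").read_text())
        meta["laterality"] = "OS"
        path.with_suffix(".json").write_text(json.dumps(meta))
        back = read_vf_csv(path)
        assert back.pd_prob[loc(-3, 3)] is ProbCategory.P1

    def test_missing_column_rejected(self, tmp_path):
        vf = make_vf()
        path = tmp_path / "bad.csv"
        write_vf_csv(vf, path)
        import pandas as pd
        df = pd.read_csv(path).drop(columns=["pd_prob"])
        df.to_csv(path, index=False)
        with pytest.raises(ValueError, match="pd_prob"):
            read_vf_csv(path)
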