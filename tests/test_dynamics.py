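"""Dynamic layer: region clustering, Venn partitions, progression scans
and sign-change reporting."""

import numpy as np
import pandas as pd
import pytest

import dynqtl as dq


def _scan_frame(rows):
    return pd.DataFrame(rows, columns=["marker", "group", "cm", "p_value",
                                       "effect"])


class TestRegionMatching:
    def test_within_window_merges(self):
        scans = {"DS1": _scan_frame([("A", "C1", 12.0, 1e-8, 0.5)]),
                 "DS2": _scan_frame([("B", "C1", 15.0, 1e-6, 0.4)])}
        regions = dq.match_regions(scans, window_cm=5.0)
        assert len(regions) == 1
        assert regions[0].venn_class == "DS1 & DS2"

    def test_different_groups_never_merge(self):
        scans = {"DS1": _scan_frame([("A", "C1", 12.0, 1e-8, 0.5)]),
                 "DS2": _scan_frame([("B", "C2", 12.0, 1e-6, 0.4)])}
        regions = dq.match_regions(scans, window_cm=5.0)
        assert len(regions) == 2

    def test_single_linkage_chain(self):
        # Chain 0, 4, 8 merges transitively; 20 stays separate.
        scans = {"DS1": _scan_frame(
            [("A", "C1", 0.0, 1e-8, 0.5), ("B", "C1", 4.0, 1e-7, 0.5),
             ("C", "C1", 8.0, 1e-6, 0.5), ("D", "C1", 20.0, 1e-5, 0.5)])}
        regions = dq.match_regions(scans, window_cm=5.0)
        sizes = sorted(len(r.all_members) for r in regions)
        assert sizes == [1, 3]

    def test_missing_position_errors(self):
        scans = {"DS1": pd.DataFrame({"marker": ["A"], "p_value": [1e-8],
                                      "effect": [0.5]})}
        with pytest.raises(ValueError, match="A"):
            dq.match_regions(scans, window_cm=5.0)

    def test_stage_order_invariance(self):
        f1 = _scan_frame([("A", "C1", 10.0, 1e-8, 0.5)])
        f2 = _scan_frame([("B", "C1", 13.0, 1e-6, -0.4)])
        r_ab = dq.match_regions({"DS1": f1, "DS2": f2}, 5.0)
        r_ba = dq.match_regions({"DS2": f2, "DS1": f1}, 5.0)
        assert [sorted(r.all_members) for r in r_ab] == \
            [sorted(r.all_members) for r in r_ba]


class TestVenn:
    def test_identical_lists_all_shared(self):
        frame = _scan_frame([("A", "C1", 10.0, 1e-8, 0.5)])
        scans = {s: frame.copy() for s in ("DS1", "DS2", "DS3")}
        counts = dq.venn_counts(dq.match_regions(scans, 5.0))
        assert counts["DS1 & DS2 & DS3"] == 1
        assert counts.sum() == 1

    def test_disjoint_lists_single_stage_classes(self):
        scans = {"DS1": _scan_frame([("A", "C1", 10.0, 1e-8, 0.5)]),
                 "DS2": _scan_frame([("B", "C2", 10.0, 1e-8, 0.5)]),
                 "DS3": _scan_frame([("C", "C3", 10.0, 1e-8, 0.5)])}
        counts = dq.venn_counts(dq.match_regions(scans, 5.0))
        assert counts["DS1 only"] == 1
        assert counts["DS2 only"] == 1
        assert counts["DS3 only"] == 1
        assert counts.sum() == 3

    def test_totals_reconcile_per_stage(self):
        scans = {"DS1": _scan_frame([("A", "C1", 10.0, 1e-8, 0.5),
                                     ("B", "C2", 50.0, 1e-7, 0.3)]),
                 "DS2": _scan_frame([("C", "C1", 12.0, 1e-6, 0.4)]),
                 "DS3": _scan_frame([])}
        regions = dq.match_regions(scans, 5.0)
        counts = dq.venn_counts(regions)
        for stage, expect in (("DS1", 2), ("DS2", 1), ("DS3", 0)):
            total = sum(c for cls, c in counts.items() if stage in cls)
            assert total == expect

    def test_marker_level_counts(self):
        frame = _scan_frame([("A", "C1", 10.0, 1e-8, 0.5)])
        counts = dq.marker_venn_counts(
            {"DS1": frame, "DS2": frame, "DS3": _scan_frame([])})
        assert counts["DS1 & DS2"] == 1


class TestSignChanges:
    def _region(self, effects):
        stages = tuple(effects)
        return dq.QTLRegionMatch(
            "C1@10.0", "C1", 10.0, "A", 1e-8,
            members={s: pd.DataFrame({"marker": ["A"], "cm": [10.0],
                                      "p_value": [1e-8], "effect": [e]})
                     for s, e in effects.items()},
            stages=stages, venn_class="x", effects=effects)

    def test_consistent_signs_not_reported(self):
        rep = dq.sign_change_report(
            [self._region({"DS1": 0.5, "DS2": 0.4, "DS3": 0.3})])
        assert rep.empty

    def test_opposite_signs_reported_with_pair(self):
        rep = dq.sign_change_report([self._region({"DS1": 0.5, "DS3": -0.4})])
        assert len(rep) == 1
        assert rep.iloc[0]["stage_a"] == "DS1"
        assert rep.iloc[0]["stage_b"] == "DS3"
        assert rep.iloc[0]["effect_a"] == 0.5


@pytest.fixture(scope="module")
def prog_setup():
    gmap = dq.GeneticMap.uniform({f"C{i}": 8 for i in range(1, 5)}, 100.0)
    design = dq.CrossingDesign(
        ["P1", "P2", "P3", "P4"],
        [("F1", "P1", "P2", 80), ("F2", "P3", "P4", 80)])
    geno, _ = dq.simulate_genotypes(gmap, design, seed=2,
                                    force_segregating=["C2_03"])
    return gmap, geno


def _bv(values, lines, stage):
    return dq.BlueVector(pd.Series(values, index=lines), stage, 2, 1.0)


class TestProgression:
    def test_constant_shift_yields_no_qtl(self, prog_setup):
        gmap, geno = prog_setup
        rng = np.random.default_rng(3)
        y1 = rng.normal(50, 1, geno.n_lines)
        b1 = _bv(y1, geno.lines, "DS1")
        b2 = _bv(y1 + 20.0, geno.lines, "DS2")
        res = dq.progression_scan(b1, b2, geno, gmap)
        assert res.n_significant == 0

    def test_identical_stages_abort(self, prog_setup):
        gmap, geno = prog_setup
        y = np.random.default_rng(4).normal(50, 1, geno.n_lines)
        b1 = _bv(y, geno.lines, "DS1")
        b2 = _bv(y.copy(), geno.lines, "DS2")
        with pytest.raises(ValueError, match="identical"):
            dq.progression_scan(b1, b2, geno, gmap)

    def test_sign_switch_detected_with_doubled_effect(self, prog_setup):
        gmap, geno = prog_setup
        rng = np.random.default_rng(5)
        x = geno.column("C2_03")
        b = 0.6
        y1 = b * x + rng.normal(0, 0.15, geno.n_lines)
        y2 = -b * x + rng.normal(0, 0.15, geno.n_lines)
        res = dq.progression_scan(_bv(y1, geno.lines, "DS1"),
                                  _bv(y2, geno.lines, "DS2"), geno, gmap)
        row = res.table.set_index("marker").loc["C2_03"]
        assert row["significant"]
        assert row["effect"] == pytest.approx(-2 * b, abs=0.15)

    def test_equal_effects_cancel(self, prog_setup):
        gmap, geno = prog_setup
        rng = np.random.default_rng(6)
        x = geno.column("C2_03")
        hits = 0
        for _ in range(20):
            y1 = 0.8 * x + rng.normal(0, 0.15, geno.n_lines)
            y2 = 0.8 * x + rng.normal(0, 0.15, geno.n_lines)
            res = dq.progression_scan(_bv(y1, geno.lines, "DS1"),
                                      _bv(y2, geno.lines, "DS2"), geno,
                                      gmap)
            hits += bool(res.table.set_index("marker")
                         .loc["C2_03", "significant"])
        assert hits <= 2            # power < 10 % when effects cancel

    def test_negated_delta_flips_effects_same_pvalues(self, prog_setup):
        gmap, geno = prog_setup
        rng = np.random.default_rng(7)
        x = geno.column("C2_03")
        y1 = 0.5 * x + rng.normal(0, 0.2, geno.n_lines)
        y2 = -0.5 * x + rng.normal(0, 0.2, geno.n_lines)
        b1 = _bv(y1, geno.lines, "DS1")
        b2 = _bv(y2, geno.lines, "DS2")
        fwd = dq.progression_scan(b1, b2, geno, gmap).table
        rev = dq.progression_scan(b2, b1, geno, gmap).table
        assert np.allclose(fwd["p_value"], rev["p_value"],
                           rtol=1e-9, equal_nan=True)
        ok = fwd["effect"].notna()
        assert np.allclose(fwd.loc[ok, "effect"], -rev.loc[ok, "effect"],
                           rtol=1e-9)
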