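"""Association scan: Holm correction, cofactor selection, F-test oracle
agreement, invariances and effect-estimate calibration."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dynqtl as dq

from .oracles import best_subset_by_sbc, f_test_marker


class TestHolm:
    def test_step_down_hand_examples(self):
        # 0.001 <= 0.05/3, 0.02 <= 0.05/2, 0.04 <= 0.05: all rejected.
        assert dq.holm_correct([0.001, 0.02, 0.04], 0.05).tolist() == \
            [True, True, True]
        # 0.03 > 0.025 stops the step-down procedure after the first.
        assert dq.holm_correct([0.001, 0.03, 0.04], 0.05).tolist() == \
            [True, False, False]

    def test_nothing_significant(self):
        assert not dq.holm_correct([1.0, 1.0, 1.0], 0.05).any()
        assert dq.holm_correct([], 0.05).size == 0

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            dq.holm_correct([0.0, 0.5], 0.05)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.floats(1e-12, 1.0), min_size=1, max_size=40),
           st.floats(0.01, 0.2))
    def test_holm_rejections_superset_of_bonferroni(self, pvals, alpha):
        holm = dq.holm_correct(pvals, alpha)
        bonf = np.asarray(pvals) <= alpha / len(pvals)
        assert np.all(holm[bonf])


class TestCofactorSelection:
    def test_perfect_predictor_selected_first(self, make_geno):
        rng = np.random.default_rng(0)
        calls = (rng.random((40, 8)) < 0.5).astype(float)
        geno = make_geno(calls, ["F1"] * 20 + ["F2"] * 20)
        fam_centered = calls[:, 3] - np.where(np.arange(40) < 20,
                                              calls[:20, 3].mean(),
                                              calls[20:, 3].mean())
        y = pd.Series(fam_centered, index=geno.lines)
        cofs = dq.select_cofactors(y, geno)
        assert cofs[0] == "M03"

    def test_forward_path_matches_exhaustive_sbc(self, make_geno):
        # Three-marker instances: the stepwise search must land on the
        # same subset as brute-force enumeration of all 8 subsets.
        rng = np.random.default_rng(12)
        for _ in range(10):
            calls = (rng.random((60, 3)) < 0.5).astype(float)
            fams = ["F1"] * 30 + ["F2"] * 30
            y_vec = (1.1 * calls[:, 0] - 0.9 * calls[:, 2]
                     + rng.normal(0, 0.7, 60))
            geno = make_geno(calls, fams)
            y = pd.Series(y_vec, index=geno.lines)
            selected = dq.select_cofactors(y, geno)
            _, best = best_subset_by_sbc(y_vec, fams,
                                         [calls[:, j] for j in range(3)])
            assert sorted(geno.marker_index(m) for m in selected) == \
                sorted(best)

    def test_null_trait_selects_near_empty_sets(self, small_map,
                                                small_design):
        # Monte-Carlo distribution of selected-set sizes under a pure-noise
        # trait (100 lines, 50 markers): BIC-stopped forward selection
        # admits a small number of spurious cofactors.
        rng = np.random.default_rng(77)
        sizes = []
        for _ in range(60):
            geno, _ = dq.simulate_genotypes(small_map, small_design,
                                            seed=rng.integers(2 ** 31))
            y = pd.Series(rng.standard_normal(100), index=geno.lines)
            sizes.append(len(dq.select_cofactors(y, geno)))
        sizes = np.asarray(sizes)
        assert np.mean(sizes) <= 2.0
        assert np.mean(sizes <= 2) >= 0.7


class TestScan:
    def test_family_confounded_marker_inestimable(self, make_geno):
        calls = np.zeros((8, 2))
        calls[4:, 0] = 1.0              # identical to family split
        calls[::2, 1] = 1.0
        geno = make_geno(calls, ["F1"] * 4 + ["F2"] * 4)
        y = pd.Series(np.arange(8.0), index=geno.lines)
        res = dq.scan_markers(y, geno)
        row = res.table.set_index("marker").loc["M00"]
        assert row["p_value"] == 1.0
        assert np.isnan(row["effect"])
        assert not row["significant"]

    def test_matches_statsmodels_oracle_with_missing_data(self, make_geno):
        rng = np.random.default_rng(5)
        n, m = 50, 8
        calls = (rng.random((n, m)) < 0.5).astype(float)
        calls[rng.random((n, m)) < 0.05] = np.nan
        fams = ["F1"] * 25 + ["F2"] * 25
        geno = make_geno(calls, fams)
        y_vec = rng.normal(0, 1, n) + np.nan_to_num(calls[:, 1])
        y = pd.Series(y_vec, index=geno.lines)
        res = dq.scan_markers(y, geno).table.set_index("marker")
        for j in range(m):
            mask = ~np.isnan(calls[:, j])
            if calls[mask, j].std() == 0:
                continue
            _, p_oracle = f_test_marker(
                y_vec[mask], np.asarray(fams)[mask], calls[mask, j])
            assert res.loc[f"M{j:02d}", "p_value"] == \
                pytest.approx(p_oracle, rel=1e-10)

    def test_shift_and_permutation_invariance(self, make_geno):
        rng = np.random.default_rng(6)
        calls = (rng.random((60, 10)) < 0.5).astype(float)
        fams = ["F1"] * 30 + ["F2"] * 30
        geno = make_geno(calls, fams)
        y = pd.Series(rng.normal(0, 1, 60) + calls[:, 2], index=geno.lines)
        p0 = dq.scan_markers(y, geno).table["p_value"]
        p_shift = dq.scan_markers(y + 100.0, geno).table["p_value"]
        assert np.allclose(p0, p_shift, rtol=1e-9, equal_nan=True)
        perm = rng.permutation(60)
        p_perm = dq.scan_markers(y.iloc[perm], geno).table["p_value"]
        assert np.allclose(p0, p_perm, rtol=1e-9, equal_nan=True)

    def test_duplicate_columns_collapsed(self, make_geno):
        rng = np.random.default_rng(7)
        base = (rng.random(40) < 0.5).astype(float)
        calls = np.column_stack([base, base,
                                 (rng.random(40) < 0.5).astype(float)])
        geno = make_geno(calls, ["F1"] * 40)
        y = pd.Series(base + rng.normal(0, 0.4, 40), index=geno.lines)
        res = dq.scan_markers(y, geno)
        t = res.table.set_index("marker")
        assert t.loc["M01", "duplicate_of"] == "M00"
        assert t.loc["M01", "p_value"] == t.loc["M00", "p_value"]
        assert res.m_tested == 2  # duplicates do not inflate Holm's m

    def test_cofactor_window_exclusion(self, make_geno):
        # A cofactor tightly linked to the tested marker must be excluded
        # from that marker's fit (window > 0), otherwise it absorbs the QTL.
        rng = np.random.default_rng(8)
        gmap = dq.GeneticMap.from_arrays(
            ["Q", "COF", "FAR"], ["C1", "C1", "C2"], [10.0, 13.0, 50.0])
        causal = (rng.random(120) < 0.5).astype(float)
        flip = rng.random(120) < 0.03
        linked = np.where(flip, 1 - causal, causal)
        far = (rng.random(120) < 0.5).astype(float)
        geno = make_geno(np.column_stack([causal, linked, far]),
                         ["F1"] * 120, markers=["Q", "COF", "FAR"])
        y = pd.Series(causal + rng.normal(0, 0.5, 120), index=geno.lines)
        p_with_window = dq.scan_markers(
            y, geno, gmap, cofactors=["COF"],
            cofactor_window=10.0).table.set_index("marker")
        p_literal = dq.scan_markers(
            y, geno, gmap, cofactors=["COF"],
            cofactor_window=0.0).table.set_index("marker")
        assert p_with_window.loc["Q", "p_value"] < 1e-6
        assert p_literal.loc["Q", "p_value"] > \
            p_with_window.loc["Q", "p_value"] * 1e3

    def test_effect_estimate_unbiased(self, make_geno):
        # Mean bias of the allele-substitution estimate below 5 % of |b|.
        rng = np.random.default_rng(9)
        b = 0.5
        estimates = []
        for _ in range(200):
            calls = (rng.random((200, 20)) < 0.5).astype(float)
            fams = ["F1"] * 100 + ["F2"] * 100
            geno = make_geno(calls, fams)
            y = pd.Series(b * calls[:, 4] + rng.normal(0, 1, 200),
                          index=geno.lines)
            res = dq.scan_markers(y, geno).table.set_index("marker")
            estimates.append(res.loc["M04", "effect"])
        assert abs(np.mean(estimates) - b) < 0.05 * b

    def test_power_on_monogenic_preset_trait(self, make_geno):
        # h2 = 0.9 single-QTL trait, effect 0.5 SD, 647 lines: the causal
        # marker must clear the Holm threshold in (nearly) every replicate.
        rng = np.random.default_rng(10)
        hits = 0
        reps = 20
        for _ in range(reps):
            calls = (rng.random((647, 60)) < 0.5).astype(float)
            fams = (["F1"] * 131 + ["F2"] * 120 + ["F3"] * 200
                    + ["F4"] * 196)
            geno = make_geno(calls, fams)
            # Effect 0.5 phenotypic SD; polygenic background tops the
            # genotypic variance up to h2 = 0.9 of a unit-variance trait.
            qtl = 0.5 * calls[:, 30]
            poly = rng.normal(0, np.sqrt(0.9 - 0.0625), 647)
            noise = rng.normal(0, np.sqrt(0.1), 647)
            y = pd.Series(qtl + poly + noise, index=geno.lines)
            res = dq.scan_markers(y, geno).table.set_index("marker")
            hits += bool(res.loc["M30", "significant"])
        assert hits >= int(0.95 * reps)


class TestModelObject:
    def test_association_scan_fit_summary(self, tiny_study):
        blues = dq.compute_blues(tiny_study.phenotypes, "DS1")
        res = dq.AssociationScan(blues, tiny_study.genotypes,
                                 tiny_study.gmap).fit()
        assert res.stage == "DS1"
        assert res.m_tested > 100
        text = res.summary()
        assert "QTL scan" in text and "DS1" in text
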