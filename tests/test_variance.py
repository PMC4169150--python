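"""Explained-genotypic-variance accounting: p_G, sequential partial R2,
temporal profiles."""

import numpy as np
import pandas as pd
import pytest

import dynqtl as dq

from .oracles import sequential_r2


def _geno_y(make_geno, n=200, m=8, seed=0, families=2):
    rng = np.random.default_rng(seed)
    calls = (rng.random((n, m)) < 0.5).astype(float)
    fams = [f"F{k % families}" for k in range(n)]
    geno = make_geno(calls, sorted(fams))
    return rng, calls, geno


class TestProportionGenotypicVariance:
    def test_empty_marker_set_gives_zero(self, make_geno):
        _, _, geno = _geno_y(make_geno)
        y = pd.Series(np.random.default_rng(1).normal(size=200),
                      index=geno.lines)
        acc = dq.proportion_genotypic_variance(y, geno, [], h2=0.9)
        assert acc.p_g == 0.0
        assert acc.r2_adj == 0.0

    def test_plugin_arithmetic_scaling(self, make_geno):
        # Same fit divided by two heritabilities: p_G scales as 1/h2, and
        # R2_adj = 0.63-style arithmetic gives p_G = 100 * R2_adj / h2.
        rng, calls, geno = _geno_y(make_geno, seed=2)
        y = pd.Series(calls[:, 0] + 0.5 * calls[:, 1]
                      + rng.normal(0, 0.6, 200), index=geno.lines)
        a1 = dq.proportion_genotypic_variance(y, geno, ["M00", "M01"], 0.90)
        a2 = dq.proportion_genotypic_variance(y, geno, ["M00", "M01"], 0.45)
        assert a1.p_g == pytest.approx(100 * a1.r2_adj / 0.90)
        assert a2.p_g == pytest.approx(2 * a1.p_g)

    def test_noiseless_monogenic_pg_is_100(self, make_geno):
        _, calls, geno = _geno_y(make_geno, n=647, seed=3)
        y = pd.Series(0.8 * calls[:, 3], index=geno.lines)
        acc = dq.proportion_genotypic_variance(y, geno, ["M03"], h2=1.0)
        assert acc.p_g == pytest.approx(100.0, abs=1.0)

    def test_allele_flip_invariance(self, make_geno):
        rng, calls, geno = _geno_y(make_geno, seed=4)
        y = pd.Series(calls[:, 0] - calls[:, 2] + rng.normal(0, 0.5, 200),
                      index=geno.lines)
        flipped = calls.copy()
        flipped[:, 0] = 1 - flipped[:, 0]
        geno_f = dq.GenotypeMatrix(flipped, geno.lines, geno.markers,
                                   geno.families)
        a = dq.proportion_genotypic_variance(y, geno, ["M00", "M02"], 0.8)
        b = dq.proportion_genotypic_variance(y, geno_f, ["M00", "M02"], 0.8)
        assert a.p_g == pytest.approx(b.p_g, rel=1e-9)

    def test_pg_above_100_flagged_not_clamped(self, make_geno):
        _, calls, geno = _geno_y(make_geno, n=60, seed=5)
        y = pd.Series(calls[:, 0], index=geno.lines)
        acc = dq.proportion_genotypic_variance(y, geno, ["M00"], h2=0.5)
        assert acc.p_g > 100.0
        assert acc.exceeds_h2

    def test_noise_marker_barely_moves_adjusted_r2(self, make_geno):
        rng, calls, geno = _geno_y(make_geno, seed=6)
        y = pd.Series(calls[:, 0] + rng.normal(0, 0.5, 200),
                      index=geno.lines)
        base = dq.proportion_genotypic_variance(y, geno, ["M00"], 0.9)
        plus = dq.proportion_genotypic_variance(y, geno, ["M00", "M07"], 0.9)
        # The df penalty keeps a pure-noise marker from inflating R2_adj.
        assert plus.r2_adj - base.r2_adj < 0.02


class TestSequentialShares:
    def test_orthogonal_markers_shares_equal_marginals(self, make_geno):
        # Orthogonalised (balanced) two-marker design: sequential shares
        # coincide with marginal R2 values.
        combos = np.array([[0, 0], [0, 1], [1, 0], [1, 1]] * 25, dtype=float)
        geno = make_geno(combos, ["F1"] * 100)
        rng = np.random.default_rng(7)
        y = pd.Series(combos[:, 0] + 0.5 * combos[:, 1]
                      + rng.normal(0, 0.3, 100), index=geno.lines)
        seq = dq.sequential_partial_r2(y, geno, ["M00", "M01"])
        marg0 = dq.sequential_partial_r2(y, geno, ["M00"]).seq_r2[0]
        marg1 = dq.sequential_partial_r2(y, geno, ["M01"]).seq_r2[0]
        assert seq.seq_r2[0] == pytest.approx(marg0, rel=1e-9)
        assert seq.seq_r2[1] == pytest.approx(marg1, rel=1e-9)

    def test_duplicate_marker_second_share_zero(self, make_geno):
        rng = np.random.default_rng(8)
        col = (rng.random(100) < 0.5).astype(float)
        geno = make_geno(np.column_stack([col, col]), ["F1"] * 100)
        y = pd.Series(col + rng.normal(0, 0.4, 100), index=geno.lines)
        seq = dq.sequential_partial_r2(y, geno, ["M00", "M01"])
        assert seq.seq_r2[1] == 0.0
        assert bool(seq.collinear[1])

    def test_matches_nested_rss_oracle(self, make_geno):
        rng = np.random.default_rng(9)
        base = (rng.random(120) < 0.5).astype(float)
        # Correlated triple: linked markers sharing signal.
        m2 = np.where(rng.random(120) < 0.2, 1 - base, base)
        m3 = (rng.random(120) < 0.5).astype(float)
        calls = np.column_stack([base, m2, m3])
        fams = ["F1"] * 60 + ["F2"] * 60
        geno = make_geno(calls, fams)
        y_vec = base + 0.4 * m3 + rng.normal(0, 0.5, 120)
        y = pd.Series(y_vec, index=geno.lines)
        seq = dq.sequential_partial_r2(y, geno, ["M00", "M01", "M02"])
        oracle = sequential_r2(y_vec, fams, [base, m2, m3])
        assert np.allclose(seq.seq_r2.to_numpy(), oracle, rtol=1e-10)

    def test_share_sum_is_order_invariant(self, make_geno):
        rng, calls, geno = _geno_y(make_geno, seed=10)
        y = pd.Series(calls[:, 0] + 0.6 * calls[:, 1]
                      + rng.normal(0, 0.5, 200), index=geno.lines)
        s1 = dq.sequential_partial_r2(y, geno, ["M00", "M01", "M02"])
        s2 = dq.sequential_partial_r2(y, geno, ["M02", "M01", "M00"])
        assert s1.seq_r2.sum() == pytest.approx(s2.seq_r2.sum(), rel=1e-9)
        assert (s1.seq_r2 >= -1e-12).all()

    def test_shares_sum_to_model_r2(self, make_geno):
        rng, calls, geno = _geno_y(make_geno, seed=11)
        y = pd.Series(calls[:, 0] + rng.normal(0, 0.7, 200),
                      index=geno.lines)
        acc = dq.proportion_genotypic_variance(
            y, geno, ["M00", "M03", "M05"], 0.9)
        assert acc.shares.seq_r2.sum() == pytest.approx(
            acc.notes["r2_unadjusted"], abs=1e-10)

    def test_order_by_pvalue_ties_by_map(self, make_geno):
        _, calls, geno = _geno_y(make_geno, seed=12)
        p = pd.Series([0.5, 0.001, 0.001], index=["M00", "M01", "M02"])
        ordered = dq.variance.order_by_association(
            ["M00", "M01", "M02"], p, geno)
        assert ordered == ["M01", "M02", "M00"]


class TestTemporalProfile:
    def _profile(self, seed):
        rng = np.random.default_rng(seed)
        n = 250
        calls = (rng.random((n, 4)) < 0.5).astype(float)
        gmap = dq.GeneticMap.from_arrays(
            ["M00", "M01", "M02", "M03"], ["C1", "C2", "C3", "C4"],
            [10.0, 10.0, 10.0, 10.0])
        lines = pd.Index([f"L{i:03d}" for i in range(n)])
        geno = dq.GenotypeMatrix(calls, lines, gmap.markers,
                                 pd.Series(["F1"] * n, index=lines))
        # M00 persistent, M01 active at DS1 only.
        y = {"DS1": calls[:, 0] + calls[:, 1] + rng.normal(0, 0.3, n),
             "DS2": calls[:, 0] + rng.normal(0, 0.3, n),
             "DS3": calls[:, 0] + rng.normal(0, 0.3, n)}
        blues, scans = {}, {}
        for s, vals in y.items():
            blues[s] = pd.Series(vals, index=lines)
            res = dq.scan_markers(blues[s], geno, gmap)
            scans[s] = res
        regions = dq.match_regions(
            {s: scans[s] for s in y}, 5.0, gmap)
        prof = dq.temporal_pg_profile(
            regions, blues, scans, geno, {s: 1.0 for s in y})
        return prof, regions

    def test_stage_specific_region_fades(self):
        late = []
        persist_ratio = []
        for seed in range(5):
            prof, regions = self._profile(seed)
            r_m01 = [r.region_id for r in regions
                     if "M01" in r.all_members]
            r_m00 = [r.region_id for r in regions
                     if "M00" in r.all_members]
            if not r_m01 or not r_m00:
                continue
            sub = prof[prof.region == r_m01[0]].set_index("stage")
            late += [sub.loc["DS2", "pg_share"], sub.loc["DS3", "pg_share"]]
            p = prof[prof.region == r_m00[0]].set_index("stage")["pg_share"]
            persist_ratio.append(p.max() / max(p.min(), 1e-9))
        assert np.mean(late) < 1.0           # < 1 % absolute at later stages
        assert np.median(persist_ratio) < 2.0  # persistent region is stable

    def test_null_architecture_shares_near_zero(self, make_geno):
        rng = np.random.default_rng(30)
        n = 300
        calls = (rng.random((n, 3)) < 0.5).astype(float)
        gmap = dq.GeneticMap.from_arrays(["M00", "M01", "M02"],
                                         ["C1", "C2", "C3"], [5.0] * 3)
        geno = make_geno(calls, ["F1"] * n)
        blues = {s: pd.Series(rng.normal(0, 1, n), index=geno.lines)
                 for s in ("DS1", "DS2")}
        scans = {s: dq.scan_markers(blues[s], geno, gmap)
                 for s in blues}
        # Force a region list from all markers (none is significant).
        fake = {s: pd.DataFrame({
            "marker": ["M00"], "group": ["C1"], "cm": [5.0],
            "p_value": [0.5], "effect": [0.0]}) for s in blues}
        regions = dq.match_regions(fake, 5.0, gmap)
        prof = dq.temporal_pg_profile(regions, blues, scans, geno,
                                      {s: 1.0 for s in blues})
        assert (prof.pg_share.abs() < 2.0).all()
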