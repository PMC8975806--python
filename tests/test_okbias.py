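"""Ok-seq strand-bias binning, meta-profiles, region statistics, group tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from forktrap import okbias, simgen
from forktrap.okbias import (
    bin_fragments,
    compare_groups,
    gene_offset_matrix,
    length_normalized_profile,
    meta_profile,
    pct_l2r,
    region_stat,
)

SIZES = {"chrS": 200_000}


def _bins(crick_frac, coverage=100, chrom="chrS", size=200_000):
    """Deterministic bin table with per-bin Crick fraction."""
    n = size // 1000
    frac = np.broadcast_to(np.asarray(crick_frac, dtype=float), (n,))
    crick = np.round(coverage * frac).astype(int)
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": np.arange(n) * 1000,
            "watson_count": coverage - crick,
            "crick_count": crick,
        }
    )


def _genes(rows):
    return pd.DataFrame(
        rows, columns=["id", "chrom", "tss", "tts", "strand", "length", "fpkm"]
    )


class TestBinning:
    def test_midpoint_assignment_example(self):
        frags = pd.DataFrame(
            [("chrS", 1500, 1650, "-")], columns=["chrom", "start", "end", "strand"]
        )
        out = bin_fragments(frags, SIZES)
        row = out[out["start"] == 1000].iloc[0]
        assert row["crick_count"] == 1 and row["watson_count"] == 0
        assert out["crick_count"].sum() == 1

    def test_total_counts_conserved(self):
        rng = np.random.default_rng(0)
        starts = rng.integers(0, 199_000, 500)
        frags = pd.DataFrame(
            {
                "chrom": "chrS",
                "start": starts,
                "end": starts + rng.integers(100, 201, 500),
                "strand": rng.choice(["+", "-"], 500),
            }
        )
        out = bin_fragments(frags, SIZES)
        assert (out["watson_count"] + out["crick_count"]).sum() == 500

    def test_unknown_chromosome_rejected(self):
        frags = pd.DataFrame(
            [("chrX", 10, 100, "+")], columns=["chrom", "start", "end", "strand"]
        )
        with pytest.raises(ValueError, match="unknown"):
            bin_fragments(frags, SIZES)


class TestPctL2R:
    def test_pure_crick_is_hundred(self):
        bins = pd.DataFrame(
            {"chrom": ["chrS"], "start": [0], "watson_count": [0], "crick_count": [10]}
        )
        assert pct_l2r(bins).iloc[0] == 100.0

    def test_balanced_is_fifty(self):
        bins = pd.DataFrame(
            {"chrom": ["chrS"], "start": [0], "watson_count": [7], "crick_count": [7]}
        )
        assert pct_l2r(bins).iloc[0] == 50.0

    def test_zero_coverage_is_missing(self):
        bins = pd.DataFrame(
            {"chrom": ["chrS"], "start": [0], "watson_count": [0], "crick_count": [0]}
        )
        assert pct_l2r(bins).isna().iloc[0]

    def test_bounded_on_random_counts(self, rng):
        bins = pd.DataFrame(
            {
                "chrom": "chrS",
                "start": np.arange(100) * 1000,
                "watson_count": rng.integers(0, 50, 100),
                "crick_count": rng.integers(0, 50, 100),
            }
        )
        pct = pct_l2r(bins).dropna()
        assert pct.between(0, 100).all()


class TestMetaProfile:
    def test_uniform_bias_gives_flat_profile(self):
        bins = _bins(0.5)
        genes = _genes([("g0", "chrS", 100_000, 150_000, "+", 50_000, 5.0)])
        (p,) = meta_profile(bins, genes, anchor="TSS")
        np.testing.assert_allclose(p.pct_l2r, 50.0)

    def test_minus_strand_mirroring_equivalence(self):
        # plus-strand gene with a step up at TSS
        frac = np.full(200, 0.3)
        frac[100:] = 0.7
        bins_plus = _bins(frac)
        genes_plus = _genes([("g0", "chrS", 100_000, 150_000, "+", 50_000, 5.0)])
        # reverse-complement scenario: mirrored genome, minus-strand gene
        bins_minus = _bins(1.0 - frac[::-1])
        genes_minus = _genes([("g0", "chrS", 99_999, 49_999, "-", 50_000, 5.0)])
        _, mp, _ = gene_offset_matrix(bins_plus, genes_plus, "TSS", 20)
        _, mm, _ = gene_offset_matrix(bins_minus, genes_minus, "TSS", 20)
        np.testing.assert_allclose(mp, mm)

    def test_double_mirroring_is_identity(self):
        rng = np.random.default_rng(7)
        frac = rng.uniform(0.2, 0.8, 200)
        bins = _bins(frac)
        genes = _genes([("g0", "chrS", 100_000, 150_000, "+", 50_000, 5.0)])
        offs, m1, _ = gene_offset_matrix(bins, genes, "TSS", 10)
        mirrored = 100.0 - m1[0][::-1]
        back = 100.0 - mirrored[::-1]
        np.testing.assert_allclose(back, m1[0])

    def test_fpkm_quartiles_ordered_when_efficiency_tracks_expression(self):
        rng = np.random.default_rng(1)
        n = 40
        starts = 120_000 + 400_000 * np.arange(n)
        fpkm = np.linspace(1, 100, n)
        genes = pd.DataFrame(
            {
                "id": [f"g{i}" for i in range(n)],
                "chrom": "chrS",
                "tss": starts,
                "tts": starts + 150_000,
                "strand": "+",
                "length": 150_000,
                "fpkm": fpkm,
                "efficiency": np.linspace(0.1, 0.8, n),
            }
        )
        model = simgen.RFDModel(genes=genes, chrom_sizes={"chrS": int(starts[-1] + 300_000)})
        bins, gtab, _ = simgen.gen_okseq_counts(model, coverage=200, seed=0)
        profiles = meta_profile(bins, gtab, anchor="TSS", grouping="fpkm-quartile")
        at5 = {p.group: p.pct_l2r[p.offsets_kb == 5][0] for p in profiles}
        assert at5["Q1"] < at5["Q2"] < at5["Q3"] < at5["Q4"]


class TestLengthNormalized:
    def test_constant_input_constant_output(self):
        bins = _bins(0.5)
        genes = _genes([("g0", "chrS", 50_000, 150_000, "+", 100_000, 5.0)])
        grid, prof = length_normalized_profile(bins, genes, n_norm_bins=40)
        np.testing.assert_allclose(prof, 50.0)

    def test_linear_ramp_preserved_by_interpolation(self):
        frac = np.linspace(0.2, 0.8, 200)
        bins = _bins(frac, coverage=10_000)
        genes = _genes([("g0", "chrS", 0, 199_999, "+", 199_999, 5.0)])
        grid, prof = length_normalized_profile(bins, genes, n_norm_bins=50)
        fitted = np.polyfit(grid, prof, 1)
        resid = prof - np.polyval(fitted, grid)
        assert np.abs(resid).max() < 0.5  # linear up to count rounding

    def test_identity_when_gene_matches_bin_count(self):
        rng = np.random.default_rng(3)
        frac = rng.uniform(0.3, 0.7, 200)
        bins = _bins(frac, coverage=1000)
        genes = _genes([("g0", "chrS", 40_000, 80_000, "+", 40_000, 5.0)])
        grid, prof = length_normalized_profile(bins, genes, n_norm_bins=41)
        expect = 100.0 * frac[40:81]
        np.testing.assert_allclose(prof, expect, atol=0.1)


class TestRegionStat:
    def test_flat_profile_zero_statistic(self):
        bins = _bins(0.5)
        genes = _genes([("g0", "chrS", 100_000, 150_000, "+", 50_000, 5.0)])
        out = region_stat(bins, genes, anchor="TSS")
        assert out["stat"].iloc[0] == pytest.approx(0.0, abs=1e-9)

    def test_step_profile_statistic_equals_step(self):
        frac = np.full(200, 0.4)
        frac[100:] = 0.6
        bins = _bins(frac)
        genes = _genes([("g0", "chrS", 100_000, 150_000, "+", 50_000, 5.0)])
        out = region_stat(bins, genes, anchor="TSS")
        assert out["stat"].iloc[0] == pytest.approx(20.0, abs=1e-9)

    def test_tts_ranges_are_local(self):
        frac = np.full(200, 0.7)
        frac[150:] = 0.3  # termination at TTS = 150 kb
        bins = _bins(frac)
        genes = _genes([("g0", "chrS", 100_000, 150_000, "+", 50_000, 5.0)])
        out = region_stat(bins, genes, anchor="TTS")
        assert out["stat"].iloc[0] == pytest.approx(-40.0, abs=1e-9)


def _brute_force_h(groups):
    """Independent Kruskal-Wallis H (no ties), from the rank-sum definition."""
    pooled = np.concatenate(groups)
    order = pooled.argsort()
    ranks = np.empty(len(pooled))
    ranks[order] = np.arange(1, len(pooled) + 1)
    n = len(pooled)
    start, h = 0, 0.0
    for g in groups:
        h += ranks[start : start + len(g)].sum() ** 2 / len(g)
        start += len(g)
    return 12.0 / (n * (n + 1)) * h - 3 * (n + 1)


class TestCompareGroups:
    def test_identical_groups_h_zero_p_one(self):
        res = compare_groups({"a": [1.0, 2.0, 3.0], "b": [2.0, 3.0, 1.0]})
        assert res.h == 0.0
        assert res.p_value == 1.0

    def test_h_matches_hand_ranked_oracle(self):
        groups = {"a": [1, 2, 3], "b": [4, 5, 6], "c": [7, 8, 9]}
        res = compare_groups(groups)
        expect = _brute_force_h([np.array(v, float) for v in groups.values()])
        assert res.h == pytest.approx(expect, rel=1e-12)
        assert res.epsilon_squared == pytest.approx(expect / 8.0, rel=1e-12)

    def test_exact_permutation_matches_independent_enumeration(self):
        from itertools import combinations

        a, b = np.array([1.0, 3.0, 5.0]), np.array([2.0, 4.0, 9.0, 11.0])
        res = compare_groups({"a": a, "b": b}, exact=True)
        pooled = np.concatenate([a, b])
        h_obs = _brute_force_h([a, b])
        hits = total = 0
        for pick in combinations(range(7), 3):
            ga = pooled[list(pick)]
            gb = pooled[[i for i in range(7) if i not in pick]]
            if _brute_force_h([ga, gb]) >= h_obs - 1e-12:
                hits += 1
            total += 1
        assert res.p_value == pytest.approx(hits / total, rel=1e-12)

    def test_power_to_separate_shifted_efficiency(self):
        """WT-like vs efficiency-shifted condition separates at p < 0.01."""
        from forktrap.cli import default_rfd_model

        wt = default_rfd_model(n_genes=60, efficiency=0.60, seed=0)
        mut = default_rfd_model(n_genes=60, efficiency=0.45, seed=0)
        bw, gw, _ = simgen.gen_okseq_counts(wt, coverage=100, seed=1)
        bm, gm, _ = simgen.gen_okseq_counts(mut, coverage=100, seed=2)
        res = compare_groups(
            {
                "WT": region_stat(bw, gw, "TSS")["stat"],
                "mutant": region_stat(bm, gm, "TSS")["stat"],
            }
        )
        assert res.p_value < 0.01
        assert res.pairwise["rank_biserial"].abs().iloc[0] > 0.3

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            compare_groups({"a": [1.0], "b": [2.0, 3.0]})
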