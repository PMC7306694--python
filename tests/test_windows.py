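"""Windowed diversity statistics against brute-force oracles, VCF/mask
loading, gene-proximity classification and the associated tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import divscape.windows as dw
from divscape.synthetic import write_vcf
from divscape.windows import (
    GenotypeMatrix,
    classify_gene_proximity,
    fit_proximity_glm,
    hudson_fst_windows,
    make_windows,
    sign_binomial_test,
    subsample_haplotypes,
    window_stats,
)

from oracles import (
    oracle_pairwise_diffs,
    oracle_segregating_sites,
    oracle_tajima_d,
)
from conftest import random_genotype_matrix


class TestWindowStats:
    def test_worked_example(self, worked_example_gm):
        tab = window_stats(worked_example_gm, contig_length=5000)
        assert tab.loc[0, "S"] == 3
        assert tab.loc[0, "pi_total"] == pytest.approx(2.0)
        assert tab.loc[0, "tajima_d"] == pytest.approx(2.012, abs=5e-4)

    def test_monomorphic_window(self):
        gm = GenotypeMatrix("c", np.array([5]), np.zeros((4, 1), dtype=np.int8))
        tab = window_stats(gm, contig_length=5000)
        assert tab.loc[0, "S"] == 0
        assert tab.loc[0, "pi"] == 0.0
        assert np.isnan(tab.loc[0, "tajima_d"])

    def test_tajima_d_matches_independent_oracle(self):
        """window_stats D equals a direct-formula implementation to 1e-10."""
        rng = np.random.default_rng(123)
        for _ in range(100):
            gm = random_genotype_matrix(rng, missing_frac=0.1 * rng.random())
            tab = window_stats(gm, contig_length=5000)
            expected = oracle_tajima_d(gm.calls, gm.n_hap)
            got = tab.loc[0, "tajima_d"]
            if np.isnan(expected):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(expected, abs=1e-10)
            assert tab.loc[0, "S"] == oracle_segregating_sites(gm.calls)
            assert tab.loc[0, "pi_total"] == pytest.approx(
                oracle_pairwise_diffs(gm.calls), abs=1e-10)

    def test_d_undefined_iff_no_segregating_sites(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            gm = random_genotype_matrix(rng)
            tab = window_stats(gm, contig_length=5000)
            assert np.isnan(tab.loc[0, "tajima_d"]) == (tab.loc[0, "S"] == 0)

    def test_pi_denominator_modes(self):
        gm = random_genotype_matrix(np.random.default_rng(2), n_hap=6, n_sites=10)
        win = make_windows("chr1", 5000)
        acc = np.array([4000])
        t_acc = window_stats(gm, win, accessible=acc)
        t_nom = window_stats(gm, win, accessible=acc, pi_denominator="nominal")
        assert t_acc.loc[0, "pi"] == pytest.approx(
            t_nom.loc[0, "pi"] * 5000 / 4000)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_s_invariant_to_row_order_and_allele_relabel(self, seed):
        rng = np.random.default_rng(seed)
        gm = random_genotype_matrix(rng)
        base = window_stats(gm, contig_length=5000).loc[0]
        perm = rng.permutation(gm.n_hap)
        gm_perm = GenotypeMatrix(gm.contig, gm.positions, gm.calls[perm])
        flipped = np.where(gm.calls >= 0, 1 - gm.calls, gm.calls).astype(np.int8)
        gm_flip = GenotypeMatrix(gm.contig, gm.positions, flipped)
        for other in (gm_perm, gm_flip):
            tab = window_stats(other, contig_length=5000).loc[0]
            assert tab["S"] == base["S"]
            assert tab["pi_total"] == pytest.approx(base["pi_total"], abs=1e-12)


class TestLoadGenotypes:
    def test_vcf_roundtrip_and_mask(self, tmp_path, rng):
        gm = random_genotype_matrix(rng, n_hap=8, n_sites=12)
        write_vcf(gm, tmp_path / "pop.vcf", contig_length=5000)
        loaded = dw.load_genotypes({"pop": tmp_path / "pop.vcf"})["pop"]
        assert np.array_equal(loaded.positions, gm.positions)
        assert np.array_equal(loaded.calls, gm.calls)
        # mask the first two sites
        bed = tmp_path / "mask.bed"
        bed.write_text(f"chr1\t{gm.positions[0]}\t{gm.positions[1] + 1}\n")
        masked = dw.load_genotypes({"pop": tmp_path / "pop.vcf"},
                                   mask_path=bed)["pop"]
        assert masked.n_sites == gm.n_sites - 2

    def test_multiallelic_and_indel_records_dropped(self, tmp_path):
        vcf = tmp_path / "multi.vcf"
        vcf.write_text("\n".join([
            "##fileformat=VCFv4.2",
            "##contig=<ID=chr1,length=1000>",
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2",
            "chr1\t10\t.\tA\tT\t.\tPASS\t.\tGT\t0/1\t0/0",
            "chr1\t20\t.\tA\tT,G\t.\tPASS\t.\tGT\t0/1\t0/2",
            "chr1\t30\t.\tA\tAT\t.\tPASS\t.\tGT\t0/1\t0/0",
            "chr1\t40\t.\tC\tG\t.\tPASS\t.\tGT\t1/1\t0/0",
        ]) + "\n")
        gm = dw.load_genotypes({"p": vcf})["p"]
        assert gm.n_sites == 2
        assert list(gm.positions) == [9, 39]

    def test_high_missingness_sites_dropped(self, tmp_path):
        vcf = tmp_path / "miss.vcf"
        vcf.write_text("\n".join([
            "##fileformat=VCFv4.2",
            "##contig=<ID=chr1,length=1000>",
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2",
            "chr1\t10\t.\tA\tT\t.\tPASS\t.\tGT\t./.\t./1",
            "chr1\t20\t.\tA\tT\t.\tPASS\t.\tGT\t0/1\t./.",
        ]) + "\n")
        gm = dw.load_genotypes({"p": vcf})["p"]
        assert gm.n_sites == 1  # 3/4 missing haplotypes exceeds 0.5 threshold
        assert gm.positions[0] == 19


class TestSubsample:
    def test_identity_when_all_requested(self, rng):
        gm = random_genotype_matrix(rng, n_hap=8)
        assert subsample_haplotypes(gm, 4, seed=0) is gm

    def test_deterministic_given_seed(self, rng):
        gm = random_genotype_matrix(rng, n_hap=22)
        a = subsample_haplotypes(gm, 4, seed=9)
        b = subsample_haplotypes(gm, 4, seed=9)
        assert np.array_equal(a.calls, b.calls)

    def test_too_few_individuals_raises_with_three_flag_escape(self, rng):
        gm = random_genotype_matrix(rng, n_hap=6)
        with pytest.raises(ValueError, match="allow_three"):
            subsample_haplotypes(gm, 4)
        out = subsample_haplotypes(gm, 3, allow_three=True)
        assert out.n_hap == 6

    def test_resampling_stability_on_simulated_data(self):
        """Two independent 4-of-11 subsamples give similar median S."""
        from divscape.coalescent import DemographyModel, simulate_coalescent_window

        rng = np.random.default_rng(17)
        pos_all, cols = [], []
        for j in range(150):
            g, p = simulate_coalescent_window(22, 10.0, DemographyModel(), rng)
            pos_all.append(p + j * 5000)
            cols.append(g)
        gm = GenotypeMatrix("chr1", np.concatenate(pos_all),
                            np.concatenate(cols, axis=1))
        meds = []
        for seed in (1, 2):
            sub = subsample_haplotypes(gm, 4, seed=seed)
            tab = window_stats(sub, contig_length=150 * 5000)
            meds.append(tab["S"].median())
        assert abs(meds[0] - meds[1]) / max(meds) < 0.15


class TestHudsonFst:
    def test_identical_frequencies_give_zero_centered_fst(self, rng):
        gm = random_genotype_matrix(rng, n_hap=16, n_sites=30)
        half_a = GenotypeMatrix(gm.contig, gm.positions, gm.calls[:8])
        half_b = GenotypeMatrix(gm.contig, gm.positions, gm.calls[8:])
        win = make_windows("chr1", 5000)
        fst = hudson_fst_windows(half_a, half_b, win).loc[0, "fst"]
        assert abs(fst) < 0.25  # resampled halves of one population

    def test_fixed_difference_gives_fst_one(self):
        a = GenotypeMatrix("c", np.array([1]), np.ones((20, 1), dtype=np.int8))
        b = GenotypeMatrix("c", np.array([1]), np.zeros((20, 1), dtype=np.int8))
        fst = hudson_fst_windows(a, b, make_windows("c", 5000)).loc[0, "fst"]
        assert fst == pytest.approx(1.0)

    def test_single_site_matches_hand_evaluation(self):
        # p_A=0.2, p_B=0.8, n=10 each: num = 0.36 - 2*0.16/9, den = 0.68
        a_calls = np.array([[1]] * 2 + [[0]] * 8, dtype=np.int8)
        b_calls = 1 - a_calls
        a = GenotypeMatrix("c", np.array([1]), a_calls)
        b = GenotypeMatrix("c", np.array([1]), b_calls)
        fst = hudson_fst_windows(a, b, make_windows("c", 5000)).loc[0, "fst"]
        expected = (0.36 - 2 * (0.2 * 0.8) / 9) / 0.68
        assert fst == pytest.approx(expected, abs=1e-12)

    def test_no_shared_sites_flagged_nan(self, rng):
        a = GenotypeMatrix("c", np.array([1]), np.ones((4, 1), dtype=np.int8))
        b = GenotypeMatrix("c", np.array([2]), np.ones((4, 1), dtype=np.int8))
        with pytest.warns(UserWarning):
            fst = hudson_fst_windows(a, b, make_windows("c", 5000)).loc[0, "fst"]
        assert np.isnan(fst)


class TestGeneProximity:
    WINDOWS = pd.DataFrame({"contig": "c", "start": [0], "end": [5000]})

    @pytest.mark.parametrize("gene,expected", [
        ((1000, 2000), "overlap"),
        ((9999, 11000), "adjacent"),   # gap 4,999 < 5,000
        ((10001, 11000), "distant"),   # gap 5,001
        ((10000, 11000), "distant"),   # gap exactly 5,000 is not adjacent
    ])
    def test_boundary_conventions(self, gene, expected):
        labels = classify_gene_proximity(self.WINDOWS,
                                         {"c": np.array([gene])})
        assert labels.iloc[0] == expected

    def test_missing_contig_warns_distant(self):
        with pytest.warns(UserWarning, match="absent"):
            labels = classify_gene_proximity(self.WINDOWS, {"other": np.array([(0, 10)])})
        assert (labels == "distant").all()

    def test_partition_complete(self, rng):
        wins = make_windows("c", 500_000)
        genes = np.sort(rng.choice(500_000, size=(40, 2)))
        genes = genes[genes[:, 0] < genes[:, 1]]
        labels = classify_gene_proximity(wins, {"c": genes})
        assert labels.isin(["overlap", "adjacent", "distant"]).all()
        assert len(labels) == len(wins)


class TestProximityGlm:
    def _table(self, rates, n, rng):
        recs = []
        for prox, rate in rates.items():
            recs.append(pd.DataFrame({
                "population": "p", "contig": "c",
                "start": np.arange(n), "S": rng.poisson(rate, n),
                "proximity": prox}))
        return pd.concat(recs, ignore_index=True)

    def test_null_coefficients_near_zero(self, rng):
        tab = self._table({"overlap": 20, "adjacent": 20, "distant": 20},
                          1700, rng)
        fit = fit_proximity_glm(tab)
        for name in fit.params.index:
            if name != "Intercept":
                assert abs(fit.params[name]) < 3 * fit.bse[name]

    def test_rate_ratio_recovered(self, rng):
        tab = self._table({"adjacent": 20, "overlap": 16}, 4000, rng)
        fit = fit_proximity_glm(tab)
        coef = fit.params["C(proximity)[T.overlap]"]
        assert abs(coef - np.log(0.8)) < 3 * fit.bse["C(proximity)[T.overlap]"]

    def test_single_class_rejected(self, rng):
        tab = self._table({"overlap": 20}, 50, rng)
        with pytest.raises(ValueError):
            fit_proximity_glm(tab)

    def test_null_wald_p_roughly_uniform(self):
        """Wald p-values under the null are approximately uniform."""
        from scipy import stats

        rng = np.random.default_rng(88)
        pvals = []
        for _ in range(200):
            tab = self._table({"overlap": 20, "distant": 20}, 120, rng)
            fit = fit_proximity_glm(tab)
            pvals.append(fit.pvalues["C(proximity)[T.overlap]"])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestSignBinomial:
    def test_printed_value_12_of_15(self):
        assert round(sign_binomial_test(12, 15), 3) == 0.035

    def test_closed_forms(self):
        assert sign_binomial_test(15, 15) == pytest.approx(2 * 0.5**15)
        assert sign_binomial_test(8, 15) == 1.0

    def test_symmetry_and_errors(self):
        assert sign_binomial_test(3, 15) == pytest.approx(
            sign_binomial_test(12, 15))
        with pytest.raises(ValueError):
            sign_binomial_test(0, 0)
        with pytest.raises(ValueError):
            sign_binomial_test(5, 3)
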