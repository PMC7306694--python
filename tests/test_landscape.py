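"""Landscape correlation matrices, randomization null, alignment
distances, the Mantel test and the invasive-vs-native comparison."""

import numpy as np
import pandas as pd
import pytest

from divscape.landscape import (
    alignment_distance,
    compare_invasive_native_correlations,
    diversity_wide,
    extract_busco_windows,
    mantel_test,
    randomization_null,
    spearman_matrix,
    tajima_correlations,
)
from divscape.synthetic import LandscapeSpec, generate_annotations

from oracles import oracle_spearman


def _wide(rng, n_pops=3, n_windows=40, shared=1.0, noise=1.0):
    base = rng.normal(size=n_windows)
    return pd.DataFrame({f"p{i}": shared * base + noise * rng.normal(size=n_windows)
                         for i in range(n_pops)})


class TestSpearmanMatrix:
    def test_self_correlation_is_one(self, rng):
        wide = _wide(rng)
        rho, n = spearman_matrix(wide[["p0", "p1"]].assign(p0b=wide["p0"]))
        assert rho.loc["p0", "p0b"] == pytest.approx(1.0)

    def test_reversed_ranks_give_minus_one(self):
        wide = pd.DataFrame({"a": np.arange(20.0), "b": -np.arange(20.0)})
        rho, _ = spearman_matrix(wide)
        assert rho.loc["a", "b"] == pytest.approx(-1.0)

    def test_matches_brute_force_rank_pearson(self, rng):
        """Every reported rho equals rank-then-Pearson to 1e-12."""
        for _ in range(10):
            wide = _wide(rng, n_pops=4, n_windows=30)
            wide.iloc[rng.integers(0, 30, 5), 0] = np.nan  # pairwise deletion
            rho, _ = spearman_matrix(wide)
            for a in wide.columns:
                for b in wide.columns:
                    if a >= b:
                        continue
                    sub = wide[[a, b]].dropna()
                    assert rho.loc[a, b] == pytest.approx(
                        oracle_spearman(sub[a], sub[b]), abs=1e-12)

    def test_pairwise_complete_counts(self, rng):
        wide = _wide(rng, n_pops=2, n_windows=30)
        wide.iloc[:5, 0] = np.nan
        rho, n = spearman_matrix(wide)
        assert n.loc["p0", "p1"] == 25

    def test_too_few_windows_rejected(self, rng):
        wide = _wide(rng, n_windows=5)
        with pytest.raises(ValueError, match="shared windows"):
            spearman_matrix(wide)

    def test_constant_vector_flagged(self, rng):
        wide = pd.DataFrame({"a": np.ones(20), "b": np.arange(20.0)})
        with pytest.warns(UserWarning, match="constant"):
            rho, _ = spearman_matrix(wide)
        assert np.isnan(rho.loc["a", "b"])


class TestRandomizationNull:
    def test_k_equal_to_all_windows_reproduces_full_rho(self, rng):
        wide = _wide(rng, n_windows=30)
        full, _ = spearman_matrix(wide)
        null, _ = randomization_null(wide, k=30, n_iter=5, seed=1)
        for r in null.itertuples():
            assert r.rho == pytest.approx(full.loc[r.pop_a, r.pop_b], abs=1e-12)

    def test_deterministic_given_seed(self, rng):
        wide = _wide(rng, n_windows=50)
        a, _ = randomization_null(wide, k=20, n_iter=10, seed=3)
        b, _ = randomization_null(wide, k=20, n_iter=10, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_k_too_large_rejected(self, rng):
        with pytest.raises(ValueError):
            randomization_null(_wide(rng, n_windows=20), k=21)


class TestBuscoWindows:
    def test_shared_only_excludes_partial_orthologs(self):
        spec = LandscapeSpec(n_windows=50)
        ann_a = generate_annotations(spec, 0.6, seed=1, busco_fraction=1.0)
        ann_b = ann_a[ann_a["busco_id"] != "BUSCO00001"]
        bw = extract_busco_windows({"a": ann_a, "b": ann_b}, shared_only=True)
        assert "BUSCO00001" not in set(bw["ortholog"])
        shared = set(ann_a.loc[ann_a.busco_id != "", "busco_id"]) & \
            set(ann_b.loc[ann_b.busco_id != "", "busco_id"])
        assert bw["ortholog"].nunique() == len(shared)

    def test_window_spans_first_to_last_exon(self):
        spec = LandscapeSpec(n_windows=30)
        ann = generate_annotations(spec, 0.5, seed=2, busco_fraction=1.0)
        bw = extract_busco_windows({"a": ann})
        exons = ann[(ann.feature == "exon")]
        for r in bw.itertuples():
            grp = exons[exons.busco_id == r.ortholog]
            assert r.start == grp["start"].min()
            assert r.end == grp["end"].max()


class TestAlignmentDistance:
    def test_identical_sequences_zero(self):
        d, p = alignment_distance({"a": "ACGTACGT", "b": "ACGTACGT"})
        assert d.loc["a", "b"] == 0.0

    def test_stated_formula(self):
        s1 = "A" * 100
        s2 = "A" * 90 + "C" * 10
        d, p = alignment_distance({"x": s1, "y": s2})
        assert p.loc["x", "y"] == pytest.approx(0.1)
        assert d.loc["x", "y"] == pytest.approx(np.sqrt(0.1))

    def test_all_different_gives_one(self):
        d, _ = alignment_distance({"x": "AAAA", "y": "CCCC"})
        assert d.loc["x", "y"] == pytest.approx(1.0)

    def test_gaps_excluded_pairwise(self):
        d, p = alignment_distance({"x": "AC-TA", "y": "ACGTC"})
        # comparable sites: A,C,T,A vs A,C,T,C -> 1 of 4 differ
        assert p.loc["x", "y"] == pytest.approx(0.25)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            alignment_distance({"x": "ACGT", "y": "ACG"})

    def test_fasta_input(self, tmp_path):
        fa = tmp_path / "aln.fasta"
        fa.write_text(">a\nACGT\n>b\nACGA\n")
        d, p = alignment_distance(fa)
        assert p.loc["a", "b"] == pytest.approx(0.25)


def _random_sym(rng, n, labels):
    m = rng.normal(size=(n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0)
    return pd.DataFrame(m, index=labels, columns=labels)


class TestMantel:
    def test_perfect_monotone_association(self, rng):
        labels = list("abcdefg")
        m1 = _random_sym(rng, 7, labels)
        iu = np.triu_indices(7, 1)
        r2 = np.zeros((7, 7))
        r2[iu] = np.argsort(np.argsort(m1.values[iu])) + 1.0
        r2 += r2.T
        m2 = pd.DataFrame(r2, index=labels, columns=labels)
        r, p = mantel_test(m1, m2, n_perm=99, seed=0)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(1 / 100)

    def test_deterministic_given_seed(self, rng):
        m1, m2 = _random_sym(rng, 6, range(6)), _random_sym(rng, 6, range(6))
        r1, p1 = mantel_test(m1, m2, n_perm=200, seed=5)
        r2, p2 = mantel_test(m1, m2, n_perm=200, seed=5)
        assert (r1, p1) == (r2, p2)

    def test_statistic_matches_scikit_bio(self, rng):
        """Cross-check the Mantel statistic against an independent library."""
        skbio_dist = pytest.importorskip("skbio.stats.distance")
        n = 8
        a = np.abs(_random_sym(rng, n, range(n)).to_numpy())
        b = np.abs(_random_sym(rng, n, range(n)).to_numpy())
        np.fill_diagonal(a, 0)
        np.fill_diagonal(b, 0)
        r_mine, _ = mantel_test(pd.DataFrame(a), pd.DataFrame(b),
                                n_perm=10, seed=0)
        r_skbio, _, _ = skbio_dist.mantel(
            skbio_dist.DistanceMatrix(a), skbio_dist.DistanceMatrix(b),
            method="spearman", permutations=0)
        assert r_mine == pytest.approx(r_skbio, abs=1e-12)

    def test_invariant_to_consistent_relabeling(self, rng):
        labels = list("abcdef")
        m1, m2 = _random_sym(rng, 6, labels), _random_sym(rng, 6, labels)
        r0, p0 = mantel_test(m1, m2, n_perm=300, seed=9)
        perm = ["c", "a", "f", "b", "e", "d"]
        r1, p1 = mantel_test(m1.loc[perm, perm], m2.loc[perm, perm],
                             n_perm=300, seed=9)
        assert r1 == pytest.approx(r0, abs=1e-12)

    def test_label_mismatch_and_small_n_rejected(self, rng):
        m1 = _random_sym(rng, 5, list("abcde"))
        m2 = _random_sym(rng, 5, list("abcdf"))
        with pytest.raises(ValueError):
            mantel_test(m1, m2)
        m3 = _random_sym(rng, 3, list("abc"))
        with pytest.raises(ValueError):
            mantel_test(m3, m3)


class TestInvasiveNativeComparison:
    def _rho(self, vals, labels):
        m = pd.DataFrame(vals, index=labels, columns=labels, dtype=float)
        np.fill_diagonal(m.values, 1.0)
        return m

    def test_all_weaker_closed_form(self):
        labels = ["inv", "nat"] + [f"o{i}" for i in range(8)]
        m = pd.DataFrame(0.5, index=labels, columns=labels)
        m.loc["inv", [f"o{i}" for i in range(8)]] = 0.2
        m.loc[[f"o{i}" for i in range(8)], "inv"] = 0.2
        np.fill_diagonal(m.values, 1.0)
        status = {"inv": "invasive", "nat": "native",
                  **{f"o{i}": "other" for i in range(8)}}
        res = compare_invasive_native_correlations(m, status)
        assert res["counts"] == (8, 0)
        assert res["sign_test_p"] == pytest.approx(2 * 0.5**8)

    def test_missing_status_rejected(self, rng):
        m = self._rho(0.3, ["a", "b", "c"])
        with pytest.raises(ValueError):
            compare_invasive_native_correlations(m, {"a": "invasive"})

    def test_null_counts_binomial(self, rng):
        """No invasion effect: direction counts behave like fair coin flips."""
        counts = []
        labels = ["inv", "nat"] + [f"o{i}" for i in range(6)]
        status = {"inv": "invasive", "nat": "native",
                  **{f"o{i}": "other" for i in range(6)}}
        for _ in range(200):
            m = self._rho(rng.normal(0.3, 0.1, size=(8, 8)), labels)
            m.values[:] = (m.values + m.values.T) / 2
            res = compare_invasive_native_correlations(m, status)
            counts.append(res["counts"][0])
        assert abs(np.mean(counts) - 3.0) < 0.5  # E[k] = 6/2


def test_tajima_correlations_drop_undefined_pairwise(diversity_table_pair):
    tabs = diversity_table_pair
    tabs["p1"].loc[:4, "tajima_d"] = np.nan
    rho, n = tajima_correlations(tabs)
    assert n.loc["p1", "p2"] == 55
    assert -1 <= rho.loc["p1", "p2"] <= 1


def test_diversity_wide_aligns_on_window_keys(diversity_table_pair):
    wide = diversity_wide(diversity_table_pair, "S")
    assert wide.shape == (60, 2)
    assert list(wide.columns) == ["p1", "p2"]
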