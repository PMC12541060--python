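"""Candidate enumeration, grouped correlation, trans null and network assembly."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from creglink.linking import (
    bh_adjust,
    build_link_network,
    build_null,
    candidate_pairs,
    candidate_tfs_for_gene,
    find_promoter_peaks,
    grouped_correlation,
    null_significance,
)
from creglink.regions import GenomicRegion


def _genes(rows):
    return pd.DataFrame(rows, columns=["gene", "chrom", "tss", "strand"]).set_index("gene")


class TestCandidatePairs:
    def test_gene_without_nearby_peak_has_no_pairs(self):
        peaks = [GenomicRegion("chr1", 2_000_000, 2_000_500)]
        genes = _genes([("G1", "chr1", 100_000, "+")])
        assert len(candidate_pairs(peaks, genes)) == 0

    def test_peak_at_tss_included(self):
        peaks = [GenomicRegion("chr1", 99_750, 100_250)]
        genes = _genes([("G1", "chr1", 100_000, "+")])
        pairs = candidate_pairs(peaks, genes)
        assert list(pairs["gene"]) == ["G1"]
        assert pairs.iloc[0]["tss_distance"] == 0

    def test_matches_brute_force(self, rng):
        peaks = [
            GenomicRegion(f"chr{rng.integers(1, 3)}", int(s), int(s) + 400)
            for s in rng.integers(0, 2_000_000, size=50)
        ]
        genes = _genes([
            (f"G{i}", f"chr{rng.integers(1, 3)}", int(rng.integers(0, 2_000_000)), "+")
            for i in range(10)
        ])
        got = set(map(tuple, candidate_pairs(peaks, genes)[["peak_index", "gene"]].values))
        expected = set()
        for i, p in enumerate(peaks):
            for g, row in genes.iterrows():
                if p.chrom == row["chrom"] and abs(p.center - row["tss"]) <= 500_000:
                    expected.add((i, g))
        assert got == expected


class TestGroupedCorrelation:
    def _pairs(self):
        return pd.DataFrame({"peak_index": [0], "gene": ["G1"], "tss_distance": [0]})

    def test_identical_vectors_give_one(self):
        acc = np.array([[1.0, 2.0, 3.0, 4.0]])
        out = grouped_correlation(self._pairs(), acc, acc.copy(), pd.Index(["G1"]))
        assert out.iloc[0]["r"] == pytest.approx(1.0)

    def test_reversed_vectors_give_minus_one(self):
        acc = np.array([[1.0, 2.0, 3.0, 4.0]])
        expr = np.array([[4.0, 3.0, 2.0, 1.0]])
        out = grouped_correlation(self._pairs(), acc, expr, pd.Index(["G1"]))
        assert out.iloc[0]["r"] == pytest.approx(-1.0)

    def test_matches_definitional_oracle(self, rng):
        acc = rng.normal(size=(1, 6))
        expr = rng.normal(size=(1, 6))
        out = grouped_correlation(self._pairs(), acc, expr, pd.Index(["G1"]))
        x, y = acc[0], expr[0]
        r_oracle = (
            ((x - x.mean()) * (y - y.mean())).sum()
            / np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        )
        assert out.iloc[0]["r"] == pytest.approx(r_oracle, abs=1e-12)

    def test_zero_variance_pair_dropped(self):
        acc = np.ones((1, 5))
        expr = np.arange(5.0)[None, :]
        out = grouped_correlation(self._pairs(), acc, expr, pd.Index(["G1"]))
        assert len(out) == 0

    def test_too_few_groups_rejected(self):
        with pytest.raises(ValueError):
            grouped_correlation(self._pairs(), np.ones((1, 2)), np.ones((1, 2)),
                                pd.Index(["G1"]))

    def test_shift_invariance_of_r(self, rng):
        acc = rng.normal(size=(1, 20))
        expr = rng.normal(size=(1, 20))
        a = grouped_correlation(self._pairs(), acc, expr, pd.Index(["G1"]))
        b = grouped_correlation(self._pairs(), acc + 7.5, expr + 7.5, pd.Index(["G1"]))
        assert a.iloc[0]["r"] == pytest.approx(b.iloc[0]["r"], abs=1e-12)


class TestNullModel:
    def _setup(self, rng, n_peaks=120, n_genes=8, n_groups=200):
        peaks = []
        for c in ("chr1", "chr2", "chr3"):
            for i in range(n_peaks // 3):
                peaks.append(GenomicRegion(c, i * 1000, i * 1000 + 400))
        genes = _genes([
            (f"G{i}", "chr1", i * 5000 + 1000, "+") for i in range(n_genes)
        ])
        acc = rng.normal(size=(len(peaks), n_groups))
        expr = rng.normal(size=(n_genes, n_groups))
        return peaks, genes, acc, expr

    def test_null_peak_count_and_off_chromosome(self, rng):
        peaks, genes, acc, expr = self._setup(rng)
        null = build_null(peaks, genes, acc, expr, n_null=50, seed=1)
        assert len(null.null_peaks["chr1"]) == 50
        chroms = {peaks[i].chrom for i in null.null_peaks["chr1"]}
        assert "chr1" not in chroms

    def test_sampling_with_replacement_when_short(self, rng):
        peaks, genes, acc, expr = self._setup(rng)
        null = build_null(peaks, genes, acc, expr, n_null=1000, seed=1)
        assert len(null.null_peaks["chr1"]) == 1000  # 80 trans peaks, resampled

    def test_independent_data_mean_near_zero(self, rng):
        peaks, genes, acc, expr = self._setup(rng)
        null = build_null(peaks, genes, acc, expr, n_null=80, seed=2)
        assert np.abs(null.mu0).max() < 0.05

    def test_seed_reproducibility(self, rng):
        peaks, genes, acc, expr = self._setup(rng)
        a = build_null(peaks, genes, acc, expr, n_null=40, seed=7)
        b = build_null(peaks, genes, acc, expr, n_null=40, seed=7)
        for c in a.null_peaks:
            np.testing.assert_array_equal(a.null_peaks[c], b.null_peaks[c])


class TestNullSignificance:
    def test_r_equal_mu_gives_z0_p1(self):
        z, p = null_significance(np.array([0.3]), np.array([0.3]), np.array([0.1]))
        assert z[0] == 0.0
        assert p[0] == 1.0

    def test_normal_cdf_oracle(self):
        z, p = null_significance(np.array([0.4]), np.array([0.0]), np.array([0.2]))
        assert z[0] == pytest.approx(2.0)
        assert p[0] == pytest.approx(2 * norm.sf(2.0), rel=1e-12)
        assert p[0] == pytest.approx(0.0455, abs=2e-4)

    def test_symmetry(self):
        _, p_hi = null_significance(np.array([0.5]), np.array([0.2]), np.array([0.1]))
        _, p_lo = null_significance(np.array([-0.1]), np.array([0.2]), np.array([0.1]))
        assert p_hi[0] == pytest.approx(p_lo[0], rel=1e-12)

    def test_zero_sd_rejected(self):
        with pytest.raises(ValueError):
            null_significance(np.array([0.1]), np.array([0.0]), np.array([0.0]))


def _bh_oracle(p):
    """Independent step-up implementation."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(n)
    prev = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        val = min(prev, p[i] * n / rank)
        adj[i] = val
        prev = val
    return adj


class TestBH:
    def test_hand_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_matches_oracle_on_random_p(self, rng):
        p = rng.random(1000)
        np.testing.assert_allclose(bh_adjust(p), _bh_oracle(p), atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestNetworkAssembly:
    def _inputs(self):
        peaks = [
            GenomicRegion("chr1", 99_500, 100_400),   # promoter peak of G1
            GenomicRegion("chr1", 150_000, 150_500),  # distal peak
            GenomicRegion("chr1", 300_000, 300_500),  # distal peak
        ]
        genes = _genes([("G1", "chr1", 100_000, "+")])
        return peaks, genes

    def _corr(self, p_values):
        n = len(p_values)
        return pd.DataFrame({
            "peak_index": [1, 2][:n],
            "gene": ["G1"] * n,
            "r": [0.5] * n,
            "z": [4.0] * n,
            "p": p_values,
        })

    def _coaccess(self, score_1, score_2):
        return pd.DataFrame({
            "peak_i": [0, 0], "peak_j": [1, 2],
            "score": [score_1, score_2],
            "distance": [50_000, 200_000], "n_windows": [1, 1],
        })

    def test_reliable_requires_both_criteria(self):
        peaks, genes = self._inputs()
        net = build_link_network(
            self._corr([0.001, 0.001]), self._coaccess(0.30, 0.15), peaks, genes
        )
        by_peak = net.set_index("peak_index")
        assert bool(by_peak.loc[1, "reliable"])   # fdr < 0.1, coaccess 0.30 > 0.2
        assert not bool(by_peak.loc[2, "reliable"])  # coaccess 0.15 fails

    def test_oc_fdr_override(self):
        peaks, genes = self._inputs()
        corr = self._corr([0.15])  # fdr = 0.15: fails at 0.1, passes at OC's 0.2
        co = self._coaccess(0.30, 0.30).iloc[:1]
        default = build_link_network(corr, co, peaks, genes)
        oc = build_link_network(corr, co, peaks, genes, cancer_label="OC")
        assert not default["reliable"].any()
        assert oc["reliable"].all()

    def test_gene_without_promoter_peak_excluded(self):
        peaks = [GenomicRegion("chr1", 150_000, 150_500)]
        genes = _genes([("G1", "chr1", 100_000, "+")])
        corr = pd.DataFrame({
            "peak_index": [0], "gene": ["G1"], "r": [0.5], "z": [4.0], "p": [0.001],
        })
        net = build_link_network(corr, self._coaccess(0.3, 0.3), peaks, genes)
        assert len(net) == 0

    def test_promoter_peak_self_coaccess_is_one(self):
        peaks, genes = self._inputs()
        corr = pd.DataFrame({
            "peak_index": [0], "gene": ["G1"], "r": [0.6], "z": [5.0], "p": [1e-6],
        })
        net = build_link_network(corr, self._coaccess(0.0, 0.0), peaks, genes)
        assert net.iloc[0]["coaccess"] == 1.0

    def test_promoter_lookup_prefers_nearest(self):
        peaks = [
            GenomicRegion("chr1", 99_100, 99_900),
            GenomicRegion("chr1", 99_800, 100_300),
        ]
        genes = _genes([("G1", "chr1", 100_000, "+")])
        promoters = find_promoter_peaks(peaks, genes)
        assert promoters["G1"][0] == 1  # center 100050 is closest to the TSS


class TestCandidateTFs:
    def _network(self):
        return pd.DataFrame({
            "gene": ["G1", "G1", "G1"],
            "peak_index": [0, 1, 2],
            "reliable": [True, True, False],
        })

    def _matches(self):
        return pd.DataFrame(
            [[True, True, False], [False, True, True], [True, True, True]],
            columns=["A", "B", "C"],
        )

    def test_union_over_reliable_peaks(self):
        assert candidate_tfs_for_gene(self._network(), self._matches(), "G1") == ["A", "B", "C"]

    def test_single_peak(self):
        net = self._network().iloc[:1]
        assert candidate_tfs_for_gene(net, self._matches(), "G1") == ["A", "B"]

    def test_absent_gene_empty(self):
        assert candidate_tfs_for_gene(self._network(), self._matches(), "G9") == []

    def test_no_reliable_links_empty(self):
        net = self._network()
        net["reliable"] = False
        assert candidate_tfs_for_gene(net, self._matches(), "G1") == []
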