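"""Motif scanning, chromVAR deviations, footprint profiles and the TF filter."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from creglink.tf import (
    FootprintProfile,
    MotifModel,
    chromvar_deviations,
    footprint_profile,
    read_jaspar_pfms,
    sample_background_peaks,
    scan_motifs,
    tumor_specific_tfs,
)

BASES = "ACGT"


def _random_seq(rng, n):
    return "".join(rng.choice(list(BASES), size=n))


def _random_motif(rng, name="M1", width=8):
    pfm = rng.integers(0, 20, size=(4, width)).astype(float)
    pfm += 1
    pfm *= 100 / pfm.sum(axis=0)  # constant column sums
    return MotifModel(name, pfm)


def _revcomp(s):
    return s.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def _scan_oracle(seq, motif, score_fraction=0.8):
    """Naive per-position loop on both strands."""
    lod = motif.log_odds()
    thr = score_fraction * lod.max(axis=0).sum()
    for strand_seq in (seq, _revcomp(seq)):
        s = strand_seq.upper()
        for i in range(len(s) - motif.width + 1):
            total = 0.0
            for j, base in enumerate(s[i: i + motif.width]):
                total += lod[BASES.index(base), j] if base in BASES else 0.0
            if total >= thr:
                return True
    return False


class TestMotifModel:
    def test_pfm_validation(self):
        with pytest.raises(ValueError):
            MotifModel("bad", np.ones((3, 8)))
        with pytest.raises(ValueError):
            MotifModel("bad", -np.ones((4, 8)))
        with pytest.raises(ValueError):
            MotifModel("short", np.ones((4, 3)))

    def test_jaspar_parsing(self):
        text = (
            ">MA0001.1 TESTTF\n"
            "A [ 10  0 20  5 ]\n"
            "C [  0 25  0  5 ]\n"
            "G [ 15  0  5  5 ]\n"
            "T [  0  0  0 10 ]\n"
        )
        (m,) = read_jaspar_pfms(text)
        assert m.name == "TESTTF"
        assert m.width == 4
        assert m.consensus[1] == "C"


class TestScanMotifs:
    def test_consensus_embedded_matches(self, rng):
        motif = _random_motif(rng)
        seq = _random_seq(rng, 50) + motif.consensus + _random_seq(rng, 50)
        assert scan_motifs([seq], [motif]).iloc[0, 0]

    def test_reverse_complement_matches(self, rng):
        motif = _random_motif(rng)
        seq = _random_seq(rng, 40) + _revcomp(motif.consensus) + _random_seq(rng, 40)
        assert scan_motifs([seq], [motif]).iloc[0, 0]

    def test_all_n_sequence_no_match(self, rng):
        motif = _random_motif(rng)
        assert not scan_motifs(["N" * 100], [motif]).iloc[0, 0]

    def test_sequence_shorter_than_motif(self, rng):
        motif = _random_motif(rng, width=12)
        assert not scan_motifs(["ACGT"], [motif]).iloc[0, 0]

    def test_agrees_with_per_position_oracle(self, rng):
        motifs = [_random_motif(rng, f"M{i}", width=int(w))
                  for i, w in enumerate(rng.integers(5, 10, size=3))]
        seqs = [_random_seq(rng, int(n)) for n in rng.integers(20, 120, size=50)]
        # spike some consensus sequences in to get positives
        for i in range(0, 50, 7):
            seqs[i] = seqs[i] + motifs[i % 3].consensus
        result = scan_motifs(seqs, motifs)
        for i, seq in enumerate(seqs):
            for j, motif in enumerate(motifs):
                assert result.iloc[i, j] == _scan_oracle(seq, motif), (i, j)


class TestBackgroundPeaks:
    def test_identical_features_sample_uniformly(self, rng):
        gc = np.full(40, 0.5)
        acc = np.full(40, 2.0)
        bg = sample_background_peaks(gc, acc, n_bg=30, seed=0)
        assert bg.shape == (40, 30)
        for i in range(40):
            assert i not in bg[i]

    def test_seed_reproducibility(self, rng):
        gc = rng.random(200)
        acc = rng.gamma(1.0, 2.0, size=200)
        a = sample_background_peaks(gc, acc, seed=5)
        b = sample_background_peaks(gc, acc, seed=5)
        np.testing.assert_array_equal(a, b)

    def test_backgrounds_match_source_features(self, rng):
        gc = rng.random(500)
        acc = rng.gamma(1.0, 2.0, size=500)
        bg = sample_background_peaks(gc, acc, seed=1)
        gc_rank = np.argsort(np.argsort(gc)) / 500
        for i in range(0, 500, 17):
            # background GC stays in the neighborhood of the source peak's GC
            assert np.abs(gc_rank[bg[i]] - gc_rank[i]).mean() < 0.25

    def test_single_peak_rejected(self):
        with pytest.raises(ValueError):
            sample_background_peaks(np.array([0.5]), np.array([1.0]))


class TestChromVARDeviations:
    def test_all_peaks_motif_has_zero_raw_deviation(self, rng):
        counts = sp.csr_matrix(rng.poisson(3.0, size=(30, 20)).astype(float))
        matches = pd.DataFrame({"ALL": np.ones(30, dtype=bool),
                                "SOME": rng.random(30) < 0.4})
        bg = sample_background_peaks(rng.random(30), rng.gamma(1, 2, 30), n_bg=10, seed=0)
        dev = chromvar_deviations(counts, matches, bg)
        np.testing.assert_allclose(dev.raw["ALL"].to_numpy(), 0.0, atol=1e-12)

    def test_toy_raw_deviation_by_hand(self):
        # 3 peaks x 2 cells; motif matches peaks 0 and 2
        counts = np.array([[4.0, 1.0], [2.0, 2.0], [0.0, 3.0]])
        matches = pd.DataFrame({"M": [True, False, True]})
        bg = np.zeros((3, 5), dtype=int)  # backgrounds irrelevant for raw values
        bg[:] = [[1], [0], [1]]
        dev = chromvar_deviations(sp.csr_matrix(counts), matches, bg)
        # peak totals: 5, 4, 3; grand total 12; matched fraction = 8/12
        # cell totals: 6, 6 -> expected = 4 each; observed = 4, 4
        np.testing.assert_allclose(dev.raw["M"].to_numpy(), [0.0, 0.0], atol=1e-12)
        counts2 = counts.copy()
        counts2[0, 0] = 6.0  # cell 0: total 8, obs 6; fraction = 10/14
        dev2 = chromvar_deviations(sp.csr_matrix(counts2), matches, bg)
        expected0 = (6.0 - 8.0 * (10 / 14)) / (8.0 * (10 / 14))
        assert dev2.raw["M"].iloc[0] == pytest.approx(expected0, abs=1e-12)

    def test_planted_shift_recovered(self, small_cohort):
        from scipy.stats import mannwhitneyu

        cohort = small_cohort
        atac = cohort.atac
        bg = sample_background_peaks(
            atac.peak_gc, np.asarray(atac.counts.mean(axis=1)).ravel(), seed=2
        )
        dev = chromvar_deviations(atac.counts, cohort.motif_matches, bg,
                                  cells=atac.cells, seed=2)
        labels = atac.cell_meta["cell_type"].to_numpy()
        t, e = labels == "Tumor", labels == "Epithelial"
        zt_all, ze_all = [], []
        for motif in cohort.truth.true_tumor_tfs:
            raw = dev.raw[motif].to_numpy()
            assert np.nanmean(raw[t]) > np.nanmean(raw[e])
            z = dev.z[motif].to_numpy()
            zt_all.append(z[t][~np.isnan(z[t])])
            ze_all.append(z[e][~np.isnan(z[e])])
        # pooled over the planted motifs (per-motif power at this toy scale is
        # limited because planted peaks crowd the same accessibility stratum)
        p = mannwhitneyu(np.concatenate(zt_all), np.concatenate(ze_all),
                         alternative="greater").pvalue
        assert p < 0.01


class TestFootprint:
    def _uniform_fragments(self, rng, n, center=50_000, span=2000):
        start = rng.integers(center - span, center + span, size=n)
        length = rng.integers(30, 200, size=n)
        return pd.DataFrame({
            "chrom": "chr1", "start": start, "end": start + length,
            "barcode": "C1", "count": 1,
        })

    def test_flat_process_profile_near_one(self, rng):
        frags = self._uniform_fragments(rng, 300_000)
        sites = pd.DataFrame({"chrom": ["chr1"], "center": [50_000]})
        prof = footprint_profile(frags, sites, {"C1"})
        assert abs(prof.center_depth - 1.0) < 0.05
        assert np.abs(prof.smoothed(11) - 1.0).max() < 0.15

    def test_empty_cell_set_rejected(self, rng):
        frags = self._uniform_fragments(rng, 100)
        sites = pd.DataFrame({"chrom": ["chr1"], "center": [50_000]})
        with pytest.raises(ValueError):
            footprint_profile(frags, sites, set())

    def test_zero_flank_insertions_rejected(self):
        frags = pd.DataFrame({
            "chrom": ["chr1"], "start": [50_000], "end": [50_050],
            "barcode": ["C1"], "count": [1],
        })
        sites = pd.DataFrame({"chrom": ["chr1"], "center": [50_000]})
        with pytest.raises(ValueError, match="flank"):
            footprint_profile(frags, sites, {"C1"})

    def test_depth_scaling_invariance(self, rng):
        frags = self._uniform_fragments(rng, 50_000)
        doubled = pd.concat([frags, frags], ignore_index=True)
        sites = pd.DataFrame({"chrom": ["chr1"], "center": [50_000]})
        p1 = footprint_profile(frags, sites, {"C1"})
        p2 = footprint_profile(doubled, sites, {"C1"})
        np.testing.assert_allclose(p1.profile, p2.profile, atol=1e-12)

    def test_profile_length_validated(self):
        with pytest.raises(ValueError):
            FootprintProfile("M", "T", np.ones(100), 1, 1)


class TestTumorSpecificTFs:
    def test_tf_active_in_normal_excluded(self, rng):
        # build deviations where motif M0 is higher in normal epithelium
        n = 200
        labels = np.array(["Tumor"] * 100 + ["Epithelial"] * 100)
        z = rng.normal(size=(n, 2))
        z[100:, 0] += 3.0  # M0 up in normal
        z[:100, 1] += 3.0  # M1 up in tumor
        from creglink.tf import DeviationResult

        dev = DeviationResult(
            raw=pd.DataFrame(z, columns=["M0", "M1"]),
            z=pd.DataFrame(z, columns=["M0", "M1"]),
            backgrounds=np.zeros((1, 1), dtype=int),
        )
        prof_hi = FootprintProfile("x", "T", np.ones(501) * 2, 5, 100)
        prof_lo = FootprintProfile("x", "E", np.ones(501), 5, 100)
        footprints = {
            "M0": {"Tumor": prof_lo, "Epithelial": prof_hi},
            "M1": {"Tumor": prof_hi, "Epithelial": prof_lo},
        }
        expr = np.zeros((2, n))
        expr[0] = rng.normal(1.0, 0.1, n)
        expr[1, :100] = rng.normal(2.0, 0.1, 100)  # M1 gene up in tumor
        expr[1, 100:] = rng.normal(0.5, 0.1, 100)
        table = tumor_specific_tfs(
            dev, footprints, expr, pd.Index(["M0", "M1"]), labels
        )
        sel = set(table[table.selected]["motif"])
        assert sel == {"M1"}

    def test_tf_without_expression_record_fails_criterion(self, rng):
        from creglink.tf import DeviationResult

        labels = np.array(["Tumor"] * 50 + ["Epithelial"] * 50)
        z = np.zeros((100, 1))
        z[:50] += 3.0
        dev = DeviationResult(
            raw=pd.DataFrame(z, columns=["MX"]),
            z=pd.DataFrame(z, columns=["MX"]),
            backgrounds=np.zeros((1, 1), dtype=int),
        )
        prof_hi = FootprintProfile("x", "T", np.ones(501) * 2, 5, 100)
        prof_lo = FootprintProfile("x", "E", np.ones(501), 5, 100)
        footprints = {"MX": {"Tumor": prof_hi, "Epithelial": prof_lo}}
        table = tumor_specific_tfs(
            dev, footprints, np.zeros((1, 100)), pd.Index(["OTHER"]), labels
        )
        assert not table["selected"].any()
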