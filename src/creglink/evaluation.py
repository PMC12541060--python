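"""Benchmark scenarios that exercise the pipeline end-to-end on synthetic
cohorts with planted ground truth and report recovery/calibration metrics.

Each function builds its inputs from scratch with the given seed, runs the
relevant stages of the package and measures the outcome; nothing is cached or
looked up.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import kstest, mannwhitneyu

from . import coaccess as coaccess_mod
from . import linking, preprocess, programs, tf
from .simulate import SimulationConfig, plant_footprint, simulate_cohort

LINK_COHORT = dict(n_samples=4, n_cancer_types=2, cells_per_sample=1200)
TF_COHORT = dict(n_samples=2, n_cancer_types=1, cells_per_sample=1000)
NMF_COHORT = dict(n_samples=3, n_cancer_types=1)

TECHNICAL_NULL = dict(
    tf_activity_shift=1.0, dar_fold=1.0, program_strength=0.0,
    program_hierarchy=0.0, outlier_fraction=0.0, celltype_variation=0.0,
    state_amplitude_min=0.0, state_amplitude_max=1e-9, link_amplitude=1e-9,
    gene_state_scale=0.0, tf_expr_fold=1.0, footprint_dip=0.0,
    shoulder_insertions_per_site=0.0, rna_overdispersion=0.0,
)


def _prepare_grouped(cohort, seed: int, n_groups: int = 200):
    """Count-filter cells, build LSI metacells and aggregate both modalities."""
    totals = np.asarray(cohort.atac.counts.sum(axis=0)).ravel()
    rna_totals = np.asarray(cohort.rna.counts.sum(axis=0)).ravel()
    keep = (totals > 500) & (rna_totals > 0)
    atac = cohort.atac.subset_cells(keep)
    rna = cohort.rna.subset_cells(keep)
    emb = preprocess.lsi_embedding(atac, n_components=150, random_state=seed)
    mc = preprocess.make_metacells(emb, k=50, seed=seed, n_groups=n_groups)
    agg_a = np.asarray(preprocess.log_normalize(mc.aggregate(atac.counts)).todense())
    agg_r = np.asarray(preprocess.log_normalize(mc.aggregate(rna.counts)).todense())
    return atac, rna, mc, agg_a, agg_r


def _link_network(cohort, seed: int):
    atac, rna, mc, agg_a, agg_r = _prepare_grouped(cohort, seed)
    pairs = coaccess_mod.coaccess_scores(agg_a, atac.peaks)
    cand = linking.candidate_pairs(atac.peaks, rna.genes)
    corr = linking.grouped_correlation(cand, agg_a, agg_r, rna.genes.index)
    null = linking.build_null(atac.peaks, rna.genes, agg_a, agg_r, seed=seed + 1)
    mu0, sd0 = null.lookup(corr["gene"])
    corr["z"], corr["p"] = linking.null_significance(corr["r"].to_numpy(), mu0, sd0)
    network = linking.build_link_network(corr, pairs, atac.peaks, rna.genes)
    return atac, network, len(mc)


def run_null_link_benchmark(seed: int) -> dict:
    """Cohort without planted links: p-value uniformity and false-link rate."""
    cfg = SimulationConfig(seed=seed % 2**31, n_planted_links=0, **LINK_COHORT)
    cohort = simulate_cohort(cfg)
    _, network, n_groups = _link_network(cohort, seed + 7)
    rng = np.random.default_rng(seed + 13)
    sub = rng.choice(len(network), size=min(3000, len(network)), replace=False)
    ks = kstest(network["p"].to_numpy()[sub], "uniform")
    return {
        "ks_pvalue": float(ks.pvalue),
        "ks_statistic": float(ks.statistic),
        "reliable_fraction": float(network["reliable"].mean()),
        "n_candidate_pairs": int(len(network)),
        "n_groups": int(n_groups),
    }


def run_planted_link_benchmark(seed: int) -> dict:
    """Planted links at effect 0.6: recall and precision of reliable links."""
    cfg = SimulationConfig(seed=seed % 2**31, **LINK_COHORT)
    cohort = simulate_cohort(cfg)
    atac, network, n_groups = _link_network(cohort, seed + 7)
    peak_ids = atac.peak_ids
    truth = {(r.gene, r.peak) for r in cohort.truth.true_links.itertuples()}
    pred = {(r.gene, peak_ids[r.peak_index])
            for r in network[network["reliable"]].itertuples()}
    tp = len(truth & pred)
    return {
        "recall": tp / len(truth) if truth else float("nan"),
        "precision": tp / len(pred) if pred else float("nan"),
        "n_true_links": len(truth),
        "n_predicted": len(pred),
        "n_groups": int(n_groups),
    }


def run_chromvar_benchmark(seed: int) -> dict:
    """Deviation z calibration on a technical-null cohort plus planted-shift
    recovery, with the tumor/normal labels permuted for the null Wilcoxon."""
    null_cfg = SimulationConfig(seed=(seed + 1) % 2**31, **TF_COHORT, **TECHNICAL_NULL)
    null_cohort = simulate_cohort(null_cfg)
    atac = null_cohort.atac
    bg = tf.sample_background_peaks(
        atac.peak_gc, np.asarray(atac.counts.mean(axis=1)).ravel(), seed=seed)
    dev = tf.chromvar_deviations(atac.counts, null_cohort.motif_matches, bg, seed=seed)
    z = dev.z
    mean_abs_max = float(z.mean(axis=0).abs().max())
    sd = z.std(axis=0)
    # permuted labels: tumor-vs-normal comparison on the null z-scores
    rng = np.random.default_rng(seed + 3)
    labels = rng.permutation(atac.cell_meta["cell_type"].to_numpy())
    t, e = labels == "Tumor", labels == "Epithelial"
    perm_p = []
    for m in z.columns:
        zm = z[m].to_numpy()
        a, b = zm[t][~np.isnan(zm[t])], zm[e][~np.isnan(zm[e])]
        if len(a) >= 3 and len(b) >= 3:
            perm_p.append(mannwhitneyu(a, b, alternative="two-sided").pvalue)
    perm_fdr = linking.bh_adjust(np.array(perm_p))

    shift_cfg = SimulationConfig(seed=(seed + 2) % 2**31, **TF_COHORT)
    shift_cohort = simulate_cohort(shift_cfg)
    s_atac = shift_cohort.atac
    s_bg = tf.sample_background_peaks(
        s_atac.peak_gc, np.asarray(s_atac.counts.mean(axis=1)).ravel(), seed=seed)
    s_dev = tf.chromvar_deviations(s_atac.counts, shift_cohort.motif_matches,
                                   s_bg, seed=seed)
    s_labels = s_atac.cell_meta["cell_type"].to_numpy()
    st, se = s_labels == "Tumor", s_labels == "Epithelial"
    shift_p = []
    for m in shift_cohort.truth.true_tumor_tfs:
        zm = s_dev.z[m].to_numpy()
        a, b = zm[st][~np.isnan(zm[st])], zm[se][~np.isnan(zm[se])]
        shift_p.append(mannwhitneyu(a, b, alternative="greater").pvalue)
    return {
        "null_z_mean_abs_max": mean_abs_max,
        "null_z_sd_min": float(sd.min()),
        "null_z_sd_max": float(sd.max()),
        "permuted_label_min_fdr": float(perm_fdr.min()),
        "planted_shift_max_p": float(max(shift_p)),
    }


def run_footprint_benchmark(seed: int, n_fragments: int = 420_000) -> dict:
    """Uniform Tn5 insertion process with a planted half-depth footprint."""
    rng = np.random.default_rng(seed)
    center = 50_000
    start = rng.integers(center - 2000, center + 2000, size=n_fragments)
    length = rng.integers(30, 200, size=n_fragments)
    frags = pd.DataFrame({
        "chrom": "chr1", "start": start, "end": start + length,
        "barcode": "C1", "count": 1,
    })
    sites = pd.DataFrame({"chrom": ["chr1"], "center": [center]})
    dipped = plant_footprint(frags, sites, dip_depth=0.5, seed=seed + 1)
    prof = tf.footprint_profile(dipped, sites, {"C1"}, motif="M", cell_type="T")
    return {
        "center_depth": float(prof.center_depth),
        "n_insertions": int(prof.n_insertions),
    }


def run_tf_filter_benchmark(seed: int) -> dict:
    """Full triple filter: planted tumor TFs among decoys."""
    cfg = SimulationConfig(seed=seed % 2**31, **TF_COHORT)
    cohort = simulate_cohort(cfg)
    atac = cohort.atac
    bg = tf.sample_background_peaks(
        atac.peak_gc, np.asarray(atac.counts.mean(axis=1)).ravel(), seed=seed)
    dev = tf.chromvar_deviations(atac.counts, cohort.motif_matches, bg,
                                 cells=atac.cells, seed=seed)
    meta = atac.cell_meta
    profiles: dict[str, dict[str, tf.FootprintProfile]] = {}
    for motif, sites in cohort.motif_sites.groupby("motif"):
        profiles[motif] = {}
        for label in ("Tumor", "Epithelial"):
            cells = meta.index[meta["cell_type"] == label]
            try:
                profiles[motif][label] = tf.footprint_profile(
                    cohort.fragments, sites, cells, motif=motif, cell_type=label)
            except ValueError:
                continue
    lognorm_rna = np.asarray(preprocess.log_normalize(cohort.rna.counts).todense())
    table = tf.tumor_specific_tfs(
        dev, profiles, lognorm_rna, cohort.rna.genes.index,
        meta["cell_type"].to_numpy())
    selected = set(table[table["selected"]]["motif"])
    truth = set(cohort.truth.true_tumor_tfs)
    return {
        "n_planted": len(truth),
        "n_recovered": len(selected & truth),
        "n_false_positives": len(selected - truth),
    }


def run_nmf_benchmark(seed: int, n_k_seeds: int = 10, nrun: int = 10) -> dict:
    """Rank-selection recovery simulation over regenerated cohorts, plus
    meta-program assembly on the first cohort."""
    rng = np.random.default_rng(seed + 5)

    # (a) rank recovery: per trial, a fresh 3-sample cohort; the recovered
    # rank is the majority k* over the cohort's samples
    recovered = 0
    majorities: list[int] = []
    first_cohort = None
    planted_k = 0
    for _ in range(n_k_seeds):
        cfg = SimulationConfig(seed=int(rng.integers(0, 2**31 - 1)), **NMF_COHORT)
        trial_cohort = simulate_cohort(cfg)
        planted_k = cfg.n_planted_programs
        if first_cohort is None:
            first_cohort = trial_cohort
        t_meta = trial_cohort.rna.cell_meta
        t_rel = programs.relative_expression(
            trial_cohort.rna.counts, trial_cohort.rna.genes.index,
            trial_cohort.rna.cells, t_meta["sample"].to_numpy(),
            (t_meta["cell_type"] == "Tumor").to_numpy())
        ks = []
        for sample in sorted(t_rel):
            coph = {}
            for k in programs.K_RANGE:
                res = programs.nmf_consensus(
                    t_rel[sample], k, nrun=nrun,
                    seed=int(rng.integers(0, 2**31 - 1)), sample=sample)
                coph[k] = res.cophenetic
            ks.append(programs.select_k(coph))
        majority = int(pd.Series(ks).mode().iloc[0])
        majorities.append(majority)
        recovered += int(majority == planted_k)

    cohort = first_cohort
    meta = cohort.rna.cell_meta
    rel = programs.relative_expression(
        cohort.rna.counts, cohort.rna.genes.index, cohort.rna.cells,
        meta["sample"].to_numpy(), (meta["cell_type"] == "Tumor").to_numpy())

    # (b) full discovery + meta-program assembly
    # assembly uses the consensus rank across the recovery trials (the
    # pooled estimate is far more stable than any single sample's scan)
    consensus_k = int(pd.Series(majorities).mode().iloc[0])
    sigs, W_by, k_by = programs.discover_programs(
        rel, nrun=nrun, seed=seed + 9, fixed_k=consensus_k)
    metas = programs.meta_programs(sigs, rel, W_by, seed=seed + 11)
    truth_sets = {
        p: set(cohort.truth.true_programs.loc[
            (cohort.truth.true_programs["program"] == p)
            & (cohort.truth.true_programs["sample"] == "S1"), "gene"])
        for p in range(planted_k)
    }
    overlaps = []
    matched = set()
    for mp in metas:
        best_p, best_o = None, -1
        for p, ts in truth_sets.items():
            o = len(set(mp.signature) & ts)
            if o > best_o:
                best_p, best_o = p, o
        overlaps.append(best_o)
        matched.add(best_p)
    return {
        "k_recovery_fraction": recovered / n_k_seeds,
        "n_meta_programs": len(metas),
        "n_distinct_planted_matched": len(matched),
        "min_signature_overlap": int(min(overlaps)) if overlaps else 0,
        "all_clusters_multi_sample": bool(all(len(mp.samples) >= 2 for mp in metas)),
        "k_by_sample": k_by,
    }


def run_threshold_checks() -> dict:
    """Boundary-value fidelity of every printed threshold; returns pass counts."""
    from .preprocess import QCThresholds

    checks: list[bool] = []

    def qc_pass(modality, **metrics):
        thr = QCThresholds.default(modality)
        ok = True
        t = thr
        n = metrics.get("n_count")
        f = metrics.get("n_feature")
        if t.count_min is not None:
            ok &= n > t.count_min
        if t.count_max is not None:
            ok &= n < t.count_max
        if t.feature_min is not None and f is not None:
            ok &= f > t.feature_min
        if t.feature_max is not None and f is not None:
            ok &= f < t.feature_max
        if t.tss_min is not None:
            ok &= metrics.get("tss", 0) > t.tss_min
        if t.nucleosome_max is not None:
            ok &= metrics.get("nuc", 0) < t.nucleosome_max
        if t.mito_max_pct is not None:
            ok &= metrics.get("mito", 0) < t.mito_max_pct
        return bool(ok)

    # scATAC bounds: 2000/30,000 counts, nucleosome < 4, TSS > 2 (strict)
    checks.append(qc_pass("atac", n_count=2001, nuc=3.99, tss=2.01))
    checks.append(not qc_pass("atac", n_count=2000, nuc=1, tss=3))
    checks.append(not qc_pass("atac", n_count=30_000, nuc=1, tss=3))
    checks.append(not qc_pass("atac", n_count=2500, nuc=4.0, tss=3))
    checks.append(not qc_pass("atac", n_count=2500, nuc=1, tss=2.0))
    # scRNA bounds: 500/50,000 counts, 500/6,000 features, mito < 25
    checks.append(qc_pass("rna", n_count=501, n_feature=501, mito=24.9))
    checks.append(not qc_pass("rna", n_count=500, n_feature=700, mito=1))
    checks.append(not qc_pass("rna", n_count=50_000, n_feature=700, mito=1))
    checks.append(not qc_pass("rna", n_count=700, n_feature=500, mito=1))
    checks.append(not qc_pass("rna", n_count=700, n_feature=6000, mito=1))
    checks.append(not qc_pass("rna", n_count=700, n_feature=700, mito=25.0))
    # multiome bounds: ATAC 1,000/20,000; RNA 500/25,000
    checks.append(qc_pass("multiome_atac", n_count=1001, tss=2.5, mito=1))
    checks.append(not qc_pass("multiome_atac", n_count=20_000, tss=2.5, mito=1))
    checks.append(not qc_pass("multiome_atac", n_count=1000, tss=2.5, mito=1))
    checks.append(qc_pass("multiome_rna", n_count=501, n_feature=501, mito=1))
    checks.append(not qc_pass("multiome_rna", n_count=25_000, n_feature=700, mito=1))
    # 500 kb caps
    checks.append(coaccess_mod.WINDOW_SIZE == 500_000)
    checks.append(linking.LINK_WINDOW == 500_000)
    # 1000 trans-null peaks
    checks.append(linking.N_NULL_PEAKS == 1000)
    # co-accessibility > 0.2, FDR < 0.1 with the OC 0.2 override
    checks.append(linking.COACCESS_CUT == 0.2)
    checks.append(linking.FDR_CUT == 0.1)
    checks.append(linking.PER_CANCER_FDR.get("OC") == 0.2)
    # NMF defaults: k = 2..6, nrun = 30, top-100 signatures, > 500 tumor cells
    checks.append(list(programs.K_RANGE) == [2, 3, 4, 5, 6])
    checks.append(programs.NRUN == 30)
    checks.append(programs.TOP_N_GENES == 100)
    checks.append(programs.MIN_TUMOR_CELLS == 500)
    return {"n_checks": len(checks), "n_passed": int(sum(checks))}
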