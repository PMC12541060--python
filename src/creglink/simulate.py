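"""Synthetic paired scATAC/scRNA cohort with planted regulatory ground truth.

The generator emulates a multi-sample, multi-cancer-type tumor cohort:
~10 cell types (tumor, normal epithelium, immune and stromal compartments),
sparse Poisson counts over a small multi-chromosome genome, and planted
structure that every downstream stage can recover:

* peak-gene links — a per-cell latent factor couples an enhancer peak, the
  gene's promoter peak and the gene's expression so the grouped (metacell)
  Pearson correlation has expectation ~ ``link_effect_size``;
* tumor-specific TFs — peaks matched to the chosen motifs are amplified by
  ``tf_activity_shift`` in tumor cells, the TF genes are overexpressed there,
  and tumor-cell fragments carry a footprint (protected center, elevated
  shoulders) at the motif sites;
* cell-type/cancer-type differential peaks (planted DARs);
* intratumor expression programs mixed into tumor cells of every sample.

Non-planted peak-gene pairs are conditionally independent given cell type and
depth, which is what makes the trans-chromosomal null calibration exact here.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

from .regions import (
    AccessibilityMatrix,
    ExpressionMatrix,
    GenomicRegion,
)

CELL_TYPES = [
    "Tumor", "Epithelial", "Tcell", "Bcell", "Myeloid",
    "Fibroblast", "Myofibroblast", "Endothelial", "Plasma", "Mast",
]


class ConfigError(ValueError):
    """An infeasible simulation configuration."""


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort. Counts are per cohort unless noted."""

    n_samples: int = 4
    n_cancer_types: int = 2
    cells_per_sample: int = 1200
    n_peaks: int = 2000
    n_genes: int = 600
    n_motifs: int = 50
    fraction_tumor_cells: float = 0.45
    link_effect_size: float = 0.6
    n_planted_links: int = 50
    n_planted_programs: int = 4
    program_gene_count: int = 100
    tf_activity_shift: float = 2.0
    sparsity: float = 0.15
    seed: int = 0
    # secondary knobs (defaults are the cohort's fixed conditions)
    n_tumor_tfs: int = 5
    n_planted_dars: int = 60
    dar_fold: float = 6.0
    tf_expr_fold: float = 3.0
    program_strength: float = 5.0
    program_subvariant: float = 0.0
    program_hierarchy: float = 1.5
    parent_gene_count: int = 30
    outlier_fraction: float = 0.10
    outlier_gene_count: int = 40
    outlier_strength: float = 1.5
    enhancer_min_dist: int = 5_000
    enhancer_max_dist: int = 150_000
    n_state_dims: int = 128
    n_microstates: int = 120
    microstate_noise: float = 0.25
    state_amplitude_min: float = 0.5
    state_amplitude_max: float = 1.0
    gene_state_scale: float = 0.25
    link_amplitude: float = 1.0
    gene_spacing: int = 50_000
    n_chromosomes: int = 4
    n_mito_genes: int = 10
    atac_depth: float = 6000.0
    rna_depth: float = 3000.0
    fragments_per_cell: float = 250.0
    fraction_degraded: float = 0.08
    footprint_dip: float = 0.5
    shoulder_insertions_per_site: float = 12.0
    matches_per_motif: int = 40
    celltype_variation: float = 1.0
    overdispersion: float = 0.0  # ATAC lognormal rate noise sd; 0 = pure Poisson
    rna_overdispersion: float = 0.7  # RNA lognormal rate noise sd
    poisson_noise: bool = True  # False returns expected rates (diagnostic mode)

    def __post_init__(self):
        for name in ("n_samples", "n_cancer_types", "cells_per_sample", "n_peaks",
                     "n_genes", "n_motifs", "program_gene_count"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if not 0 < self.link_effect_size <= 1:
            raise ConfigError("link_effect_size must be in (0, 1]")
        if not 0 < self.sparsity < 1:
            raise ConfigError("sparsity must be in (0, 1)")
        if not 0 <= self.fraction_tumor_cells < 1:
            raise ConfigError("fraction_tumor_cells must be in [0, 1)")

    def to_yaml(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "SimulationConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class TruthTables:
    """Planted ground truth: links, tumor TFs, programs, DARs, degraded cells."""

    true_links: pd.DataFrame       # gene, peak, kind (enhancer|promoter), effect
    true_tumor_tfs: list[str]
    true_programs: pd.DataFrame    # sample, program, gene
    true_dars: pd.DataFrame        # peak, cell_type, cancer_type
    degraded_cells: list[str] = field(default_factory=list)


@dataclass
class Cohort:
    atac: AccessibilityMatrix
    rna: ExpressionMatrix
    fragments: pd.DataFrame
    motif_matches: pd.DataFrame   # peaks x motifs boolean, index = peak position
    motif_sites: pd.DataFrame     # motif, chrom, center, peak_index
    truth: TruthTables
    config: SimulationConfig


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _calibrate_sharpness(base: np.ndarray, ct_mult: np.ndarray, depth: float,
                         target: float) -> float:
    """Exponent tau on the base propensity such that the expected nonzero
    fraction of Poisson counts matches the target sparsity."""

    def expected_nonzero(tau: float) -> float:
        b = base ** tau
        rate = b[:, None] * ct_mult
        rate = rate / rate.sum(axis=0, keepdims=True) * depth
        return float(np.mean(1.0 - np.exp(-rate)))

    lo, hi = 0.05, 12.0
    if expected_nonzero(lo) < target:
        return lo
    if expected_nonzero(hi) > target:
        return hi
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if expected_nonzero(mid) > target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _unit_vector(rng, k: int) -> np.ndarray:
    v = rng.standard_normal(k)
    return v / np.linalg.norm(v)


# ---------------------------------------------------------------------------
# the generator
# ---------------------------------------------------------------------------

def simulate_cohort(config: SimulationConfig) -> Cohort:
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n_cells = cfg.n_samples * cfg.cells_per_sample

    # --- cells ------------------------------------------------------------
    samples = np.repeat([f"S{i+1}" for i in range(cfg.n_samples)], cfg.cells_per_sample)
    cancer_names = [f"C{chr(ord('A') + i)}" for i in range(cfg.n_cancer_types)]
    sample_cancer = {f"S{i+1}": cancer_names[i % cfg.n_cancer_types]
                     for i in range(cfg.n_samples)}
    cancers = np.array([sample_cancer[s] for s in samples])
    probs = np.empty(len(CELL_TYPES))
    probs[0] = cfg.fraction_tumor_cells
    probs[1] = min(0.15, (1 - cfg.fraction_tumor_cells) / 2)
    probs[2:] = (1.0 - probs[0] - probs[1]) / (len(CELL_TYPES) - 2)
    ct_codes = rng.choice(len(CELL_TYPES), size=n_cells, p=probs)
    cell_types = np.array(CELL_TYPES)[ct_codes]
    degraded = rng.random(n_cells) < cfg.fraction_degraded
    barcodes = [f"CELL{i:05d}-{samples[i]}" for i in range(n_cells)]
    cell_meta = pd.DataFrame({
        "cell_type": cell_types,
        "cancer_type": cancers,
        "sample": samples,
        "planted_quality": np.where(degraded, "degraded", "good"),
    }, index=barcodes)
    tumor_mask = cell_types == "Tumor"

    # --- genome layout ----------------------------------------------------
    chroms = [f"chr{i+1}" for i in range(cfg.n_chromosomes)]
    n_reg_genes = cfg.n_genes
    genes_per_chrom = int(np.ceil(n_reg_genes / cfg.n_chromosomes))
    gene_rows = []
    motif_names = [f"TF{i+1:03d}" for i in range(cfg.n_motifs)]
    if cfg.n_motifs > n_reg_genes:
        raise ConfigError("need n_genes >= n_motifs so every motif has a TF gene")
    g = 0
    for ci, chrom in enumerate(chroms):
        for j in range(genes_per_chrom):
            if g >= n_reg_genes:
                break
            name = motif_names[g] if g < cfg.n_motifs else f"G{g+1:04d}"
            tss = 150_000 + j * cfg.gene_spacing
            gene_rows.append((name, chrom, tss, "+" if (g % 2 == 0) else "-"))
            g += 1
    chrom_span = {c: 300_000 + genes_per_chrom * cfg.gene_spacing for c in chroms}
    for k in range(cfg.n_mito_genes):
        gene_rows.append((f"MT-{k+1}", chroms[k % len(chroms)],
                          chrom_span[chroms[k % len(chroms)]] - 5_000 - 137 * k, "+"))
    genes = pd.DataFrame(gene_rows, columns=["gene", "chrom", "tss", "strand"]) \
        .set_index("gene")

    # peaks: one promoter peak per regular gene + distal peaks
    peak_list: list[GenomicRegion] = []
    promoter_of: dict[str, int] = {}
    for name, row in genes.iterrows():
        if str(name).startswith("MT-"):
            continue
        peak_list.append(GenomicRegion(row["chrom"], int(row["tss"]) - 200,
                                       int(row["tss"]) + 300))
    n_promoters = len(peak_list)
    n_distal = cfg.n_peaks - n_promoters
    if n_distal < 1:
        raise ConfigError("n_peaks must exceed the number of promoter peaks")
    seen = {p.id for p in peak_list}
    tss_by_chrom = {ch: np.sort(genes.loc[genes["chrom"] == ch, "tss"].to_numpy())
                    for ch in chroms}
    per_chrom = int(np.ceil(n_distal / len(chroms)))
    for chrom in chroms:
        placed = 0
        tss_sorted = tss_by_chrom[chrom]
        while placed < per_chrom and len(peak_list) < cfg.n_peaks:
            start = int(rng.integers(1_000, chrom_span[chrom]))
            width = int(rng.integers(300, 800))
            center = start + width // 2
            # distal peaks stay clear of TSS pile-ups (promoter peaks cover those)
            j = np.searchsorted(tss_sorted, center)
            near = min(
                abs(center - tss_sorted[max(j - 1, 0)]),
                abs(center - tss_sorted[min(j, len(tss_sorted) - 1)]),
            ) if len(tss_sorted) else 10**9
            if near < 4000:
                continue
            r = GenomicRegion(chrom, start, start + width)
            if r.id in seen:
                continue
            seen.add(r.id)
            peak_list.append(r)
            placed += 1
    order = sorted(range(len(peak_list)),
                   key=lambda i: (peak_list[i].chrom, peak_list[i].start))
    peak_list = [peak_list[i] for i in order]
    peak_ids = [p.id for p in peak_list]
    pos_of = {pid: i for i, pid in enumerate(peak_ids)}
    for name, row in genes.iterrows():
        if str(name).startswith("MT-"):
            continue
        pid = GenomicRegion(row["chrom"], int(row["tss"]) - 200, int(row["tss"]) + 300).id
        promoter_of[str(name)] = pos_of[pid]
    n_peaks = len(peak_list)
    peak_centers = np.array([p.center for p in peak_list])
    peak_chroms = np.array([p.chrom for p in peak_list])
    peak_gc = rng.beta(5, 5, size=n_peaks)
    promoter_set = set(promoter_of.values())

    # --- motif matches and sites -------------------------------------------
    distal_idx = np.array([i for i in range(n_peaks) if i not in promoter_set])
    match = np.zeros((n_peaks, cfg.n_motifs), dtype=bool)
    for m in range(cfg.n_motifs):
        chosen = rng.choice(distal_idx, size=min(cfg.matches_per_motif, len(distal_idx)),
                            replace=False)
        match[chosen, m] = True
    motif_matches = pd.DataFrame(match, columns=motif_names)
    site_rows = []
    for m, mname in enumerate(motif_names):
        for i in np.flatnonzero(match[:, m]):
            jitter = int(rng.integers(-100, 101))
            site_rows.append((mname, peak_chroms[i], int(peak_centers[i]) + jitter, int(i)))
    motif_sites = pd.DataFrame(site_rows, columns=["motif", "chrom", "center", "peak_index"])
    true_tfs = sorted(rng.choice(motif_names, size=cfg.n_tumor_tfs, replace=False))
    tf_peak_mask = match[:, [motif_names.index(t) for t in true_tfs]].any(axis=1)

    # --- planted links ------------------------------------------------------
    # cell-state manifold: every cell sits in a K-dim latent space; each peak
    # and gene responds to the state along its own loading direction, so that
    # kNN metacells (which track state) preserve feature co-variation.
    K = cfg.n_state_dims
    centers = rng.standard_normal((K, cfg.n_microstates))
    microstate = rng.integers(0, cfg.n_microstates, size=n_cells)
    state = centers[:, microstate] \
        + cfg.microstate_noise * rng.standard_normal((K, n_cells))

    eligible_genes = [g for g in genes.index
                      if not str(g).startswith(("MT-", "TF"))]
    eligible_genes = list(np.array(eligible_genes, dtype=object)[
        rng.permutation(len(eligible_genes))])
    link_rows = []
    link_specs = []  # (gene, enh_idx, prom_idx, v_peak (K,), v_gene (K,))
    used_peaks: set[int] = set()
    rho = cfg.link_effect_size
    for gene in eligible_genes:
        if len(link_rows) // 2 >= cfg.n_planted_links:
            break
        row = genes.loc[gene]
        d = np.abs(peak_centers - int(row["tss"]))
        cand = np.flatnonzero(
            (peak_chroms == row["chrom"]) & (d >= cfg.enhancer_min_dist)
            & (d <= cfg.enhancer_max_dist) & ~tf_peak_mask
        )
        cand = [c for c in cand if c not in promoter_set and c not in used_peaks]
        if not cand:
            continue
        enh = int(rng.choice(cand))
        used_peaks.add(enh)
        prom = promoter_of[str(gene)]
        v_peak = _unit_vector(rng, K)
        ortho = _unit_vector(rng, K)
        ortho -= (ortho @ v_peak) * v_peak
        ortho /= np.linalg.norm(ortho)
        # metacell aggregation, counting noise, expression overdispersion and
        # the log transform attenuate the planted alignment by a known factor
        # (~0.78 under these study conditions); compensate so the realized
        # grouped correlation has expectation ~ link_effect_size
        rho_eff = min(1.0, rho / 0.78)
        v_gene = rho_eff * v_peak + np.sqrt(1.0 - rho_eff**2) * ortho
        link_specs.append((gene, enh, prom, v_peak, v_gene))
        link_rows.append((gene, peak_ids[enh], "enhancer", rho))
        link_rows.append((gene, peak_ids[prom], "promoter", rho))
    if len(link_rows) // 2 < cfg.n_planted_links:
        raise ConfigError(
            f"could only place {len(link_rows) // 2} of {cfg.n_planted_links} planted "
            "links; no eligible peaks within the enhancer distance band"
        )
    true_links = pd.DataFrame(link_rows, columns=["gene", "peak", "kind", "effect"])

    # --- planted DARs -------------------------------------------------------
    free_distal = np.array([i for i in distal_idx
                            if i not in used_peaks and not tf_peak_mask[i]])
    dar_peaks = rng.choice(free_distal, size=min(cfg.n_planted_dars, len(free_distal)),
                           replace=False)
    dar_rows = []
    for i in dar_peaks:
        ct = CELL_TYPES[int(rng.integers(0, len(CELL_TYPES)))]
        ca = cancer_names[int(rng.integers(0, cfg.n_cancer_types))]
        dar_rows.append((peak_ids[int(i)], int(i), ct, ca))
    true_dars = pd.DataFrame(dar_rows, columns=["peak", "peak_index", "cell_type",
                                                "cancer_type"])

    # --- planted programs ---------------------------------------------------
    link_genes = {r[0] for r in link_rows}
    program_pool = [g for g in genes.index
                    if not str(g).startswith(("MT-", "TF")) and g not in link_genes]
    need = cfg.n_planted_programs * cfg.program_gene_count
    if len(program_pool) < need:
        raise ConfigError(
            f"need {need} free genes for programs, only {len(program_pool)} available"
        )
    n_parents = (cfg.n_planted_programs + 1) // 2
    need_parent = n_parents * cfg.parent_gene_count if cfg.program_hierarchy > 0 else 0
    if len(program_pool) < need + need_parent:
        raise ConfigError(
            f"need {need + need_parent} free genes for programs, only "
            f"{len(program_pool)} available"
        )
    chosen = rng.choice(np.array(program_pool, dtype=object),
                        size=need + need_parent, replace=False)
    program_genes = {p: list(chosen[p * cfg.program_gene_count:(p + 1) * cfg.program_gene_count])
                     for p in range(cfg.n_planted_programs)}
    parent_genes = {
        q: list(chosen[need + q * cfg.parent_gene_count:
                       need + (q + 1) * cfg.parent_gene_count])
        for q in range(n_parents)
    } if cfg.program_hierarchy > 0 else {}
    prog_rows = [(f"S{i+1}", p, g)
                 for i in range(cfg.n_samples)
                 for p in range(cfg.n_planted_programs)
                 for g in program_genes[p]]
    true_programs = pd.DataFrame(prog_rows, columns=["sample", "program", "gene"])
    # per tumor cell: sparse nonnegative program loadings
    loadings = np.zeros((cfg.n_planted_programs, n_cells))
    t_idx = np.flatnonzero(tumor_mask)
    if len(t_idx):
        # balanced primary assignment plus a little cross-program mixing
        P = cfg.n_planted_programs
        primary = rng.permuted(np.resize(np.arange(P), len(t_idx)))
        mix = rng.dirichlet(np.full(P, 0.25), size=len(t_idx)).T
        onehot = np.zeros((P, len(t_idx)))
        onehot[primary, np.arange(len(t_idx))] = 1.0
        raw = 4.0 * onehot + mix
        loadings[:, t_idx] = raw / raw.sum(axis=0, keepdims=True)

    # --- ATAC rates ---------------------------------------------------------
    base_peak = rng.gamma(0.6, 1.0, size=n_peaks) + 1e-4
    base_peak[list(promoter_set)] *= 3.0
    # motif-bearing peaks are accessible chromatin by construction: TF motifs
    # matched inside called peaks should carry measurable Tn5 coverage
    matched_any = match.any(axis=1)
    base_peak[matched_any] = np.maximum(base_peak[matched_any],
                                        np.quantile(base_peak, 0.55))

    ct_mult = rng.gamma(16.0, 1.0 / 16.0, size=(n_peaks, len(CELL_TYPES))) \
        ** cfg.celltype_variation
    linked_peaks = sorted({x for _, e, p, *_ in link_specs for x in (e, p)})
    ct_mult[linked_peaks, :] = 1.0  # planted link peaks are cell-type-uniform
    base_peak[linked_peaks] = np.maximum(base_peak[linked_peaks],
                                         np.median(base_peak) * 3.0)
    tau = _calibrate_sharpness(base_peak, ct_mult, cfg.atac_depth, cfg.sparsity)
    base_sharp = base_peak ** tau
    # planted link peaks are highly accessible so counting noise does not
    # drown the planted covariation
    base_sharp[linked_peaks] = np.maximum(base_sharp[linked_peaks],
                                          np.quantile(base_sharp, 0.92))
    # planted DARs are accessible in their target population by definition
    dar_idx = true_dars["peak_index"].to_numpy()
    base_sharp[dar_idx] = np.maximum(base_sharp[dar_idx],
                                     np.quantile(base_sharp, 0.85))

    # state loadings: dense random directions, amplitude U(min, max)
    amp_p = rng.uniform(cfg.state_amplitude_min, cfg.state_amplitude_max, size=n_peaks)
    Vp = rng.standard_normal((n_peaks, K))
    Vp /= np.linalg.norm(Vp, axis=1, keepdims=True)
    for gene, enh, prom, v_peak, _v_gene in link_specs:
        Vp[enh] = v_peak
        Vp[prom] = v_peak
        amp_p[enh] = cfg.link_amplitude
        amp_p[prom] = cfg.link_amplitude
    Lp = amp_p[:, None] * Vp

    atac_rate = base_sharp[:, None] * ct_mult[:, ct_codes]
    atac_rate *= np.exp(Lp @ state - 0.5 * amp_p[:, None] ** 2)
    if cfg.tf_activity_shift != 1.0:
        atac_rate[np.ix_(tf_peak_mask, tumor_mask)] *= cfg.tf_activity_shift
    for _, i, ct, ca in true_dars.itertuples(index=False):
        cells_sel = (cell_types == ct) & (cancers == ca)
        atac_rate[i, cells_sel] *= cfg.dar_fold
    if cfg.overdispersion > 0:
        atac_rate *= np.exp(cfg.overdispersion * rng.standard_normal(atac_rate.shape)
                            - 0.5 * cfg.overdispersion ** 2)
    depth_atac = np.exp(rng.normal(np.log(cfg.atac_depth), 0.3, size=n_cells))
    depth_atac[degraded] *= 0.15
    atac_rate = atac_rate / atac_rate.sum(axis=0, keepdims=True) * depth_atac
    if cfg.poisson_noise:
        atac_counts = rng.poisson(atac_rate).astype(np.int64)
    else:
        atac_counts = atac_rate
    atac = AccessibilityMatrix(sp.csr_matrix(atac_counts), peak_list, barcodes,
                               cell_meta, peak_gc)

    # --- RNA rates ----------------------------------------------------------
    n_all_genes = len(genes)
    base_gene = rng.gamma(0.8, 1.0, size=n_all_genes) + 1e-4
    gct_mult = rng.gamma(16.0, 1.0 / 16.0, size=(n_all_genes, len(CELL_TYPES))) \
        ** cfg.celltype_variation
    gene_pos = {gname: i for i, gname in enumerate(genes.index)}
    mito_rows = [gene_pos[gname] for gname in genes.index if str(gname).startswith("MT-")]
    base_gene[mito_rows] = np.median(base_gene)
    gct_mult[mito_rows, :] = 1.0
    # TF genes are expressed at a sensible baseline (the filter's expression
    # criterion is about fold change, not detectability)
    tf_rows = [gene_pos[m] for m in motif_names]
    base_gene[tf_rows] = np.maximum(base_gene[tf_rows], np.quantile(base_gene, 0.7))
    gct_mult[tf_rows, :] = 1.0
    planted_gene_rows = sorted({gene_pos[gname] for gname, *_ in link_specs})
    gct_mult[planted_gene_rows, :] = 1.0
    base_gene[planted_gene_rows] = np.maximum(base_gene[planted_gene_rows],
                                              np.median(base_gene) * 3.0)
    amp_g = cfg.gene_state_scale * rng.uniform(
        cfg.state_amplitude_min, cfg.state_amplitude_max, size=n_all_genes)
    Vg = rng.standard_normal((n_all_genes, K))
    Vg /= np.linalg.norm(Vg, axis=1, keepdims=True)
    for gene, _enh, _prom, _v_peak, v_gene in link_specs:
        Vg[gene_pos[gene]] = v_gene
        amp_g[gene_pos[gene]] = cfg.link_amplitude
    # program genes vary by program membership alone, keeping the planted
    # factor blocks exchangeable for the consensus-NMF rank scan
    prog_rows = sorted({gene_pos[g] for gl in program_genes.values() for g in gl})
    amp_g[prog_rows] = 0.0
    Lg = amp_g[:, None] * Vg
    rna_rate = base_gene[:, None] * gct_mult[:, ct_codes]
    rna_rate *= np.exp(Lg @ state - 0.5 * amp_g[:, None] ** 2)
    for t in true_tfs:
        rna_rate[gene_pos[t], tumor_mask] *= cfg.tf_expr_fold
    # a two-level hierarchy: sibling programs (2q, 2q+1) share a weak parent
    # module, so coarse factorizations merge them the same way in every restart
    n_par = max(len(parent_genes), 1)
    primary_full = np.full(n_cells, -1)
    if len(t_idx):
        primary_full[t_idx] = primary
    for q, gl in parent_genes.items():
        rows = [gene_pos[gname] for gname in gl]
        members = (primary_full == 2 * q)
        if 2 * q + 1 < cfg.n_planted_programs:
            members |= primary_full == 2 * q + 1
        # graded parent strengths: coarse merges have a unique best order, so
        # every restart coarsens the hierarchy the same way; the boost is a
        # flat indicator so it adds no within-program gradient for spare
        # factors to latch onto
        strength = cfg.program_hierarchy * (1.4 - 0.8 * q / max(n_par - 1, 1))
        rna_rate[rows] *= 1.0 + strength * members[None, :].astype(float)
    for p, gl in program_genes.items():
        rows = [gene_pos[gname] for gname in gl]
        boost = 1.0 + cfg.program_strength * loadings[p][None, :]
        if cfg.program_subvariant > 0:
            # two weak sub-shades per program: at ranks above the planted one
            # the factorization has several near-equivalent refinements, so
            # restarts disagree and the consensus destabilizes
            delta = np.full(len(rows), cfg.program_subvariant)
            shade = np.where(rng.random(n_cells) < 0.5, 1.0, -1.0)
            boost = boost * (1.0 + delta[:, None] * shade[None, :]
                             * (loadings[p] > 0.3)[None, :])
        rna_rate[rows] *= boost
    # a few 'stressed' tumor cells carry private extreme gene programs; rank
    # scans above the planted rank chase these cells with init-dependent
    # membership, the way overfitted factors behave on real single-cell data
    if cfg.outlier_fraction > 0 and len(t_idx):
        n_out = int(round(cfg.outlier_fraction * len(t_idx)))
        out_cells = rng.choice(t_idx, size=n_out, replace=False)
        for oc in out_cells:
            gsel = rng.choice(n_all_genes, size=min(cfg.outlier_gene_count, n_all_genes),
                              replace=False)
            rna_rate[gsel, oc] *= np.exp(
                cfg.outlier_strength * np.abs(rng.standard_normal(len(gsel))))
    rna_rate[np.ix_(mito_rows, degraded)] *= 10.0
    if cfg.rna_overdispersion > 0:
        rna_rate *= np.exp(cfg.rna_overdispersion * rng.standard_normal(rna_rate.shape)
                           - 0.5 * cfg.rna_overdispersion ** 2)
    depth_rna = np.exp(rng.normal(np.log(cfg.rna_depth), 0.3, size=n_cells))
    depth_rna[degraded] *= 0.2
    rna_rate = rna_rate / rna_rate.sum(axis=0, keepdims=True) * depth_rna
    if cfg.poisson_noise:
        rna_counts = rng.poisson(rna_rate).astype(np.int64)
    else:
        rna_counts = rna_rate
    rna = ExpressionMatrix(sp.csr_matrix(rna_counts), genes, barcodes, cell_meta)

    # --- fragments ----------------------------------------------------------
    fragments = _simulate_fragments(cfg, rng, peak_list, peak_centers, genes,
                                    base_sharp, ct_mult, ct_codes, tf_peak_mask,
                                    tumor_mask, barcodes, degraded, chrom_span)
    planted_sites = motif_sites[motif_sites["motif"].isin(true_tfs)]
    tumor_barcodes = {barcodes[i] for i in np.flatnonzero(tumor_mask)}
    if len(planted_sites) and cfg.shoulder_insertions_per_site > 0 and tumor_mask.any():
        fragments = pd.concat([
            fragments,
            _shoulder_fragments(cfg, rng, planted_sites, barcodes, tumor_mask),
        ], ignore_index=True)
    if cfg.footprint_dip > 0 and len(planted_sites):
        fragments = plant_footprint(fragments, planted_sites, cfg.footprint_dip,
                                    active_barcodes=tumor_barcodes,
                                    seed=int(rng.integers(0, 2**31 - 1)))
    fragments = fragments.sort_values(["chrom", "start", "end", "barcode"],
                                      kind="stable").reset_index(drop=True)

    truth = TruthTables(
        true_links=true_links,
        true_tumor_tfs=list(true_tfs),
        true_programs=true_programs,
        true_dars=true_dars.drop(columns="peak_index"),
        degraded_cells=[barcodes[i] for i in np.flatnonzero(degraded)],
    )
    return Cohort(atac, rna, fragments, motif_matches, motif_sites, truth, cfg)


def _simulate_fragments(cfg, rng, peak_list, peak_centers, genes, base_sharp,
                        ct_mult, ct_codes, tf_peak_mask, tumor_mask, barcodes,
                        degraded, chrom_span):
    n_cells = len(barcodes)
    peak_chroms = np.array([p.chrom for p in peak_list])
    peak_width = np.array([p.length for p in peak_list])
    reg_genes = genes[~genes.index.str.startswith("MT-")]
    tss_pos = reg_genes["tss"].to_numpy()
    tss_chrom = reg_genes["chrom"].to_numpy()
    chrom_names = sorted(chrom_span)
    # per-cell-type peak sampling distribution (incl. the tumor TF shift)
    type_rate = base_sharp[:, None] * ct_mult
    type_rate_tumor = type_rate[:, 0].copy()
    type_rate_tumor[tf_peak_mask] *= cfg.tf_activity_shift
    type_probs = {}
    for t in range(ct_mult.shape[1]):
        r = type_rate_tumor if t == 0 else type_rate[:, t]
        type_probs[t] = r / r.sum()

    rows_chrom, rows_start, rows_end, rows_bc, rows_count = [], [], [], [], []
    n_frags = rng.poisson(cfg.fragments_per_cell, size=n_cells)
    for i in range(n_cells):
        k = int(n_frags[i])
        if k == 0:
            continue
        if degraded[i]:
            chrom_sel = rng.choice(len(chrom_names), size=k)
            pos = np.array([rng.integers(2_000, chrom_span[chrom_names[c]])
                            for c in chrom_sel])
            chrom_arr = np.array(chrom_names, dtype=object)[chrom_sel]
            mono = rng.random(k) < 0.85
        else:
            from_tss = rng.random(k) < 0.5
            n_tss = int(from_tss.sum())
            chrom_arr = np.empty(k, dtype=object)
            pos = np.empty(k, dtype=np.int64)
            if n_tss:
                gi = rng.integers(0, len(tss_pos), size=n_tss)
                pos[from_tss] = tss_pos[gi] + rng.normal(0, 200, size=n_tss).astype(int)
                chrom_arr[from_tss] = tss_chrom[gi]
            n_pk = k - n_tss
            if n_pk:
                pi = rng.choice(len(peak_list), size=n_pk, p=type_probs[ct_codes[i]])
                offset = rng.integers(-300, 300 + peak_width[pi])
                pos[~from_tss] = peak_centers[pi] - peak_width[pi] // 2 + offset
                chrom_arr[~from_tss] = peak_chroms[pi]
            mono = rng.random(k) < 0.25
        length = np.where(
            mono,
            np.clip(rng.normal(200, 30, size=k), 147, 294),
            np.clip(rng.normal(80, 25, size=k), 20, 146),
        ).astype(int)
        start = np.maximum(pos - length // 2, 1)
        rows_chrom.append(chrom_arr)
        rows_start.append(start)
        rows_end.append(start + length)
        rows_bc.append(np.repeat(barcodes[i], k))
        rows_count.append(1 + (rng.random(k) < 0.1).astype(int))
    return pd.DataFrame({
        "chrom": np.concatenate(rows_chrom),
        "start": np.concatenate(rows_start),
        "end": np.concatenate(rows_end),
        "barcode": np.concatenate(rows_bc),
        "count": np.concatenate(rows_count),
    })


def _shoulder_fragments(cfg, rng, planted_sites, barcodes, tumor_mask):
    """Extra tumor-cell insertions in the 10-60 bp shoulders around bound motif
    sites — the elevated local accessibility of an occupied TF site."""
    t_idx = np.flatnonzero(tumor_mask)
    rows = []
    for _, site in planted_sites.iterrows():
        n = rng.poisson(cfg.shoulder_insertions_per_site)
        if n == 0:
            continue
        offs = rng.integers(10, 61, size=n) * rng.choice([-1, 1], size=n)
        length = np.clip(rng.normal(80, 25, size=n), 20, 146).astype(int)
        cells = rng.choice(t_idx, size=n)
        left = rng.random(n) < 0.5  # which fragment end sits in the shoulder
        for o, ln, c, lf in zip(offs, length, cells, left):
            pos = int(site["center"]) + int(o)
            start = max(1, pos if lf else pos - int(ln))
            rows.append((site["chrom"], start, start + int(ln), barcodes[c], 1))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "barcode", "count"])


def plant_footprint(
    fragments: pd.DataFrame,
    motif_sites: pd.DataFrame,
    dip_depth: float,
    active_barcodes=None,
    seed: int = 0,
    halfwidth: int = 10,
) -> pd.DataFrame:
    """Scale Tn5 insertion probability by (1 - dip_depth) within +/- halfwidth bp
    of motif centers for the active cells.

    Each fragment end within a protected window independently survives with
    probability 1 - dip_depth; a fragment is kept only if both of its ends
    survive.
    """
    if not 0 <= dip_depth <= 1:
        raise ValueError("dip_depth must be in [0, 1]")
    if dip_depth == 0 or not len(motif_sites):
        return fragments.copy()
    rng = np.random.default_rng(seed)
    n = len(fragments)
    in_window = np.zeros(n, dtype=int)
    chrom_arr = fragments["chrom"].to_numpy()
    s_arr = fragments["start"].to_numpy()
    e_arr = fragments["end"].to_numpy() - 1
    for chrom, sites in motif_sites.groupby("chrom"):
        centers = np.sort(sites["center"].to_numpy())
        m = chrom_arr == chrom
        if not m.any():
            continue
        for ends in (s_arr, e_arr):
            p = ends[m]
            idx = np.searchsorted(centers, p)
            left = np.clip(idx - 1, 0, len(centers) - 1)
            right = np.clip(idx, 0, len(centers) - 1)
            dist = np.minimum(np.abs(p - centers[left]), np.abs(p - centers[right]))
            in_window[np.flatnonzero(m)[dist <= halfwidth]] += 1
    if active_barcodes is not None:
        active = fragments["barcode"].isin(set(active_barcodes)).to_numpy()
        in_window = np.where(active, in_window, 0)
    keep_prob = (1.0 - dip_depth) ** in_window
    keep = rng.random(n) < keep_prob
    return fragments.loc[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# on-disk cohort
# ---------------------------------------------------------------------------

def write_cohort(cohort: Cohort, out_dir: str | os.PathLike) -> None:
    """Emit the cohort in the exact formats the readers consume, plus truth TSVs."""
    out = str(out_dir)
    os.makedirs(out, exist_ok=True)
    scipy.io.mmwrite(os.path.join(out, "atac.mtx"),
                     sp.coo_matrix(cohort.atac.counts))
    with open(os.path.join(out, "peaks.bed"), "w") as fh:
        for i, p in enumerate(cohort.atac.peaks):
            gc = cohort.atac.peak_gc[i] if cohort.atac.peak_gc is not None else 0.5
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.id}\t{gc:.6f}\n")
    with open(os.path.join(out, "atac_barcodes.tsv"), "w") as fh:
        fh.write("\n".join(cohort.atac.cells) + "\n")
    cohort.atac.cell_meta.to_csv(os.path.join(out, "cell_meta.tsv"), sep="\t")
    scipy.io.mmwrite(os.path.join(out, "rna.mtx"), sp.coo_matrix(cohort.rna.counts))
    cohort.rna.genes.to_csv(os.path.join(out, "genes.tsv"), sep="\t")
    with open(os.path.join(out, "rna_barcodes.tsv"), "w") as fh:
        fh.write("\n".join(cohort.rna.cells) + "\n")
    cohort.fragments.to_csv(os.path.join(out, "fragments.tsv"),
                            sep="\t", header=False, index=False)
    cohort.motif_matches.astype(int).to_csv(os.path.join(out, "motif_matches.tsv"),
                                            sep="\t")
    cohort.motif_sites.to_csv(os.path.join(out, "motif_sites.tsv"), sep="\t", index=False)
    cohort.truth.true_links.to_csv(os.path.join(out, "truth_links.tsv"),
                                   sep="\t", index=False)
    pd.Series(cohort.truth.true_tumor_tfs, name="motif").to_csv(
        os.path.join(out, "truth_tumor_tfs.tsv"), sep="\t", index=False)
    cohort.truth.true_programs.to_csv(os.path.join(out, "truth_programs.tsv"),
                                      sep="\t", index=False)
    cohort.truth.true_dars.to_csv(os.path.join(out, "truth_dars.tsv"),
                                  sep="\t", index=False)
    pd.Series(cohort.truth.degraded_cells, name="barcode").to_csv(
        os.path.join(out, "truth_degraded.tsv"), sep="\t", index=False)
    cohort.config.to_yaml(os.path.join(out, "config.yaml"))
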