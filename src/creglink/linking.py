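"""Peak-gene linkage with a trans-chromosomal null calibration.

For every candidate peak-gene pair (peak center within +/- 500 kb of the
strand-aware TSS, same chromosome), the Pearson correlation ``r`` between
log-normalized metacell accessibility and expression is converted to a
z-score against an empirical null built from correlations of the gene with
1000 peaks on other chromosomes: ``z = (r - mu0) / sd0``. Two-sided normal
p-values are pooled across all pairs of a cohort and BH-adjusted. A link is
*reliable* when FDR < 0.1 (0.2 for the OC cohort) and the peak's
co-accessibility with a promoter peak of the gene exceeds 0.2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .regions import GenomicRegion

log = logging.getLogger(__name__)

LINK_WINDOW = 500_000
N_NULL_PEAKS = 1000
FDR_CUT = 0.1
COACCESS_CUT = 0.2
PER_CANCER_FDR = {"OC": 0.2}


# ---------------------------------------------------------------------------
# candidate enumeration
# ---------------------------------------------------------------------------

def candidate_pairs(
    peaks: list[GenomicRegion],
    genes: pd.DataFrame,
    window: int = LINK_WINDOW,
) -> pd.DataFrame:
    """All (peak_index, gene) pairs with the peak center within TSS +/- window,
    on the gene's chromosome. ``genes`` is indexed by symbol with chrom/tss columns."""
    centers = np.array([p.center for p in peaks])
    chroms = np.array([p.chrom for p in peaks])
    rows = []
    for chrom in genes["chrom"].unique():
        pk = np.flatnonzero(chroms == chrom)
        if not len(pk):
            continue
        c = centers[pk]
        order = np.argsort(c)
        pk, c = pk[order], c[order]
        sub = genes[genes["chrom"] == chrom]
        for gene, row in sub.iterrows():
            tss = int(row["tss"])
            lo = np.searchsorted(c, tss - window, side="left")
            hi = np.searchsorted(c, tss + window, side="right")
            for k in range(lo, hi):
                rows.append((int(pk[k]), gene, int(c[k]) - tss))
    return pd.DataFrame(rows, columns=["peak_index", "gene", "tss_distance"])


# ---------------------------------------------------------------------------
# grouped correlation
# ---------------------------------------------------------------------------

def _standardize_rows(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1)
    Xc = X - mu
    ok = sd > 0
    sd_safe = np.where(ok, sd, 1.0)
    return Xc / sd_safe[:, None], ok


def grouped_correlation(
    pairs: pd.DataFrame,
    acc_groups: np.ndarray,
    expr_groups: np.ndarray,
    gene_order: pd.Index,
) -> pd.DataFrame:
    """Pearson r across metacell groups for each candidate pair.

    ``acc_groups`` is (peaks x groups) and ``expr_groups`` (genes x groups)
    log-normalized aggregated data with identical group order. Pairs where
    either vector has zero variance are dropped (logged).
    """
    n_groups = acc_groups.shape[1]
    if n_groups < 3:
        raise ValueError("need at least 3 metacell groups")
    if expr_groups.shape[1] != n_groups:
        raise ValueError("group order/count must match across modalities")
    Za, ok_a = _standardize_rows(np.asarray(acc_groups, dtype=float))
    Zg, ok_g = _standardize_rows(np.asarray(expr_groups, dtype=float))
    gene_idx = gene_order.get_indexer(pairs["gene"])
    if (gene_idx < 0).any():
        raise KeyError("pair gene missing from expression matrix")
    pi = pairs["peak_index"].to_numpy()
    usable = ok_a[pi] & ok_g[gene_idx]
    if (~usable).any():
        log.info("dropping %d zero-variance pairs", int((~usable).sum()))
    out = pairs.loc[usable].copy()
    r = np.einsum("ij,ij->i", Za[pi[usable]], Zg[gene_idx[usable]]) / n_groups
    out["r"] = np.clip(r, -1.0, 1.0)
    return out


# ---------------------------------------------------------------------------
# trans-chromosomal null
# ---------------------------------------------------------------------------

@dataclass
class NullModel:
    """Per-gene null mean/sd of trans-chromosome correlations.

    Null peaks are sampled once per chromosome (the same set serves every gene
    on that chromosome).
    """

    mu0: pd.Series
    sd0: pd.Series
    null_peaks: dict[str, np.ndarray] = field(default_factory=dict)
    seed: int = 0

    def lookup(self, genes) -> tuple[np.ndarray, np.ndarray]:
        return self.mu0.loc[genes].to_numpy(), self.sd0.loc[genes].to_numpy()


def build_null(
    peaks: list[GenomicRegion],
    genes: pd.DataFrame,
    acc_groups: np.ndarray,
    expr_groups: np.ndarray,
    n_null: int = N_NULL_PEAKS,
    seed: int = 0,
) -> NullModel:
    """Sample ``n_null`` off-chromosome peaks per chromosome and correlate them
    with every gene of that chromosome; record per-gene mean and sd."""
    rng = np.random.default_rng(seed)
    chroms = np.array([p.chrom for p in peaks])
    Za, ok_a = _standardize_rows(np.asarray(acc_groups, dtype=float))
    Zg, _ = _standardize_rows(np.asarray(expr_groups, dtype=float))
    n_groups = Za.shape[1]
    mu0 = pd.Series(index=genes.index, dtype=float)
    sd0 = pd.Series(index=genes.index, dtype=float)
    null_sets: dict[str, np.ndarray] = {}
    for chrom in genes["chrom"].unique():
        trans = np.flatnonzero((chroms != chrom) & ok_a)
        if len(trans) == 0:
            raise ValueError(f"no usable trans peaks for chromosome {chrom}")
        if len(trans) >= n_null:
            chosen = rng.choice(trans, size=n_null, replace=False)
        else:
            log.warning(
                "chromosome %s has only %d trans peaks; sampling with replacement",
                chrom, len(trans),
            )
            chosen = rng.choice(trans, size=n_null, replace=True)
        null_sets[chrom] = np.sort(chosen)
        gsel = genes.index[genes["chrom"] == chrom]
        gi = genes.index.get_indexer(gsel)
        R = (Zg[gi] @ Za[chosen].T) / n_groups  # genes x n_null
        mu0.loc[gsel] = R.mean(axis=1)
        sd = R.std(axis=1)
        if np.any(sd == 0):
            raise ValueError(f"degenerate null (sd=0) on chromosome {chrom}")
        sd0.loc[gsel] = sd
    return NullModel(mu0, sd0, null_sets, seed)


def null_significance(r: np.ndarray, mu0: np.ndarray, sd0: np.ndarray):
    """z = (r - mu0)/sd0 with a two-sided standard-normal p-value."""
    sd0 = np.asarray(sd0, dtype=float)
    if np.any(sd0 <= 0):
        raise ValueError("null standard deviation must be positive")
    z = (np.asarray(r, dtype=float) - np.asarray(mu0, dtype=float)) / sd0
    p = 2.0 * norm.sf(np.abs(z))
    return z, np.clip(p, 0.0, 1.0)


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, clipped to 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# network assembly
# ---------------------------------------------------------------------------

def find_promoter_peaks(
    peaks: list[GenomicRegion],
    genes: pd.DataFrame,
    promoter_window: int = 2000,
) -> dict[str, list[int]]:
    """Peak indices overlapping TSS +/- promoter_window/2 per gene, nearest first."""
    half = promoter_window // 2
    centers = np.array([p.center for p in peaks])
    chroms = np.array([p.chrom for p in peaks])
    starts = np.array([p.start for p in peaks])
    ends = np.array([p.end for p in peaks])
    result: dict[str, list[int]] = {}
    for gene, row in genes.iterrows():
        tss = int(row["tss"])
        mask = (chroms == row["chrom"]) & (starts < tss + half) & (ends > tss - half)
        idx = np.flatnonzero(mask)
        if len(idx):
            idx = idx[np.argsort(np.abs(centers[idx] - tss), kind="stable")]
            result[gene] = [int(i) for i in idx]
    return result


def build_link_network(
    correlated_pairs: pd.DataFrame,
    coaccess_pairs: pd.DataFrame,
    peaks: list[GenomicRegion],
    genes: pd.DataFrame,
    promoter_window: int = 2000,
    fdr_cut: float = FDR_CUT,
    coaccess_cut: float = COACCESS_CUT,
    cancer_label: str | None = None,
) -> pd.DataFrame:
    """Assemble the reliable peak-gene link network.

    ``correlated_pairs`` must carry peak_index, gene, r, z, p columns (from
    :func:`grouped_correlation` + :func:`null_significance`); BH adjustment is
    applied jointly across all pairs here. ``coaccess_pairs`` is the frame from
    :mod:`creglink.coaccess`. A peak that is itself a promoter peak of the gene
    has promoter co-accessibility 1 by convention. Genes without a promoter
    peak are excluded (logged). For cancer label "OC" the FDR cutoff is 0.2.
    """
    if cancer_label in PER_CANCER_FDR:
        fdr_cut = PER_CANCER_FDR[cancer_label]
        log.info("cancer %s: FDR cutoff override -> %.3g", cancer_label, fdr_cut)
    df = correlated_pairs.copy()
    df["fdr"] = bh_adjust(df["p"].to_numpy())

    promoters = find_promoter_peaks(peaks, genes, promoter_window)
    dropped = set(df["gene"]) - set(promoters)
    if dropped:
        log.info("excluding %d genes without a promoter peak", len(dropped))
    df = df[df["gene"].isin(promoters)].copy()

    # symmetric lookup of co-accessibility scores
    co: dict[tuple[int, int], float] = {}
    for pi, pj, s in zip(
        coaccess_pairs["peak_i"], coaccess_pairs["peak_j"], coaccess_pairs["score"]
    ):
        co[(int(pi), int(pj))] = float(s)
        co[(int(pj), int(pi))] = float(s)

    coacc = np.full(len(df), -np.inf)
    for row_i, (pk, gene) in enumerate(zip(df["peak_index"], df["gene"])):
        prom = promoters[gene]
        if pk in prom:
            coacc[row_i] = 1.0
            continue
        best = -np.inf
        for pp in prom:
            s = co.get((int(pk), pp))
            if s is not None and s > best:
                best = s
        coacc[row_i] = best
    df["coaccess"] = np.where(np.isfinite(coacc), coacc, np.nan)
    df["reliable"] = (df["fdr"] < fdr_cut) & (df["coaccess"] > coaccess_cut)

    tss = genes.loc[df["gene"], "tss"].to_numpy().astype(int)
    df["peak_chrom"] = [peaks[i].chrom for i in df["peak_index"]]
    df["peak_start"] = [peaks[i].start for i in df["peak_index"]]
    df["peak_end"] = [peaks[i].end for i in df["peak_index"]]
    df["tss_chrom"] = genes.loc[df["gene"], "chrom"].to_numpy()
    df["tss_start"] = tss
    df["tss_end"] = tss + 1
    return df.reset_index(drop=True)


def candidate_tfs_for_gene(
    network: pd.DataFrame,
    motif_matches: pd.DataFrame,
    gene: str,
) -> list[str]:
    """Union of motifs matched in any reliable peak linked to ``gene``.

    ``motif_matches`` is a boolean (peak_index x motif) frame indexed by the
    global peak index. Returns an empty list for genes absent from the network.
    """
    sub = network[(network["gene"] == gene) & network["reliable"]]
    if not len(sub):
        return []
    motifs: set[str] = set()
    for pk in sub["peak_index"].unique():
        if pk in motif_matches.index:
            row = motif_matches.loc[pk]
            motifs.update(row.index[row.astype(bool)])
    return sorted(motifs)
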