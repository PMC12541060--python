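"""Differential accessible regions (DARs), cancer-exclusive DARs, iterative
overlap merging and cell-type-conserved regulatory regions.

DARs are one-vs-rest positive markers: a Wilcoxon rank-sum test on
log-normalized accessibility of each cell type against all remaining cells,
BH-corrected across tested peaks, gated pre-test on detection fraction and
log2 fold change. Cancer-exclusive DARs are those with no >= 1 bp overlap with
a same-cell-type DAR from any other cancer type.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import mannwhitneyu, rankdata

from .regions import GenomicRegion, overlap_regions

log = logging.getLogger(__name__)

EXACT_MAX_N = 16  # exact permutation-null enumeration below this total sample size


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------

def wilcoxon_exact_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact Wilcoxon rank-sum p-value by enumerating all label splits.

    Handles ties correctly via midranks (unlike the closed-form exact
    distribution). Intended for total sample sizes <= ~16.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    n, n1 = len(pooled), len(x)
    ranks = rankdata(pooled)
    obs = ranks[:n1].sum()
    center = n1 * (n + 1) / 2.0
    obs_dev = abs(obs - center)
    hits = 0
    total = comb(n, n1)
    for idx in combinations(range(n), n1):
        s = ranks[list(idx)].sum()
        if abs(s - center) >= obs_dev - 1e-9:
            hits += 1
    return hits / total


def _wilcoxon_asymptotic(X_in: np.ndarray, X_out: np.ndarray) -> np.ndarray:
    res = mannwhitneyu(X_in, X_out, axis=-1, alternative="two-sided", method="asymptotic")
    return np.atleast_1d(res.pvalue)


@dataclass
class DARRecord:
    peak: GenomicRegion
    cell_type: str
    cancer_type: str | None
    log2_fc: float
    p: float
    fdr: float
    pct_in: float
    pct_out: float


def find_dars(
    lognorm: np.ndarray | sp.spmatrix,
    peaks: list[GenomicRegion],
    labels: np.ndarray | pd.Series,
    min_pct: float = 0.05,
    logfc_min: float = 0.25,
    fdr_max: float = 0.05,
    cancer_type: str | None = None,
) -> pd.DataFrame:
    """One-vs-rest positive-marker Wilcoxon test per cell type.

    ``lognorm`` is log-normalized accessibility (peaks x cells). Pre-test gates:
    detection fraction in the target type >= ``min_pct`` and log2 fold change
    (on expm1-means with pseudocount 1) >= ``logfc_min``. BH is applied across
    the tested peaks of each cell type; rows with fdr < ``fdr_max`` are returned.
    """
    from .linking import bh_adjust

    labels = np.asarray(labels)
    types = pd.unique(labels)
    if len(types) < 2:
        raise ValueError("need at least 2 cell types")
    X = lognorm.toarray() if sp.issparse(lognorm) else np.asarray(lognorm, dtype=float)
    rows = []
    for ct in types:
        mask = labels == ct
        n_in, n_out = int(mask.sum()), int((~mask).sum())
        if n_in < 3 or n_out < 3:
            log.info("skipping cell type %s with too few cells", ct)
            continue
        Xi, Xo = X[:, mask], X[:, ~mask]
        pct_in = (Xi > 0).mean(axis=1)
        pct_out = (Xo > 0).mean(axis=1)
        mean_in = np.expm1(Xi).mean(axis=1)
        mean_out = np.expm1(Xo).mean(axis=1)
        log2_fc = np.log2((mean_in + 1.0) / (mean_out + 1.0))
        tested = (pct_in >= min_pct) & (log2_fc >= logfc_min)
        if not tested.any():
            continue
        t_idx = np.flatnonzero(tested)
        if n_in + n_out <= EXACT_MAX_N:
            p = np.array([wilcoxon_exact_p(Xi[i], Xo[i]) for i in t_idx])
        else:
            p = _wilcoxon_asymptotic(Xi[t_idx], Xo[t_idx])
        fdr = bh_adjust(p)
        for j, i in enumerate(t_idx):
            if fdr[j] < fdr_max:
                rows.append((
                    peaks[i].id, i, ct, cancer_type, float(log2_fc[i]),
                    float(p[j]), float(fdr[j]), float(pct_in[i]), float(pct_out[i]),
                ))
    return pd.DataFrame(
        rows,
        columns=["peak", "peak_index", "cell_type", "cancer_type",
                 "log2_fc", "p", "fdr", "pct_in", "pct_out"],
    )


# ---------------------------------------------------------------------------
# cancer-exclusive DARs
# ---------------------------------------------------------------------------

def cancer_specific_dars(dars: pd.DataFrame, cell_type: str):
    """Cancer-exclusive DARs of one cell type, plus the mean exclusive proportion.

    A DAR is exclusive to its cancer iff it has no >= 1 bp overlap with any
    same-cell-type DAR from another cancer. The proportion is
    exclusive/total per cancer, averaged over cancers with any DARs.
    """
    sub = dars[dars["cell_type"] == cell_type]
    cancers = list(pd.unique(sub["cancer_type"]))
    regions = {
        ca: [GenomicRegion.from_id(p) for p in sub.loc[sub["cancer_type"] == ca, "peak"]]
        for ca in cancers
    }
    specific_rows = []
    proportions = []
    for ca in cancers:
        own = regions[ca]
        if not own:
            continue
        others: list[GenomicRegion] = []
        for cb in cancers:
            if cb != ca:
                others.extend(regions[cb])
        if others:
            hit = np.zeros(len(own), dtype=bool)
            for i, _ in overlap_regions(own, others, min_bp=1):
                hit[i] = True
        else:
            hit = np.zeros(len(own), dtype=bool)
        keep = ~hit
        proportions.append(keep.mean())
        block = sub[sub["cancer_type"] == ca].iloc[np.flatnonzero(keep)]
        specific_rows.append(block)
    specific = pd.concat(specific_rows) if specific_rows else sub.iloc[:0]
    mean_prop = float(np.mean(proportions)) if proportions else float("nan")
    return specific.reset_index(drop=True), mean_prop


# ---------------------------------------------------------------------------
# iterative overlap merging (ArchR-style)
# ---------------------------------------------------------------------------

def iterative_overlap_merge(
    regions: list[GenomicRegion],
    scores: np.ndarray,
    tiebreak: np.ndarray | None = None,
) -> list[int]:
    """Greedy score-ranked selection of mutually non-overlapping regions.

    Repeatedly keep the highest-scoring remaining region and discard every
    region overlapping it by >= 1 bp. Ties break on ``tiebreak`` (larger wins,
    e.g. log2 fold change), then on coordinate order. Returns the kept indices
    in genomic order.
    """
    scores = np.asarray(scores, dtype=float)
    if len(scores) != len(regions):
        raise ValueError("scores and regions must align")
    tb = np.zeros(len(regions)) if tiebreak is None else np.asarray(tiebreak, dtype=float)
    order = sorted(
        range(len(regions)),
        key=lambda i: (-scores[i], -tb[i], regions[i].chrom, regions[i].start, regions[i].end),
    )
    kept: list[int] = []
    kept_by_chrom: dict[str, list[int]] = {}
    for i in order:
        r = regions[i]
        clash = False
        for j in kept_by_chrom.get(r.chrom, ()):  # few kept per chromosome at desk scale
            if r.overlap_length(regions[j]) >= 1:
                clash = True
                break
        if not clash:
            kept.append(i)
            kept_by_chrom.setdefault(r.chrom, []).append(i)
    kept.sort(key=lambda i: (regions[i].chrom, regions[i].start, regions[i].end))
    return kept


# ---------------------------------------------------------------------------
# cell-type-conserved regulatory regions
# ---------------------------------------------------------------------------

def conserved_regulatory_regions(
    link_peaks_by_cancer: dict[str, list[GenomicRegion]],
    dars_by_cancer: dict[str, list[GenomicRegion]],
    link_scores_by_cancer: dict[str, np.ndarray] | None = None,
) -> list[GenomicRegion]:
    """Cell-type-conserved regulatory regions across cancer types.

    Per cancer, cell-type-associated regulatory regions are the reliable-link
    peaks with >= 1 bp overlap to that cancer's cell-type DARs. The pooled
    regions are reduced to a non-overlapping set by iterative overlap merging
    (scored by each region's per-cancer rank weight), and a merged region is
    retained only when it overlaps regulatory regions from >= 2 cancer types.
    """
    cancers = sorted(link_peaks_by_cancer)
    if len(cancers) < 2:
        raise ValueError("need at least 2 cancer types")
    assoc: dict[str, list[GenomicRegion]] = {}
    assoc_scores: dict[str, np.ndarray] = {}
    for ca in cancers:
        link_peaks = link_peaks_by_cancer[ca]
        dars = dars_by_cancer.get(ca, [])
        raw_scores = None
        if link_scores_by_cancer is not None and ca in link_scores_by_cancer:
            raw_scores = np.asarray(link_scores_by_cancer[ca], dtype=float)
        if not link_peaks or not dars:
            assoc[ca] = []
            assoc_scores[ca] = np.array([])
            continue
        pairs = overlap_regions(link_peaks, dars, min_bp=1)
        keep = sorted({i for i, _ in pairs})
        assoc[ca] = [link_peaks[i] for i in keep]
        if raw_scores is not None:
            assoc_scores[ca] = raw_scores[keep]
        else:
            assoc_scores[ca] = np.array([link_peaks[i].length for i in keep], dtype=float)

    pooled: list[GenomicRegion] = []
    pooled_cancer: list[str] = []
    pooled_scores: list[float] = []
    for ca in cancers:
        pooled.extend(assoc[ca])
        pooled_cancer.extend([ca] * len(assoc[ca]))
        pooled_scores.extend(assoc_scores[ca].tolist())
    if not pooled:
        return []
    kept_idx = iterative_overlap_merge(pooled, np.array(pooled_scores))
    unified = [pooled[i] for i in kept_idx]

    conserved: list[GenomicRegion] = []
    for region in unified:
        support = set()
        for r, ca in zip(pooled, pooled_cancer):
            if region.overlap_length(r) >= 1:
                support.add(ca)
        if len(support) >= 2:
            conserved.append(region)
    return conserved
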