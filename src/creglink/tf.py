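"""Motif scanning, chromVAR-style motif deviations, Tn5 footprinting and the
tumor-specific transcription factor filter.

The deviation of motif *m* in cell *c* compares the reads observed in
motif-matched peaks with the depth-weighted expectation,
``d_cm = (obs_cm - exp_cm) / exp_cm``, and is bias-corrected into a z-score
against background peak sets matched on GC content and mean accessibility.
A TF is tumor-specific when it shows (a) higher deviation z in tumor cells
(Wilcoxon, BH fdr < 0.05), (b) a higher flank-normalized shoulder insertion density (increased
binding) in tumor pseudo-bulk, and (c) elevated expression in tumor cells
(log2FC > 0.25, Wilcoxon fdr < 0.05) relative to normal epithelial cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from io import StringIO

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import mannwhitneyu

log = logging.getLogger(__name__)

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


# ---------------------------------------------------------------------------
# motif models and scanning
# ---------------------------------------------------------------------------

@dataclass
class MotifModel:
    """A position frequency matrix (4 x width, rows A/C/G/T) with a pseudocount."""

    name: str
    pfm: np.ndarray
    pseudocount: float = 0.8

    def __post_init__(self):
        self.pfm = np.asarray(self.pfm, dtype=float)
        if self.pfm.shape[0] != 4 or self.pfm.shape[1] < 4:
            raise ValueError("PFM must be 4 x width with width >= 4")
        if (self.pfm < 0).any():
            raise ValueError("PFM entries must be nonnegative")
        sums = self.pfm.sum(axis=0)
        if not np.allclose(sums, sums[0], rtol=1e-3):
            raise ValueError("PFM columns must sum to a constant")

    @property
    def width(self) -> int:
        return self.pfm.shape[1]

    def log_odds(self, background: float = 0.25) -> np.ndarray:
        probs = (self.pfm + self.pseudocount) / (self.pfm + self.pseudocount).sum(axis=0)
        return np.log(probs / background)

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.pfm.argmax(axis=0))


def read_jaspar_pfms(path_or_text: str, pseudocount: float = 0.8) -> list[MotifModel]:
    """Parse JASPAR-format PFM text (via Bio.motifs) into MotifModel objects."""
    from Bio import motifs as bio_motifs

    try:
        with open(path_or_text) as fh:
            text = fh.read()
    except (OSError, ValueError):
        text = path_or_text
    records = bio_motifs.parse(StringIO(text), "jaspar")
    out = []
    for m in records:
        pfm = np.array([m.counts[b] for b in "ACGT"], dtype=float)
        out.append(MotifModel(m.name or m.matrix_id, pfm, pseudocount))
    return out


def _encode(seq: str) -> np.ndarray:
    """Sequence to integer codes; N (or anything unexpected) -> 4."""
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    codes = np.full(len(arr), 4, dtype=np.int8)
    for base, code in _BASE_INDEX.items():
        codes[arr == ord(base)] = code
    return codes


def _scan_one(codes: np.ndarray, lod: np.ndarray, threshold: float) -> bool:
    w = lod.shape[1]
    n = len(codes)
    if n < w:
        return False
    # N positions score 0 (the expectation of the log-odds under background)
    lod5 = np.vstack([lod, np.zeros(w)])
    windows = np.lib.stride_tricks.sliding_window_view(codes, w)
    scores = lod5[windows, np.arange(w)].sum(axis=1)
    return bool((scores >= threshold).max())


def scan_motifs(
    peak_sequences: list[str],
    motifs: list[MotifModel],
    score_fraction: float = 0.8,
) -> pd.DataFrame:
    """Boolean peak-by-motif match matrix.

    A peak matches when any position on either strand scores at least
    ``score_fraction`` times the motif's maximum achievable log-odds score.
    """
    result = np.zeros((len(peak_sequences), len(motifs)), dtype=bool)
    encoded = [_encode(s) for s in peak_sequences]
    rc_encoded = [_encode(s.translate(_COMPLEMENT)[::-1]) for s in peak_sequences]
    for j, motif in enumerate(motifs):
        lod = motif.log_odds()
        threshold = score_fraction * lod.max(axis=0).sum()
        for i, (fwd, rev) in enumerate(zip(encoded, rc_encoded)):
            result[i, j] = _scan_one(fwd, lod, threshold) or _scan_one(rev, lod, threshold)
    return pd.DataFrame(result, columns=[m.name for m in motifs])


# ---------------------------------------------------------------------------
# background peaks and deviations
# ---------------------------------------------------------------------------

def sample_background_peaks(
    gc_content: np.ndarray,
    mean_accessibility: np.ndarray,
    n_bins: int = 50,
    n_bg: int = 50,
    seed: int = 0,
) -> np.ndarray:
    """For every peak, ``n_bg`` background peaks matched on GC and accessibility.

    Peaks are placed on an (sqrt(n_bins) x sqrt(n_bins)) equal-occupancy grid of
    GC x log mean accessibility; backgrounds are drawn (with replacement) from
    the peak's own bin, excluding the peak itself. A singleton bin falls back to
    the nearest nonempty neighboring bin (logged). Returns (n_peaks, n_bg) indices.
    """
    rng = np.random.default_rng(seed)
    gc = np.asarray(gc_content, dtype=float)
    acc = np.log1p(np.asarray(mean_accessibility, dtype=float))
    n = len(gc)
    if n < 2:
        raise ValueError("cannot sample backgrounds from a single peak")

    def _bin(values):
        qs = np.quantile(values, np.linspace(0, 1, n_bins + 1)[1:-1])
        return np.searchsorted(qs, values, side="right")

    bx, by = _bin(gc), _bin(acc)
    assignment = np.empty((n, n_bg), dtype=int)
    min_pool = max(60, n_bg)
    for i in range(n):
        # own grid cell, expanded ring-wise until the pool is populated enough
        radius = 0
        while True:
            mask = (np.abs(bx - bx[i]) <= radius) & (np.abs(by - by[i]) <= radius)
            mask[i] = False
            pool = np.flatnonzero(mask)
            if len(pool) >= min_pool or radius >= n_bins:
                break
            if radius == 0:
                log.debug("peak %d: sparse bin, expanding to neighboring bins", i)
            radius += 1
        if len(pool) == 0:
            raise ValueError("cannot sample backgrounds from a single peak")
        # kernel weighting keeps draws close in (GC, accessibility) space
        d2 = (bx[pool] - bx[i]) ** 2.0 + (by[pool] - by[i]) ** 2.0
        w = np.exp(-d2 / (2.0 * 3.0 ** 2))
        w /= w.sum()
        assignment[i] = rng.choice(pool, size=n_bg, replace=True, p=w)
    return assignment


@dataclass
class DeviationResult:
    """Motif x cell raw deviations and bias-corrected z-scores."""

    raw: pd.DataFrame
    z: pd.DataFrame
    backgrounds: np.ndarray
    seed: int = 0
    masked: pd.Series = field(default_factory=lambda: pd.Series(dtype=bool))


def chromvar_deviations(
    counts: sp.spmatrix | np.ndarray,
    matches: pd.DataFrame,
    backgrounds: np.ndarray,
    cells: list[str] | None = None,
    seed: int = 0,
) -> DeviationResult:
    """chromVAR-style bias-corrected motif deviations.

    ``counts`` is (peaks x cells); ``matches`` a boolean (peaks x motifs) frame;
    ``backgrounds`` the (peaks x n_bg) assignment from
    :func:`sample_background_peaks`. For each motif the expectation in a cell is
    ``cell_total * sum(matched peak read fractions)``; the raw deviation is the
    relative excess, and the z-score standardizes it against the deviations of
    n_bg background motif-sets (same cardinality, GC/accessibility-matched peaks).
    """
    X = sp.csr_matrix(counts, dtype=float)
    n_peaks, n_cells = X.shape
    M = matches.to_numpy(dtype=float)
    if M.shape[0] != n_peaks:
        raise ValueError("matches and counts disagree on peak count")
    if not (M.sum(axis=0) > 0).all():
        raise ValueError("every motif needs at least one matched peak")
    cell_totals = np.asarray(X.sum(axis=0)).ravel()
    peak_totals = np.asarray(X.sum(axis=1)).ravel()
    grand = peak_totals.sum()
    frac = peak_totals / grand

    def _dev(Mset: np.ndarray) -> np.ndarray:
        obs = (X.T @ Mset)  # cells x motifs
        obs = np.asarray(obs)
        expected = np.outer(cell_totals, frac @ Mset)
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(expected > 0, (obs - expected) / expected, np.nan)

    raw = _dev(M)  # cells x motifs
    f_m = frac @ M  # expected read fraction per motif set
    n_bg = backgrounds.shape[1]
    bg_devs = np.empty((n_bg, n_cells, M.shape[1]))
    for b in range(n_bg):
        Mb = np.zeros_like(M)
        perm = backgrounds[:, b]
        # background motif-set (multiset, same cardinality): each matched peak
        # replaced by its b-th background peak
        np.add.at(Mb, perm, M)
        d_b = _dev(Mb)
        # residual library-share mismatch of the background set inflates or
        # deflates its sampling variance as 1/share; rescale to the motif set
        f_b = frac @ Mb
        with np.errstate(divide="ignore", invalid="ignore"):
            d_b = d_b * np.sqrt(np.where(f_m > 0, f_b / f_m, 1.0))[None, :]
        bg_devs[b] = d_b
    mu = bg_devs.mean(axis=0)
    sd = bg_devs.std(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, (raw - mu) / sd, np.nan)
    cols = list(matches.columns)
    index = cells if cells is not None else list(range(n_cells))
    return DeviationResult(
        raw=pd.DataFrame(raw.T, index=cols, columns=index).T,
        z=pd.DataFrame(z.T, index=cols, columns=index).T,
        backgrounds=backgrounds,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# footprinting
# ---------------------------------------------------------------------------

@dataclass
class FootprintProfile:
    """Flank-normalized Tn5 insertion frequency around motif centers (+/- 250 bp)."""

    motif: str
    cell_type: str
    profile: np.ndarray  # length 501, positions -250..250
    n_sites: int
    n_insertions: int

    def __post_init__(self):
        self.profile = np.asarray(self.profile, dtype=float)
        if self.profile.shape != (501,):
            raise ValueError("profile must cover motif center +/- 250 bp (501 values)")

    @property
    def center_depth(self) -> float:
        """Mean normalized insertion frequency within +/- 10 bp of the center."""
        return float(self.profile[250 - 10: 250 + 11].mean())

    def smoothed(self, window: int = 11) -> np.ndarray:
        kernel = np.ones(window)
        num = np.convolve(self.profile, kernel, mode="same")
        den = np.convolve(np.ones_like(self.profile), kernel, mode="same")
        return num / den

    @property
    def flank_max(self) -> float:
        """Maximum of the 11-bp smoothed profile within +/- 75 bp of center."""
        sm = self.smoothed(11)
        return float(sm[250 - 75: 250 + 76].max())

    @property
    def binding_score(self) -> float:
        """Mean flank-normalized insertion density in the 10-60 bp shoulders.

        Occupied motifs concentrate Tn5 accessibility immediately around the
        protected core; averaging over the shoulder band is robust to the
        sampling spikes that dominate a pointwise maximum at low coverage.
        """
        sm = self.smoothed(11)
        left = sm[250 - 60: 250 - 9]
        right = sm[250 + 10: 250 + 61]
        return float(np.concatenate([left, right]).mean())


def footprint_profile(
    fragments: pd.DataFrame,
    motif_sites: pd.DataFrame,
    cells_of_type,
    motif: str = "?",
    cell_type: str = "?",
    flank_norm: tuple[int, int] = (200, 250),
    span: int = 250,
) -> FootprintProfile:
    """Pseudo-bulk Tn5 insertion profile around motif sites for one cell set.

    ``motif_sites`` needs columns chrom and center. Both fragment ends count as
    insertions; the aggregate per-position count is divided by the mean count in
    the 200-250 bp flanks on both sides.
    """
    cells_of_type = set(cells_of_type)
    if not cells_of_type:
        raise ValueError("empty cell set")
    if not len(motif_sites):
        raise ValueError("need at least one motif site")
    sub = fragments[fragments["barcode"].isin(cells_of_type)]
    counts = np.zeros(2 * span + 1)
    n_ins = 0
    for chrom, sites in motif_sites.groupby("chrom"):
        m = sub["chrom"] == chrom
        if not m.any():
            continue
        pos = np.concatenate([sub.loc[m, "start"].to_numpy(),
                              sub.loc[m, "end"].to_numpy() - 1])
        pos.sort()
        for center in sites["center"].to_numpy():
            lo = np.searchsorted(pos, center - span, side="left")
            hi = np.searchsorted(pos, center + span, side="right")
            if hi > lo:
                offsets = pos[lo:hi] - (center - span)
                np.add.at(counts, offsets, 1.0)
                n_ins += hi - lo
    lo_f, hi_f = flank_norm
    flank_idx = np.concatenate([
        np.arange(span - hi_f, span - lo_f + 1),
        np.arange(span + lo_f, span + hi_f + 1),
    ])
    flank_mean = counts[flank_idx].mean()
    if flank_mean <= 0:
        raise ValueError("no insertions in normalization flanks; profile not normalizable")
    return FootprintProfile(motif, cell_type, counts / flank_mean,
                            n_sites=len(motif_sites), n_insertions=n_ins)


# ---------------------------------------------------------------------------
# tumor-specific TF filter
# ---------------------------------------------------------------------------

@dataclass
class TFFilterThresholds:
    deviation_fdr: float = 0.05
    expression_fdr: float = 0.05
    expression_log2fc: float = 0.25


def tumor_specific_tfs(
    deviations: DeviationResult,
    footprints: dict[str, dict[str, FootprintProfile]],
    expression_lognorm: np.ndarray,
    gene_index: pd.Index,
    cell_labels: np.ndarray,
    tumor_label: str = "Tumor",
    normal_epithelial_label: str = "Epithelial",
    thresholds: TFFilterThresholds | None = None,
) -> pd.DataFrame:
    """Rank TFs by the triple criterion: higher motif deviation z, increased
    footprint binding and elevated expression in tumor vs normal epithelium.

    ``footprints[motif]`` maps cell-type label -> FootprintProfile. The TF gene
    is assumed to share the motif's name; a TF without an expression record
    fails criterion (c) (logged). Returns one row per motif with the individual
    criteria and the boolean ``selected``, sorted by deviation-z difference.
    """
    from .linking import bh_adjust

    thresholds = thresholds or TFFilterThresholds()
    labels = np.asarray(cell_labels)
    t_mask = labels == tumor_label
    n_mask = labels == normal_epithelial_label
    if not t_mask.any() or not n_mask.any():
        raise ValueError("both tumor and normal epithelial cells are required")

    Z = deviations.z.to_numpy().T  # motifs x cells
    motifs = list(deviations.z.columns)
    zt, zn = Z[:, t_mask], Z[:, n_mask]
    dev_p = np.ones(len(motifs))
    for i in range(len(motifs)):
        a, b = zt[i][~np.isnan(zt[i])], zn[i][~np.isnan(zn[i])]
        if len(a) >= 3 and len(b) >= 3:
            dev_p[i] = mannwhitneyu(a, b, alternative="two-sided",
                                    method="asymptotic").pvalue
    dev_fdr = bh_adjust(dev_p)
    dz = np.nanmean(zt, axis=1) - np.nanmean(zn, axis=1)
    crit_a = (dz > 0) & (dev_fdr < thresholds.deviation_fdr)

    crit_b = np.zeros(len(motifs), dtype=bool)
    for i, m in enumerate(motifs):
        prof = footprints.get(m, {})
        pt, pn = prof.get(tumor_label), prof.get(normal_epithelial_label)
        if pt is not None and pn is not None:
            crit_b[i] = pt.binding_score > pn.binding_score

    E = np.asarray(expression_lognorm, dtype=float)
    expr_p = np.ones(len(motifs))
    expr_fc = np.zeros(len(motifs))
    has_expr = np.zeros(len(motifs), dtype=bool)
    for i, m in enumerate(motifs):
        gi = gene_index.get_loc(m) if m in gene_index else None
        if gi is None:
            log.info("TF %s has no expression record; criterion (c) fails", m)
            continue
        has_expr[i] = True
        xt, xn = E[gi, t_mask], E[gi, n_mask]
        expr_fc[i] = np.log2((np.expm1(xt).mean() + 1) / (np.expm1(xn).mean() + 1))
        expr_p[i] = mannwhitneyu(xt, xn, alternative="two-sided",
                                 method="asymptotic").pvalue
    expr_fdr = bh_adjust(expr_p)
    crit_c = has_expr & (expr_fc > thresholds.expression_log2fc) & \
        (expr_fdr < thresholds.expression_fdr)

    out = pd.DataFrame({
        "motif": motifs,
        "deviation_z_diff": dz,
        "deviation_fdr": dev_fdr,
        "higher_deviation": crit_a,
        "increased_binding": crit_b,
        "expression_log2fc": expr_fc,
        "expression_fdr": expr_fdr,
        "elevated_expression": crit_c,
    })
    out["selected"] = crit_a & crit_b & crit_c
    return out.sort_values("deviation_z_diff", ascending=False).reset_index(drop=True)
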