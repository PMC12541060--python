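"""Per-cell QC metrics and filters, log-normalization, LSI embedding and metacells.

QC bounds default to the thresholds used throughout the pipeline: scATAC cells
need 2000 < nCount_peaks < 30,000, nucleosome signal < 4 and TSS enrichment > 2;
scRNA cells need 500 < nCount_RNA < 50,000, 500 < nFeature_RNA < 6,000 and
mitochondrial fraction < 25%; multiome cells combine 1,000 < nCount_ATAC < 20,000
with 500 < nCount_RNA < 25,000. All inequalities are strict.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.neighbors import NearestNeighbors
from sklearn.utils.extmath import randomized_svd

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# QC thresholds
# ---------------------------------------------------------------------------

@dataclass
class QCThresholds:
    """Per-modality QC bounds. ``None`` disables a bound; all comparisons strict."""

    modality: str  # atac | rna | multiome_atac | multiome_rna
    count_min: float | None = None
    count_max: float | None = None
    feature_min: float | None = None
    feature_max: float | None = None
    tss_min: float | None = None
    nucleosome_max: float | None = None
    mito_max_pct: float | None = None

    def __post_init__(self):
        for lo, hi in ((self.count_min, self.count_max), (self.feature_min, self.feature_max)):
            if lo is not None and hi is not None and not lo < hi:
                raise ValueError(f"lower bound {lo} must be < upper bound {hi}")

    @classmethod
    def default(cls, modality: str) -> "QCThresholds":
        presets = {
            "atac": cls("atac", count_min=2000, count_max=30_000,
                        nucleosome_max=4, tss_min=2),
            "rna": cls("rna", count_min=500, count_max=50_000,
                       feature_min=500, feature_max=6_000, mito_max_pct=25),
            "multiome_atac": cls("multiome_atac", count_min=1_000, count_max=20_000,
                                 tss_min=2, mito_max_pct=25),
            "multiome_rna": cls("multiome_rna", count_min=500, count_max=25_000,
                                feature_min=500, feature_max=6_000, mito_max_pct=25),
        }
        try:
            return presets[modality]
        except KeyError:
            raise ValueError(f"unknown modality {modality!r}") from None


# ---------------------------------------------------------------------------
# fragment-derived metrics
# ---------------------------------------------------------------------------

def _fragment_arrays(fragments: pd.DataFrame):
    return (
        fragments["chrom"].to_numpy(),
        fragments["start"].to_numpy(),
        fragments["end"].to_numpy(),
        fragments["barcode"].to_numpy(),
    )


def tss_enrichment(
    fragments: pd.DataFrame,
    tss_list: pd.DataFrame,
    window: int = 1000,
    flank: int = 100,
    pseudocount: float = 0.5,
) -> pd.Series:
    """Per-cell TSS enrichment score.

    Both fragment ends count as Tn5 insertions. The score is the mean insertion
    count per base over TSS +/- ``window`` divided by the mean insertion count in
    the outer ``flank`` bp on each side, with a pseudocount in the denominator.
    Cells with no fragments score 0.

    ``tss_list`` needs columns ``chrom`` and ``tss``.
    """
    if not len(tss_list):
        raise ValueError("need at least one TSS")
    chroms, starts, ends, barcodes = _fragment_arrays(fragments)
    cells, cell_codes = np.unique(barcodes, return_inverse=True)
    center_hits = np.zeros(len(cells), dtype=float)
    flank_hits = np.zeros(len(cells), dtype=float)

    # insertion positions: both ends (end is exclusive -> last covered base end-1)
    ins_pos = np.concatenate([starts, ends - 1])
    ins_chrom = np.concatenate([chroms, chroms])
    codes = np.concatenate([cell_codes, cell_codes])

    tss_by_chrom = {c: np.sort(g["tss"].to_numpy()) for c, g in tss_list.groupby("chrom")}
    for chrom, tss_pos in tss_by_chrom.items():
        m = ins_chrom == chrom
        if not m.any():
            continue
        pos = ins_pos[m]
        cc = codes[m]
        idx = np.searchsorted(tss_pos, pos)
        left = np.clip(idx - 1, 0, len(tss_pos) - 1)
        right = np.clip(idx, 0, len(tss_pos) - 1)
        dist = np.minimum(np.abs(pos - tss_pos[left]), np.abs(pos - tss_pos[right]))
        in_center = dist <= window
        in_flank = (dist > window - flank) & (dist <= window)
        np.add.at(center_hits, cc[in_center], 1.0)
        np.add.at(flank_hits, cc[in_flank], 1.0)

    n_tss = len(tss_list)
    center_rate = center_hits / (n_tss * (2 * window + 1))
    flank_rate = (flank_hits + pseudocount) / (n_tss * 2 * flank)
    score = np.where(center_hits > 0, center_rate / flank_rate, 0.0)
    return pd.Series(score, index=cells, name="tss_enrichment")


def nucleosome_signal(
    fragments: pd.DataFrame,
    mono_range: tuple[int, int] = (147, 294),
    sub_max: int = 147,
) -> pd.Series:
    """Per-cell mononucleosome / subnucleosome fragment-length ratio.

    Fragments of 147-294 bp count as mononucleosome, < 147 bp as subnucleosome.
    A cell with no subnucleosome fragments gets +inf.
    """
    length = (fragments["end"] - fragments["start"]).to_numpy()
    barcode = fragments["barcode"]
    mono = pd.Series(((length >= mono_range[0]) & (length <= mono_range[1])).astype(float)) \
        .groupby(barcode.to_numpy()).sum()
    subn = pd.Series((length < sub_max).astype(float)).groupby(barcode.to_numpy()).sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = mono / subn
    ratio = ratio.replace(np.nan, np.inf)
    ratio[(mono == 0) & (subn > 0)] = 0.0
    ratio.name = "nucleosome_signal"
    return ratio


def atac_qc_metrics(counts: sp.spmatrix, cells: list[str],
                    fragments: pd.DataFrame | None = None,
                    tss_list: pd.DataFrame | None = None) -> pd.DataFrame:
    """Assemble the per-cell metric table used by :func:`qc_filter` for ATAC data."""
    counts = sp.csr_matrix(counts)
    metrics = pd.DataFrame(index=cells)
    metrics["n_count"] = np.asarray(counts.sum(axis=0)).ravel()
    metrics["n_feature"] = np.asarray((counts > 0).sum(axis=0)).ravel()
    if fragments is not None and tss_list is not None:
        metrics["tss_enrichment"] = tss_enrichment(fragments, tss_list).reindex(cells).fillna(0.0)
        metrics["nucleosome_signal"] = (
            nucleosome_signal(fragments).reindex(cells).fillna(np.inf)
        )
    return metrics


def rna_qc_metrics(counts: sp.spmatrix, genes: pd.DataFrame, cells: list[str]) -> pd.DataFrame:
    counts = sp.csr_matrix(counts)
    metrics = pd.DataFrame(index=cells)
    total = np.asarray(counts.sum(axis=0)).ravel()
    metrics["n_count"] = total
    metrics["n_feature"] = np.asarray((counts > 0).sum(axis=0)).ravel()
    mito = np.array([g.startswith(("MT-", "mt-")) for g in genes.index])
    if mito.any():
        mito_counts = np.asarray(counts[mito].sum(axis=0)).ravel()
        with np.errstate(invalid="ignore", divide="ignore"):
            metrics["pct_mito"] = np.where(total > 0, 100.0 * mito_counts / total, 0.0)
    else:
        metrics["pct_mito"] = 0.0
    return metrics


def qc_filter(matrix, metrics: pd.DataFrame, thresholds: QCThresholds):
    """Apply QC bounds; returns (filtered matrix, report).

    A cell is kept iff it strictly satisfies every configured bound. The report
    lists per-criterion removal counts (criteria may co-fire, so the column sum
    can exceed the number of removed cells).
    """
    metrics = metrics.reindex(matrix.cells)
    n = len(matrix.cells)
    fail = {}

    def _col(name, default):
        return metrics[name].to_numpy() if name in metrics else np.full(n, default)

    count = _col("n_count", np.nan)
    feat = _col("n_feature", np.nan)
    t = thresholds
    if t.count_min is not None:
        fail["count_min"] = ~(count > t.count_min)
    if t.count_max is not None:
        fail["count_max"] = ~(count < t.count_max)
    if t.feature_min is not None:
        fail["feature_min"] = ~(feat > t.feature_min)
    if t.feature_max is not None:
        fail["feature_max"] = ~(feat < t.feature_max)
    if t.tss_min is not None:
        fail["tss_min"] = ~(_col("tss_enrichment", 0.0) > t.tss_min)
    if t.nucleosome_max is not None:
        fail["nucleosome_max"] = ~(_col("nucleosome_signal", np.inf) < t.nucleosome_max)
    if t.mito_max_pct is not None:
        fail["mito_max_pct"] = ~(_col("pct_mito", 0.0) < t.mito_max_pct)

    failed_any = np.zeros(n, dtype=bool)
    for m in fail.values():
        failed_any |= m
    keep = ~failed_any
    report = pd.Series({k: int(v.sum()) for k, v in fail.items()}, name="removed")
    report["total_removed"] = int(failed_any.sum())
    report["total_kept"] = int(keep.sum())
    if keep.sum() == 0:
        warnings.warn("QC removed every cell", stacklevel=2)
    return matrix.subset_cells(keep), report


# ---------------------------------------------------------------------------
# normalization / embedding / metacells
# ---------------------------------------------------------------------------

def log_normalize(counts: sp.spmatrix | np.ndarray, scale: float = 1e4) -> sp.csr_matrix:
    """Library-size log-normalization: x <- ln(1 + count / column_total * scale)."""
    dense_in = not sp.issparse(counts)
    X = sp.csr_matrix(counts, dtype=float)
    totals = np.asarray(X.sum(axis=0)).ravel()
    if np.any(totals <= 0):
        raise ValueError("cells with zero total counts must be removed before normalization")
    X = X.multiply(scale / totals).tocsr()
    X.data = np.log1p(X.data)
    return X.toarray() if dense_in else X


def lsi_embedding(
    matrix,
    n_components: int = 30,
    drop_first_if_depth_corr: float = 0.9,
    random_state: int = 0,
) -> np.ndarray:
    """TF-IDF + truncated SVD (latent semantic indexing) of an accessibility matrix.

    The first component is dropped when its absolute correlation with
    sequencing depth exceeds ``drop_first_if_depth_corr``.
    """
    counts = sp.csr_matrix(matrix.counts, dtype=float)
    depth = np.asarray(counts.sum(axis=0)).ravel()
    if np.any(depth <= 0):
        raise ValueError("cells with zero counts cannot be embedded")
    df = np.asarray((counts > 0).sum(axis=1)).ravel()
    nonzero_peaks = df > 0
    counts = counts[nonzero_peaks]
    df = df[nonzero_peaks]
    n_cells = counts.shape[1]
    tf = counts.multiply(1.0 / depth)
    idf = np.log(1.0 + n_cells / df)
    X = tf.multiply(idf[:, None]).tocsc().T.tocsr()  # cells x peaks

    k = n_components + 1
    max_rank = min(X.shape) - 1
    if k > max_rank:
        warnings.warn(f"rank-deficient input: using {max_rank} components")
        k = max_rank
    U, S, _ = randomized_svd(X, n_components=k, random_state=random_state)
    emb = U * S
    first = emb[:, 0]
    sd = first.std()
    corr = 0.0 if sd == 0 or depth.std() == 0 else np.corrcoef(first, depth)[0, 1]
    if abs(corr) > drop_first_if_depth_corr:
        emb = emb[:, 1:]
    else:
        emb = emb[:, :-1]
    return emb[:, :n_components]


@dataclass
class MetacellMap:
    """k-nearest-neighbor cell groups ('metacells'); each group has exactly k members."""

    groups: list[np.ndarray]
    k: int
    seeds: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self):
        seen = set()
        for g in self.groups:
            if len(g) != self.k:
                raise ValueError("every metacell group must have exactly k members")
            key = frozenset(int(i) for i in g)
            if key in seen:
                raise ValueError("duplicate metacell group")
            seen.add(key)

    def __len__(self):
        return len(self.groups)

    def indicator(self, n_cells: int) -> sp.csr_matrix:
        """Sparse (n_cells x n_groups) 0/1 membership matrix."""
        rows = np.concatenate(self.groups) if self.groups else np.array([], dtype=int)
        cols = np.repeat(np.arange(len(self.groups)), self.k)
        data = np.ones(len(rows))
        return sp.csr_matrix((data, (rows, cols)), shape=(n_cells, len(self.groups)))

    def aggregate(self, counts: sp.spmatrix) -> sp.csr_matrix:
        """Sum counts over each group: (features x n_groups)."""
        return sp.csr_matrix(counts) @ self.indicator(counts.shape[1])


def make_metacells(
    embedding: np.ndarray,
    k: int = 50,
    max_overlap: float = 0.8,
    seed: int = 0,
    n_groups: int | None = None,
) -> MetacellMap:
    """Sample kNN metacell groups from a cell embedding.

    Seed cells are drawn without replacement in random order; each group is the
    seed plus its k-1 nearest neighbors. A candidate group whose Jaccard overlap
    with any accepted group exceeds ``max_overlap`` is discarded. Stops after
    ``n_groups`` accepted groups (or when seeds are exhausted).
    """
    n_cells = embedding.shape[0]
    if n_cells < k:
        raise ValueError(f"need at least k={k} cells, got {n_cells}")
    rng = np.random.default_rng(seed)
    nn = NearestNeighbors(n_neighbors=k).fit(embedding)
    _, neighbor_idx = nn.kneighbors(embedding)
    order = rng.permutation(n_cells)
    accepted: list[np.ndarray] = []
    accepted_sets: list[set] = []
    seeds: list[int] = []
    for s in order:
        group = neighbor_idx[s]
        gset = set(int(i) for i in group)
        ok = True
        for prev in accepted_sets:
            inter = len(gset & prev)
            union = 2 * k - inter
            if inter / union > max_overlap:
                ok = False
                break
        if ok:
            accepted.append(np.sort(group))
            accepted_sets.append(gset)
            seeds.append(int(s))
            if n_groups is not None and len(accepted) >= n_groups:
                break
    return MetacellMap(accepted, k, np.array(seeds))
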