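"""Intratumor transcriptional programs: per-sample consensus NMF, cophenetic
rank selection, module scoring and cross-sample meta-program assembly.

Per qualifying sample (> 500 tumor cells) the gene-centered, zero-clipped
relative expression matrix is factorized with multiplicative-update NMF
(KL divergence) at k = 2..6 over repeated restarts; the consensus matrix over
restarts gives a cophenetic coefficient per k, and the selected rank is the k
immediately preceding the largest drop. Each program's top-100 signature genes
score all tumor cells; program-score correlations, averaged across samples, are
Ward-clustered into meta-programs. Clusters covering fewer than half of the
samples are disregarded.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.cluster.hierarchy import cophenet, cut_tree, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_score

from .preprocess import log_normalize

log = logging.getLogger(__name__)

K_RANGE = range(2, 7)
NRUN = 30
MIN_TUMOR_CELLS = 500
TOP_N_GENES = 100


# ---------------------------------------------------------------------------
# relative expression
# ---------------------------------------------------------------------------

def relative_expression(
    counts: sp.spmatrix | np.ndarray,
    genes: pd.Index,
    cells: list[str],
    sample_labels: np.ndarray,
    tumor_mask: np.ndarray,
    min_cells: int = MIN_TUMOR_CELLS,
) -> dict[str, pd.DataFrame]:
    """Per-sample nonnegative relative expression of tumor cells.

    For each sample with strictly more than ``min_cells`` tumor cells:
    log-normalize, center each gene across that sample's tumor cells, clip
    negatives to zero. Samples at or below the threshold are skipped (logged).
    """
    sample_labels = np.asarray(sample_labels)
    tumor_mask = np.asarray(tumor_mask, dtype=bool)
    result: dict[str, pd.DataFrame] = {}
    for sample in pd.unique(sample_labels):
        sel = np.flatnonzero((sample_labels == sample) & tumor_mask)
        if len(sel) <= min_cells:
            log.info("sample %s skipped: %d tumor cells (need > %d)",
                     sample, len(sel), min_cells)
            continue
        sub = sp.csr_matrix(counts)[:, sel]
        keep = np.asarray(sub.sum(axis=0)).ravel() > 0
        sel = sel[keep]
        sub = sub[:, keep]
        X = np.asarray(log_normalize(sub).todense())
        X = X - X.mean(axis=1, keepdims=True)
        np.clip(X, 0.0, None, out=X)
        result[str(sample)] = pd.DataFrame(
            X, index=genes, columns=[cells[i] for i in sel]
        )
    if not result:
        raise ValueError(f"no sample has more than {min_cells} tumor cells")
    return result


# ---------------------------------------------------------------------------
# multiplicative-update NMF with consensus clustering
# ---------------------------------------------------------------------------

def kl_divergence(V: np.ndarray, WH: np.ndarray) -> float:
    V = np.asarray(V, dtype=np.float64)
    WH = np.maximum(np.asarray(WH, dtype=np.float64), 1e-12)
    mask = V > 0
    return float((V[mask] * np.log(V[mask] / WH[mask])).sum() - V.sum() + WH.sum())


def nmf_mu_kl(
    V: np.ndarray,
    k: int,
    max_iter: int = 200,
    tol: float = 1e-4,
    seed: int = 0,
    track_objective: bool = False,
):
    """Multiplicative-update NMF under KL divergence (Brunet variant).

    Returns (W, H, objective) or, with ``track_objective``, the per-check
    objective trace as well. Raises on negative input.
    """
    V = np.asarray(V, dtype=float)
    if (V < 0).any():
        raise ValueError("NMF input must be nonnegative")
    rng = np.random.default_rng(seed)
    n, m = V.shape
    scale = np.sqrt(V.mean() / k) if V.mean() > 0 else 1.0
    # single precision: the consensus clustering and objective comparisons do
    # not need double, and the matmuls dominate the runtime
    V = V.astype(np.float32)
    W = (rng.uniform(0.1, 1.0, size=(n, k)) * scale).astype(np.float32)
    H = (rng.uniform(0.1, 1.0, size=(k, m)) * scale).astype(np.float32)
    eps = np.float32(1e-8)
    trace = []
    prev = np.inf
    for it in range(max_iter):
        WH = W @ H + eps
        H *= (W.T @ (V / WH)) / np.maximum(W.sum(axis=0)[:, None], eps)
        WH = W @ H + eps
        W *= ((V / WH) @ H.T) / np.maximum(H.sum(axis=1)[None, :], eps)
        if track_objective or it % 10 == 9 or it == max_iter - 1:
            obj = kl_divergence(V, W @ H)
            if track_objective:
                trace.append(obj)
            if prev - obj < tol * max(abs(prev), 1.0) and not track_objective:
                prev = obj
                break
            prev = obj
    obj = kl_divergence(V, W @ H)
    if track_objective:
        return W, H, obj, trace
    return W.astype(float), H.astype(float), obj


@dataclass
class NMFResult:
    sample: str
    k: int
    W: np.ndarray
    H: np.ndarray
    consensus: np.ndarray
    cophenetic: float
    objective: float
    seeds: list[int] = field(default_factory=list)


def nmf_consensus(
    V: np.ndarray | pd.DataFrame,
    k: int,
    nrun: int = NRUN,
    max_iter: int = 200,
    tol: float = 1e-4,
    seed: int = 0,
    sample: str = "?",
) -> NMFResult:
    """Consensus NMF: repeated restarts, cell co-clustering consensus and the
    cophenetic coefficient of its average-linkage dendrogram.

    Rows that are entirely zero are excluded from the factorization (their W
    rows are returned as zero).
    """
    Vdf = V if isinstance(V, pd.DataFrame) else pd.DataFrame(np.asarray(V))
    Vfull = Vdf.to_numpy(dtype=float)
    if (Vfull < 0).any():
        raise ValueError("NMF input must be nonnegative")
    used = Vfull.sum(axis=1) > 0
    Vu = Vfull[used]
    n_cells = Vfull.shape[1]
    rng = np.random.default_rng(seed)
    sub_seeds = [int(s) for s in rng.integers(0, 2**31 - 1, size=nrun)]
    co = np.zeros((n_cells, n_cells))
    best = None
    for s in sub_seeds:
        W, H, obj = nmf_mu_kl(Vu, k, max_iter=max_iter, tol=tol, seed=s)
        clus = H.argmax(axis=0)
        co += (clus[:, None] == clus[None, :]).astype(float)
        if best is None or obj < best[2]:
            best = (W, H, obj)
    consensus = co / nrun
    np.fill_diagonal(consensus, 1.0)
    dist = squareform(1.0 - consensus, checks=False)
    if np.allclose(dist, 0):
        coph = 1.0
    else:
        Zl = linkage(dist, method="average")
        coph, _ = cophenet(Zl, dist)
        coph = float(coph) if np.isfinite(coph) else 1.0
    Wfull = np.zeros((Vfull.shape[0], k))
    Wfull[used] = best[0]
    return NMFResult(sample=str(sample), k=k, W=Wfull, H=best[1],
                     consensus=consensus, cophenetic=coph,
                     objective=best[2], seeds=sub_seeds)


def select_k(cophenetic_by_k: dict[int, float]) -> int:
    """The k immediately preceding the largest drop of the cophenetic
    coefficient (ties -> smallest k); monotone increase -> largest k, warned."""
    ks = sorted(cophenetic_by_k)
    if len(ks) < 2:
        return ks[0]
    drops = [cophenetic_by_k[ks[i]] - cophenetic_by_k[ks[i + 1]] for i in range(len(ks) - 1)]
    if max(drops) <= 0:
        warnings.warn("cophenetic coefficient never decreases; selecting the largest k")
        return ks[-1]
    # ties (to numerical precision) resolve to the smallest k
    best = max(drops)
    for i, d in enumerate(drops):
        if d >= best - 1e-9:
            return ks[i]
    return ks[int(np.argmax(drops))]


# ---------------------------------------------------------------------------
# signatures and module scores
# ---------------------------------------------------------------------------

@dataclass
class ProgramSignature:
    sample: str
    program: int
    genes: list[str]
    scores: np.ndarray

    @property
    def name(self) -> str:
        return f"{self.sample}.p{self.program}"


def program_signature(
    W: pd.DataFrame,
    program: int,
    top_n: int = TOP_N_GENES,
    sample: str = "?",
) -> ProgramSignature:
    """Top ``top_n`` genes of one NMF program by descending W score
    (ties break on gene-name order)."""
    col = W.iloc[:, program]
    if len(col) < top_n:
        warnings.warn(f"only {len(col)} genes available for a top-{top_n} signature")
    order = sorted(col.index, key=lambda g: (-col[g], g))[:top_n]
    return ProgramSignature(str(sample), program, list(order),
                            col.loc[order].to_numpy())


def module_score(
    expression: pd.DataFrame,
    gene_set: list[str],
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Seurat-style module score: mean expression of the gene set minus the mean
    of bin-matched control genes, per cell.

    ``expression`` is a genes x cells frame (log-normalized). Genes are binned
    into ``n_bins`` by average expression; each set gene contributes ``n_ctrl``
    controls drawn from its bin.
    """
    present = [g for g in gene_set if g in expression.index]
    if not present:
        raise ValueError("gene set has no overlap with the expression matrix")
    rng = np.random.default_rng(seed)
    X = expression.to_numpy(dtype=float)
    avg = X.mean(axis=1)
    n_bins = min(n_bins, len(avg))
    # equal-occupancy bins on average expression (rank-based, Seurat-style)
    order = np.argsort(avg, kind="stable")
    bins = np.empty(len(avg), dtype=int)
    bins[order] = np.minimum((np.arange(len(avg)) * n_bins) // len(avg), n_bins - 1)
    gene_pos = {g: i for i, g in enumerate(expression.index)}
    ctrl_rows = []
    for g in present:
        pool = np.flatnonzero(bins == bins[gene_pos[g]])
        ctrl_rows.append(rng.choice(pool, size=n_ctrl, replace=True))
    ctrl = np.concatenate(ctrl_rows)
    set_idx = np.array([gene_pos[g] for g in present])
    return X[set_idx].mean(axis=0) - X[ctrl].mean(axis=0)


# ---------------------------------------------------------------------------
# meta-programs
# ---------------------------------------------------------------------------

@dataclass
class MetaProgram:
    members: list[tuple[str, int]]  # (sample, program index)
    signature: list[str]
    signature_scores: np.ndarray

    @property
    def samples(self) -> set[str]:
        return {s for s, _ in self.members}


def meta_programs(
    signatures: list[ProgramSignature],
    expression_by_sample: dict[str, pd.DataFrame],
    W_by_sample: dict[str, pd.DataFrame],
    coverage_fraction: float = 0.5,
    top_n: int = TOP_N_GENES,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> list[MetaProgram]:
    """Cluster per-sample programs into cross-sample meta-programs.

    Every program signature is module-scored in every sample; within-sample
    Pearson correlations between program score vectors are averaged across
    samples, Ward clustering runs on 1 - average correlation, the tree is cut
    to maximize the silhouette, and clusters whose member programs span fewer
    than ``coverage_fraction`` of the samples are dropped. Each retained
    cluster's signature is the ``top_n`` genes with the highest average NMF
    score over member programs.
    """
    samples = sorted(expression_by_sample)
    if len(samples) < 2:
        raise ValueError("need programs from at least 2 samples")
    n_prog = len(signatures)
    if n_prog < 3:
        raise ValueError("need at least 3 programs to cluster")
    rng = np.random.default_rng(seed)
    corr_sum = np.zeros((n_prog, n_prog))
    corr_n = np.zeros((n_prog, n_prog))
    for sample in samples:
        expr = expression_by_sample[sample]
        scores = np.full((n_prog, expr.shape[1]), np.nan)
        for i, sig in enumerate(signatures):
            try:
                scores[i] = module_score(expr, sig.genes, n_bins, n_ctrl,
                                         seed=int(rng.integers(0, 2**31 - 1)))
            except ValueError:
                continue
        ok = ~np.isnan(scores).any(axis=1)
        ok &= scores.std(axis=1) > 0
        idx = np.flatnonzero(ok)
        if len(idx) < 2:
            continue
        C = np.corrcoef(scores[idx])
        for a, ia in enumerate(idx):
            for b, ib in enumerate(idx):
                corr_sum[ia, ib] += C[a, b]
                corr_n[ia, ib] += 1
    with np.errstate(invalid="ignore"):
        avg_corr = np.where(corr_n > 0, corr_sum / np.maximum(corr_n, 1), 0.0)
    np.fill_diagonal(avg_corr, 1.0)
    avg_corr = 0.5 * (avg_corr + avg_corr.T)
    D = np.clip(1.0 - avg_corr, 0.0, 2.0)
    np.fill_diagonal(D, 0.0)
    Zl = linkage(squareform(D, checks=False), method="ward")

    best_labels, best_sil = None, -np.inf
    for n_clusters in range(2, n_prog):
        labels = cut_tree(Zl, n_clusters=n_clusters).ravel()
        if len(np.unique(labels)) < 2:
            continue
        try:
            sil = silhouette_score(D, labels, metric="precomputed")
        except ValueError:
            continue
        if sil > best_sil:
            best_labels, best_sil = labels, sil
    if best_labels is None:
        best_labels = np.zeros(n_prog, dtype=int)

    out: list[MetaProgram] = []
    for cl in np.unique(best_labels):
        members = [signatures[i] for i in np.flatnonzero(best_labels == cl)]
        member_samples = {m.sample for m in members}
        if len(member_samples) / len(samples) < coverage_fraction:
            continue
        # average NMF score over member programs (absent genes score 0)
        acc: dict[str, float] = {}
        for m in members:
            Wcol = W_by_sample[m.sample].iloc[:, m.program]
            for g, v in Wcol.items():
                acc[g] = acc.get(g, 0.0) + float(v)
        avg = {g: v / len(members) for g, v in acc.items()}
        top = sorted(avg, key=lambda g: (-avg[g], g))[:top_n]
        out.append(MetaProgram(
            members=[(m.sample, m.program) for m in members],
            signature=top,
            signature_scores=np.array([avg[g] for g in top]),
        ))
    if not out:
        warnings.warn("all clusters were dropped by the sample-coverage rule")
    return out


def discover_programs(
    rel_expr: dict[str, pd.DataFrame],
    k_range=K_RANGE,
    nrun: int = NRUN,
    max_iter: int = 200,
    seed: int = 0,
    top_n: int = TOP_N_GENES,
    rank_mode: str = "per_sample",
    fixed_k: int | None = None,
):
    """Full per-sample pipeline: consensus NMF over ``k_range``, cophenetic rank
    selection, program signatures. Returns (signatures, W_by_sample, k_by_sample).

    ``rank_mode="per_sample"`` selects each sample's rank independently;
    ``"cohort_majority"`` selects ranks per sample and then applies the
    majority rank to every sample — single-sample max-drop selection has a
    nonzero error rate on near-flat cophenetic curves, and samples of the
    same tumor type share their program count.
    """
    if rank_mode not in ("per_sample", "cohort_majority"):
        raise ValueError(f"unknown rank_mode {rank_mode!r}")
    rng = np.random.default_rng(seed)
    results_by_sample: dict[str, dict[int, NMFResult]] = {}
    k_by_sample: dict[str, int] = {}
    for sample in sorted(rel_expr):
        V = rel_expr[sample]
        scan = [fixed_k] if fixed_k is not None else list(k_range)
        coph: dict[int, float] = {}
        results: dict[int, NMFResult] = {}
        for k in scan:
            res = nmf_consensus(V, k, nrun=nrun, max_iter=max_iter,
                                seed=int(rng.integers(0, 2**31 - 1)), sample=sample)
            coph[k] = res.cophenetic
            results[k] = res
        results_by_sample[sample] = results
        k_by_sample[sample] = select_k(coph)
    if rank_mode == "cohort_majority" and k_by_sample:
        majority = int(pd.Series(list(k_by_sample.values())).mode().iloc[0])
        k_by_sample = {s: majority for s in k_by_sample}
    signatures: list[ProgramSignature] = []
    W_by_sample: dict[str, pd.DataFrame] = {}
    for sample in sorted(rel_expr):
        k_star = k_by_sample[sample]
        W = pd.DataFrame(results_by_sample[sample][k_star].W,
                         index=rel_expr[sample].index)
        W_by_sample[sample] = W
        for p in range(k_star):
            signatures.append(program_signature(W, p, top_n=top_n, sample=sample))
    return signatures, W_by_sample, k_by_sample
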