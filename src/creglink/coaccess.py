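"""Distance-constrained co-accessibility between peak pairs on metacell data.

The correlation structure of aggregated accessibility is regularized with a
graphical lasso whose penalty grows linearly with genomic distance, and peak
pairs further apart than the interaction cap (500 kb) are never scored. The
co-accessibility score of a pair is the regularized partial correlation
``-Omega_ij / sqrt(Omega_ii * Omega_jj)`` from the estimated precision matrix,
averaged over the overlapping windows that contain the pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from .regions import GenomicRegion

WINDOW_SIZE = 500_000


@dataclass(frozen=True)
class CoaccessWindow:
    chrom: str
    start: int
    end: int
    peak_indices: np.ndarray  # indices into the global peak list


def coaccess_windows(
    peaks: list[GenomicRegion],
    window_size: int = WINDOW_SIZE,
    step: int | None = None,
) -> list[CoaccessWindow]:
    """Tile each chromosome with overlapping windows of length window_size + step.

    Peaks are assigned to windows by center. With the default half-window step,
    every pair of peaks whose centers are within ``window_size`` of each other
    shares at least one window; the pair relation used downstream additionally
    requires the center distance to be at most ``window_size``, so more distant
    peaks are never paired even when they land in a common tile.
    """
    if step is None:
        step = window_size // 2
    length = window_size + step
    centers = np.array([p.center for p in peaks])
    chroms = np.array([p.chrom for p in peaks])
    windows: list[CoaccessWindow] = []
    for chrom in pd.unique(chroms):
        mask = chroms == chrom
        idx = np.flatnonzero(mask)
        c = centers[idx]
        order = np.argsort(c)
        idx, c = idx[order], c[order]
        first = (int(c.min()) // step) * step
        start = max(0, first - step)
        while start <= c.max():
            lo = np.searchsorted(c, start, side="left")
            hi = np.searchsorted(c, start + length, side="left")
            if hi > lo:
                windows.append(CoaccessWindow(chrom, start, start + length, idx[lo:hi]))
            start += step
    return windows


@njit(cache=False)
def _glasso_penalized(S, P, ridge, max_sweeps, tol, inner_sweeps, inner_tol):  # pragma: no cover
    p = S.shape[0]
    W = S.copy()
    for i in range(p):
        W[i, i] = S[i, i] + ridge
    B = np.zeros((p, p))
    converged = False
    for _ in range(max_sweeps):
        max_delta = 0.0
        for j in range(p):
            # lasso on column j: 0.5 b'W11 b - s12'b + sum rho |b|
            for _ in range(inner_sweeps):
                delta_in = 0.0
                for i in range(p):
                    if i == j:
                        continue
                    acc = 0.0
                    for k in range(p):
                        if k != j and k != i:
                            acc += W[i, k] * B[k, j]
                    val = S[i, j] - acc
                    thr = P[i, j]
                    if val > thr:
                        b = (val - thr) / W[i, i]
                    elif val < -thr:
                        b = (val + thr) / W[i, i]
                    else:
                        b = 0.0
                    d = abs(b - B[i, j])
                    if d > delta_in:
                        delta_in = d
                    B[i, j] = b
                if delta_in < inner_tol:
                    break
            for i in range(p):
                if i == j:
                    continue
                w = 0.0
                for k in range(p):
                    if k != j:
                        w += W[i, k] * B[k, j]
                d = abs(w - W[i, j])
                if d > max_delta:
                    max_delta = d
                W[i, j] = w
                W[j, i] = w
        if max_delta < tol:
            converged = True
            break
    Theta = np.zeros((p, p))
    for j in range(p):
        dot = 0.0
        for k in range(p):
            if k != j:
                dot += W[k, j] * B[k, j]
        denom = W[j, j] - dot
        t22 = 1.0 / denom
        Theta[j, j] = t22
        for i in range(p):
            if i != j:
                Theta[i, j] = -B[i, j] * t22
    for i in range(p):
        for j in range(i + 1, p):
            v = 0.5 * (Theta[i, j] + Theta[j, i])
            Theta[i, j] = v
            Theta[j, i] = v
    return Theta, converged


def window_glasso(
    X: np.ndarray,
    centers: np.ndarray,
    window_size: int = WINDOW_SIZE,
    distance_penalty_scale: float = 1.0,
    ridge: float = 1e-3,
    max_sweeps: int = 100,
    tol: float = 1e-5,
    window_id: str = "?",
) -> np.ndarray:
    """Precision matrix for one window.

    ``X`` is (observations x peaks) aggregated log-normalized accessibility;
    the glasso runs on its empirical correlation matrix with elementwise penalty
    ``rho_ij = distance_penalty_scale * d_ij / window_size``.
    """
    n_obs, p = X.shape
    if n_obs < 5:
        raise ValueError(f"window {window_id}: need >= 5 metacell observations")
    sd = X.std(axis=0)
    if np.any(sd == 0):
        raise ValueError(f"window {window_id}: zero-variance peak in window")
    S = np.corrcoef(X, rowvar=False)
    S = np.atleast_2d(S)
    D = np.abs(centers[:, None] - centers[None, :]).astype(float)
    P = distance_penalty_scale * D / window_size
    np.fill_diagonal(P, 0.0)
    Theta, converged = _glasso_penalized(
        np.ascontiguousarray(S), np.ascontiguousarray(P), ridge,
        max_sweeps, tol, 200, tol / 10,
    )
    if not converged:
        raise RuntimeError(f"graphical lasso did not converge in window {window_id}")
    return Theta


def precision_to_scores(Theta: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(Theta))
    scores = -Theta / np.outer(d, d)
    np.fill_diagonal(scores, 1.0)
    return scores


def coaccess_scores(
    agg_accessibility: np.ndarray,
    peaks: list[GenomicRegion],
    window_size: int = WINDOW_SIZE,
    step: int | None = None,
    distance_penalty_scale: float = 1.0,
    ridge: float = 1e-3,
    min_obs: int = 5,
) -> pd.DataFrame:
    """Co-accessibility scores for all peak pairs within ``window_size``.

    ``agg_accessibility`` is (peaks x metacell groups) log-normalized aggregated
    accessibility. Zero-variance peaks are silently excluded from estimation.
    Returns a frame with columns peak_i, peak_j (global indices, i < j), score,
    distance and n_windows; a pair scored in several windows is averaged.
    """
    X_all = np.asarray(agg_accessibility, dtype=float)
    if X_all.shape[1] < min_obs:
        raise ValueError(f"need >= {min_obs} metacell observations")
    centers = np.array([p.center for p in peaks])
    score_sum: dict[tuple[int, int], float] = {}
    score_n: dict[tuple[int, int], int] = {}
    for w_idx, window in enumerate(coaccess_windows(peaks, window_size, step)):
        idx = window.peak_indices
        X = X_all[idx].T  # obs x peaks
        sd = X.std(axis=0)
        usable = sd > 0
        if usable.sum() < 2:
            continue
        idx = idx[usable]
        X = X[:, usable]
        Theta = window_glasso(
            X, centers[idx], window_size, distance_penalty_scale, ridge,
            window_id=f"{window.chrom}:{window.start}-{window.end}",
        )
        S = precision_to_scores(Theta)
        local_centers = centers[idx]
        p = len(idx)
        for a in range(p):
            for b in range(a + 1, p):
                if abs(int(local_centers[a]) - int(local_centers[b])) > window_size:
                    continue
                gi, gj = int(idx[a]), int(idx[b])
                key = (min(gi, gj), max(gi, gj))
                score_sum[key] = score_sum.get(key, 0.0) + float(S[a, b])
                score_n[key] = score_n.get(key, 0) + 1
    rows = [
        (i, j, score_sum[(i, j)] / score_n[(i, j)],
         abs(int(centers[i]) - int(centers[j])), score_n[(i, j)])
        for (i, j) in sorted(score_sum)
    ]
    return pd.DataFrame(rows, columns=["peak_i", "peak_j", "score", "distance", "n_windows"])


def glasso_2x2_closed_form(s: float, rho: float, ridge: float = 1e-3) -> float:
    """Analytic co-accessibility score of a 2-peak window with correlation ``s``
    and off-diagonal penalty ``rho``: soft-threshold(s, rho) / (1 + ridge)."""
    soft = np.sign(s) * max(abs(s) - rho, 0.0)
    return soft / (1.0 + ridge)
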