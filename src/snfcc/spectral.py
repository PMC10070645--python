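"""Normalized spectral embedding, seeded k-means and cluster-number heuristics.

The fused similarity matrix is treated as a weighted graph. Clustering uses
the normalized-cut embedding: the top-C eigenvectors of the symmetrically
normalized affinity ``M = D^{-1/2} A D^{-1/2}``, rows rescaled to unit norm,
partitioned by k-means with multiple seeded restarts.

Two heuristics rank candidate cluster numbers from the spectrum of the
normalized graph Laplacian ``L = I - M``:

- *eigengap*: the gap between consecutive ascending Laplacian eigenvalues,
  ``gap(C) = lambda_{C+1} - lambda_C`` (large gap after C small eigenvalues
  indicates C loosely connected components);
- *rotation cost*: for each C, rotate the row-normalized top-C eigenvectors
  toward an indicator-like basis (alternating discretization) and score the
  residual misalignment; well-separated structure at the true C gives rows
  concentrated on a single axis and near-zero cost.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "spectral_embedding",
    "seeded_kmeans",
    "eigengap_scores",
    "rotation_cost_scores",
    "rank_cluster_numbers",
]


def _normalized_affinity(A: np.ndarray) -> np.ndarray:
    A = np.asarray(A, dtype=float)
    d = A.sum(axis=1)
    if (d <= 0).any():
        raise ValueError("graph has a degree-zero (disconnected) node")
    inv_sqrt = 1.0 / np.sqrt(d)
    return A * inv_sqrt[:, None] * inv_sqrt[None, :]


def spectral_embedding(A: np.ndarray, n_components: int) -> np.ndarray:
    """Row-normalized top eigenvectors of the normalized affinity."""
    M = _normalized_affinity(A)
    _, vecs = np.linalg.eigh(M)
    U = vecs[:, -n_components:][:, ::-1]
    norms = np.linalg.norm(U, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return U / norms


def seeded_kmeans(
    X: np.ndarray,
    n_clusters: int,
    rng: np.random.Generator,
    n_restarts: int = 10,
    max_iter: int = 100,
) -> np.ndarray:
    """Plain k-means with k-means++ initialization and multiple restarts.

    Small and allocation-light on purpose: the consensus loops call this tens
    of thousands of times on tiny embeddings. An emptied cluster is re-seeded
    with the point farthest from its center, so the returned labeling always
    uses all ``n_clusters`` labels (0-based).
    """
    n = X.shape[0]
    if n_clusters > n:
        raise ValueError("more clusters than points")
    sq = (X**2).sum(axis=1)
    best_inertia = np.inf
    best_labels = None
    for _ in range(n_restarts):
        # k-means++ seeding
        centers = np.empty((n_clusters, X.shape[1]))
        centers[0] = X[rng.integers(n)]
        closest = sq + (centers[0] ** 2).sum() - 2 * X @ centers[0]
        np.maximum(closest, 0, out=closest)
        for c in range(1, n_clusters):
            total = closest.sum()
            if total <= 0:
                centers[c:] = X[rng.choice(n, size=n_clusters - c, replace=False)]
                break
            idx = rng.choice(n, p=closest / total)
            centers[c] = X[idx]
            d_new = sq + (centers[c] ** 2).sum() - 2 * X @ centers[c]
            np.minimum(closest, np.maximum(d_new, 0), out=closest)

        labels = np.zeros(n, dtype=int)
        for _ in range(max_iter):
            d2 = sq[:, None] - 2 * X @ centers.T + (centers**2).sum(axis=1)[None, :]
            new_labels = d2.argmin(axis=1)
            for c in range(n_clusters):
                mask = new_labels == c
                if mask.any():
                    centers[c] = X[mask].mean(axis=0)
                else:  # re-seed an emptied cluster with the farthest point
                    far = d2.min(axis=1).argmax()
                    centers[c] = X[far]
                    new_labels[far] = c
            if (new_labels == labels).all():
                break
            labels = new_labels
        d2 = sq[:, None] - 2 * X @ centers.T + (centers**2).sum(axis=1)[None, :]
        inertia = d2[np.arange(n), labels].sum()
        if inertia < best_inertia - 1e-12:
            best_inertia = inertia
            best_labels = labels.copy()
    return best_labels


def eigengap_scores(A: np.ndarray, c_range) -> dict[int, float]:
    """Eigengap per candidate C from the normalized Laplacian spectrum."""
    M = _normalized_affinity(A)
    lam = np.sort(1.0 - np.linalg.eigvalsh(M))  # Laplacian eigenvalues, ascending
    scores = {}
    for c in c_range:
        if not (2 <= c <= A.shape[0] - 1):
            raise ValueError(f"candidate C={c} outside [2, n-1]")
        scores[c] = float(lam[c] - lam[c - 1])
    return scores


def _discretize_rotation(U: np.ndarray, max_iter: int = 30) -> np.ndarray:
    """Alternating discretization: rotate U toward a cluster-indicator basis."""
    n, C = U.shape
    # deterministic init: middle row, then rows least aligned with chosen ones
    R = np.zeros((C, C))
    R[:, 0] = U[n // 2]
    cum = np.zeros(n)
    for j in range(1, C):
        cum += np.abs(U @ R[:, j - 1])
        R[:, j] = U[int(cum.argmin())]
    last = 0.0
    for _ in range(max_iter):
        Z = U @ R
        idx = Z.argmax(axis=1)
        Xd = np.zeros_like(Z)
        Xd[np.arange(n), idx] = 1.0
        u, s, vt = np.linalg.svd(Xd.T @ U)
        obj = s.sum()
        if abs(obj - last) < 1e-10:
            break
        last = obj
        R = (u @ vt).T
    return R


def rotation_cost_scores(A: np.ndarray, c_range) -> dict[int, float]:
    """Misalignment cost per candidate C (smaller is better).

    Rows of the rotated embedding Z = U R have unit norm; the per-row cost
    ``sum_j Z_ij^2 / max_j Z_ij^2`` is 1 for a perfectly indicator-like row
    and up to C for a maximally spread one. Reported cost is the average
    excess over 1, in [0, C-1].
    """
    scores = {}
    for c in c_range:
        if not (2 <= c <= A.shape[0] - 1):
            raise ValueError(f"candidate C={c} outside [2, n-1]")
        U = spectral_embedding(A, c)
        R = _discretize_rotation(U)
        Z = U @ R
        Z2 = Z**2
        mx = Z2.max(axis=1)
        per_row = np.full(Z.shape[0], float(c))  # zero row: maximal misalignment
        nz = mx > 0
        per_row[nz] = Z2[nz].sum(axis=1) / mx[nz]
        scores[c] = float(per_row.mean() - 1.0)
    return scores


def rank_cluster_numbers(A: np.ndarray, c_range=range(2, 11), top: int = 2) -> dict:
    """Rank candidate cluster numbers by eigengap and by rotation cost.

    Returns a dict with the full per-C scores and the ``top`` candidates per
    heuristic (eigengap: largest gap first; rotation cost: smallest cost
    first). Ties break toward smaller C.
    """
    c_range = list(c_range)
    gaps = eigengap_scores(A, c_range)
    costs = rotation_cost_scores(A, c_range)
    by_gap = sorted(c_range, key=lambda c: (-gaps[c], c))
    by_cost = sorted(c_range, key=lambda c: (costs[c], c))
    return {
        "eigengap": gaps,
        "rotation_cost": costs,
        "eigengap_candidates": by_gap[:top],
        "rotation_cost_candidates": by_cost[:top],
    }
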