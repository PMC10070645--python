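"""Per-block similarity networks: distances, affinities and SNF kernels.

The chain per data type is

    distance D  ->  affinity W  ->  full kernel P and sparse (KNN) kernel S

with the locally scaled exponential kernel

    W(i,j) = exp( -d(i,j)^2 / (alpha * eps(i,j)) ),
    eps(i,j) = ( mean_K(i) + mean_K(j) + d(i,j) ) / 3,

where ``mean_K(i)`` is the mean distance from subject i to its K nearest
neighbors (self excluded), ``alpha`` the edge-weighting parameter and K the
neighborhood size. A Gaussian-density variant (``kernel="gaussian_density"``,
the scale used by some similarity-fusion tools) is available behind a flag;
it preserves the ranking of similarities.

The full kernel P is the row-stochastic global normalization
``P(i,j) = W(i,j) / (2 * sum_{k != i} W(i,k))`` with diagonal 1/2; the sparse
kernel S keeps each subject's K nearest neighbors only and row-normalizes
over them (zero diagonal). S is asymmetric by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .blocks import FeatureBlock

__all__ = [
    "SimilarityNetwork",
    "pairwise_distance",
    "affinity_matrix",
    "full_kernel",
    "knn_kernel",
    "write_matrix",
    "read_matrix",
]

NETWORK_KINDS = ("distance", "affinity", "full_kernel", "sparse_kernel", "fused")


@dataclass
class SimilarityNetwork:
    """A subject-by-subject matrix at one stage of the similarity chain."""

    subject_ids: list
    matrix: np.ndarray
    kind: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in NETWORK_KINDS:
            raise ValueError(f"unknown network kind {self.kind!r}")
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("matrix must be square")
        if m.shape[0] != len(self.subject_ids):
            raise ValueError("matrix size does not match subject_ids")
        self.matrix = m
        # row-stochastic kernels are asymmetric by construction
        if self.kind not in ("sparse_kernel", "full_kernel") and not np.allclose(
            m, m.T, atol=1e-10
        ):
            raise ValueError(f"{self.kind} matrix is not symmetric")
        if self.kind == "distance":
            if (np.diag(m) != 0).any():
                raise ValueError("distance matrix must have zero diagonal")
            if (m < 0).any():
                raise ValueError("distance matrix must be nonnegative")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


def pairwise_distance(block: FeatureBlock, metric: str) -> SimilarityNetwork:
    """Distance matrix for a preprocessed block.

    ``metric="gower"`` (mixed blocks): the block must already be
    range-standardized, so every column lies in [0,1] and the Gower distance
    is the equal-weight mean of absolute per-variable differences, itself in
    [0,1]. ``metric="euclidean"`` (numeric-only blocks): plain Euclidean
    distance on the z-scored columns.
    """
    X = np.asarray(block.values, dtype=float)
    if metric == "gower":
        if block.block_role != "mixed":
            raise ValueError("gower metric requires a mixed block")
        D = squareform(pdist(X, metric="cityblock") / X.shape[1])
    elif metric == "euclidean":
        if block.block_role != "numeric_only":
            raise ValueError("euclidean metric requires a numeric_only block")
        D = squareform(pdist(X, metric="euclidean"))
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return SimilarityNetwork(block.subject_ids, D, "distance", {"metric": metric})


def affinity_matrix(
    D: SimilarityNetwork, K: int, alpha: float, kernel: str = "exp"
) -> SimilarityNetwork:
    """Locally scaled affinity from a distance matrix.

    ``kernel="exp"`` is the scaled exponential kernel
    exp(-d^2/(alpha*eps)); ``kernel="gaussian_density"`` is the normal density
    with SD ``alpha*eps`` rescaled by its mode so values stay in (0,1].
    Pairs with a zero local scale (identical subjects) get affinity 1.
    """
    if D.kind != "distance":
        raise ValueError("affinity_matrix expects a distance network")
    n = D.n
    if not (1 <= K <= n - 1):
        raise ValueError(f"K must satisfy 1 <= K <= n-1, got K={K}, n={n}")
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    d = D.matrix
    # mean distance to the K nearest neighbors, self excluded
    sorted_d = np.sort(d, axis=1)[:, 1 : K + 1]
    mean_k = sorted_d.mean(axis=1)
    eps = (mean_k[:, None] + mean_k[None, :] + d) / 3.0
    with np.errstate(divide="ignore", invalid="ignore"):
        if kernel == "exp":
            W = np.exp(-(d**2) / (alpha * eps))
        elif kernel == "gaussian_density":
            sigma = alpha * eps
            W = np.exp(-(d**2) / (2.0 * sigma**2))
        else:
            raise ValueError(f"unknown kernel {kernel!r}")
    W[eps == 0] = 1.0  # identical subjects are maximally similar
    W = (W + W.T) / 2.0
    return SimilarityNetwork(
        D.subject_ids, W, "affinity", {"K": K, "alpha": alpha, "kernel": kernel}
    )


def full_kernel(W: SimilarityNetwork) -> SimilarityNetwork:
    """Row-stochastic global kernel: off-diagonal mass 1/2, diagonal 1/2."""
    if W.kind != "affinity":
        raise ValueError("full_kernel expects an affinity network")
    m = W.matrix.copy()
    np.fill_diagonal(m, 0.0)
    row = m.sum(axis=1)
    if (row == 0).any():
        bad = [W.subject_ids[i] for i in np.flatnonzero(row == 0)]
        raise ValueError(f"subjects with zero off-diagonal affinity mass: {bad}")
    P = m / (2.0 * row[:, None])
    np.fill_diagonal(P, 0.5)
    return SimilarityNetwork(W.subject_ids, P, "full_kernel", dict(W.params))


def knn_kernel(W: SimilarityNetwork, K: int) -> SimilarityNetwork:
    """Sparse kernel: keep each row's K nearest neighbors, row-normalize.

    Neighbors are the K largest off-diagonal affinities per row; ties at the
    K-th neighbor are broken by subject index order (deterministic).
    """
    if W.kind != "affinity":
        raise ValueError("knn_kernel expects an affinity network")
    n = W.n
    if not (1 <= K <= n - 1):
        raise ValueError(f"K must satisfy 1 <= K <= n-1, got K={K}, n={n}")
    m = W.matrix.copy()
    np.fill_diagonal(m, -np.inf)
    # stable selection: sort by (-affinity, index); keep first K per row
    order = np.argsort(-m, axis=1, kind="stable")[:, :K]
    S = np.zeros_like(m)
    rows = np.repeat(np.arange(n), K)
    S[rows, order.ravel()] = W.matrix[rows, order.ravel()]
    np.fill_diagonal(S, 0.0)
    S /= S.sum(axis=1, keepdims=True)
    return SimilarityNetwork(
        W.subject_ids, S, "sparse_kernel", {**W.params, "K": K}
    )


def write_matrix(net: SimilarityNetwork, path) -> None:
    """Serialize a network as dense delimited text with subject-id headers."""
    df = pd.DataFrame(net.matrix, index=net.subject_ids, columns=net.subject_ids)
    df.to_csv(path, float_format="%.17g")


def read_matrix(path, kind: str, params: dict | None = None) -> SimilarityNetwork:
    df = pd.read_csv(path, index_col=0)
    return SimilarityNetwork(list(df.index), df.to_numpy(float), kind, params or {})
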