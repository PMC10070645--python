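"""Model selection and final stratification.

Implements the two-step consensus scheme around the fused network:

Step 1 — for every cell of the K x alpha hyperparameter grid, build the
per-block affinities and kernels, fuse them, and consensus-cluster the fused
network (spectral clustering on repeated random subject subsamples,
aggregated into a co-clustering frequency matrix, partitioned by hierarchical
clustering).

Step 2 — retain the cell with the highest average silhouette width. Steps 1
and 2 are repeated in an outer bootstrap over subject subsamples (with
re-standardization per subsample); the retained labelings are combined in a
global consensus matrix with co-inclusion accounting, and the final
subgrouping is the hierarchical cut of that matrix.

Estimators follow the scikit-learn fit/predict idiom (``labels_`` etc.);
the module-level functions are thin wrappers returning the domain records.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.metrics import silhouette_score

from .blocks import FeatureBlock, check_aligned
from .fusion import FusionConfig, fuse
from .preprocessing import preprocess_blocks
from .similarity import (
    SimilarityNetwork,
    affinity_matrix,
    full_kernel,
    knn_kernel,
    pairwise_distance,
)
from .spectral import rank_cluster_numbers, seeded_kmeans, spectral_embedding

__all__ = [
    "ClusterAssignment",
    "ConsensusMatrix",
    "GridCell",
    "HyperParameterGrid",
    "SpectralClusterer",
    "ConsensusClusterer",
    "SNFGridSearch",
    "BootstrapConsensusClusterer",
    "estimate_cluster_numbers",
    "spectral_cluster",
    "consensus_cluster",
    "average_silhouette",
    "grid_search",
    "bootstrap_consensus",
    "cross_tabulate_solutions",
    "fuse_blocks",
]

DEFAULT_K_VALUES = (10, 15, 20, 25, 30)
DEFAULT_ALPHA_VALUES = (0.3, 0.4, 0.5, 0.6, 0.7, 0.8)


def _seed_seq(random_state) -> np.random.SeedSequence:
    if isinstance(random_state, np.random.SeedSequence):
        return random_state
    return np.random.SeedSequence(random_state)


def _as_matrix(X) -> np.ndarray:
    if isinstance(X, SimilarityNetwork):
        return X.matrix
    return np.asarray(X, dtype=float)


# ---------------------------------------------------------------------------
# domain records


@dataclass
class ClusterAssignment:
    """A labeling of subjects into clusters 1..C."""

    subject_ids: list
    labels: np.ndarray
    n_clusters: int
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.labels) != len(self.subject_ids):
            raise ValueError("labels length does not match subject_ids")
        present = set(np.unique(self.labels))
        if present != set(range(1, self.n_clusters + 1)):
            raise ValueError(
                f"label set {sorted(present)} is not exactly 1..{self.n_clusters}"
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"subject": self.subject_ids, "cluster": self.labels})


@dataclass
class ConsensusMatrix:
    """Pairwise co-clustering counts with co-inclusion denominators."""

    subject_ids: list
    co_cluster: np.ndarray
    co_inclusion: np.ndarray

    def __post_init__(self) -> None:
        if (self.co_cluster > self.co_inclusion).any():
            raise ValueError("co_cluster exceeds co_inclusion")

    @property
    def frequency(self) -> np.ndarray:
        """Co-clustering frequency; pairs never co-included get 0, diagonal 1."""
        with np.errstate(invalid="ignore"):
            f = np.where(
                self.co_inclusion > 0,
                self.co_cluster / np.maximum(self.co_inclusion, 1),
                0.0,
            )
        np.fill_diagonal(f, 1.0)
        return f

    def check_coverage(self) -> None:
        incl = np.diag(self.co_inclusion)
        if (incl == 0).any():
            bad = [self.subject_ids[i] for i in np.flatnonzero(incl == 0)]
            raise ValueError(f"subjects never included in any run: {bad}")
        off = self.co_inclusion.copy()
        np.fill_diagonal(off, 0)
        if ((off > 0).sum(axis=1) == 0).any():
            raise ValueError("a subject has zero co-inclusion with every other subject")


def _consensus_labels(
    cm: ConsensusMatrix, n_clusters: int, method: str = "average"
) -> np.ndarray:
    """Hierarchical cut of 1 - frequency into exactly ``n_clusters`` labels 1..C."""
    dis = 1.0 - cm.frequency
    np.fill_diagonal(dis, 0.0)
    dis = np.clip((dis + dis.T) / 2.0, 0.0, None)
    Z = scipy_linkage(squareform(dis, checks=False), method=method)
    raw = fcluster(Z, t=n_clusters, criterion="maxclust")
    # relabel deterministically by first appearance
    mapping: dict[int, int] = {}
    labels = np.empty_like(raw)
    for i, r in enumerate(raw):
        mapping.setdefault(r, len(mapping) + 1)
        labels[i] = mapping[r]
    if len(mapping) != n_clusters:
        raise ValueError(
            f"hierarchical cut produced {len(mapping)} clusters, requested {n_clusters}"
        )
    return labels


# ---------------------------------------------------------------------------
# estimators


class SpectralClusterer(BaseEstimator, ClusterMixin):
    """Normalized spectral clustering of a precomputed similarity matrix.

    Top-C eigenvectors of ``D^{-1/2} A D^{-1/2}``, rows renormalized,
    partitioned by seeded k-means with ``n_restarts`` restarts. Deterministic
    given ``random_state``.

    Attributes
    ----------
    labels_ : ndarray of int
        Cluster labels in 1..n_clusters.
    embedding_ : ndarray
        The row-normalized spectral embedding used for k-means.
    """

    def __init__(self, n_clusters=2, n_restarts=10, random_state=None):
        self.n_clusters = n_clusters
        self.n_restarts = n_restarts
        self.random_state = random_state

    def fit(self, X, y=None):
        A = _as_matrix(X)
        if self.n_clusters < 2:
            raise ValueError("n_clusters must be >= 2")
        U = spectral_embedding(A, self.n_clusters)
        ss = _seed_seq(self.random_state)
        for ss_try in ss.spawn(10):
            rng = np.random.default_rng(ss_try)
            labels = seeded_kmeans(U, self.n_clusters, rng, self.n_restarts)
            if len(np.unique(labels)) == self.n_clusters:
                self.embedding_ = U
                self.labels_ = labels + 1
                return self
        raise RuntimeError("k-means produced an empty cluster in 10 restarts")


class ConsensusClusterer(BaseEstimator, ClusterMixin):
    """Consensus clustering of one similarity matrix by repeated subsampling.

    Each of ``reps`` runs draws ceil(p_item * n) subjects without replacement,
    spectral-clusters the corresponding submatrix and updates co-clustering /
    co-inclusion counts. Final labels come from agglomerative hierarchical
    clustering (``linkage`` method) on 1 - frequency, cut at ``n_clusters``.

    Attributes
    ----------
    labels_ : ndarray of int, labels in 1..n_clusters.
    consensus_matrix_ : ConsensusMatrix
    """

    def __init__(
        self,
        n_clusters=2,
        reps=1000,
        p_item=0.8,
        linkage="average",
        n_restarts=10,
        random_state=None,
    ):
        self.n_clusters = n_clusters
        self.reps = reps
        self.p_item = p_item
        self.linkage = linkage
        self.n_restarts = n_restarts
        self.random_state = random_state

    def fit(self, X, y=None):
        A = _as_matrix(X)
        n = A.shape[0]
        if not (0 < self.p_item <= 1):
            raise ValueError("p_item must be in (0, 1]")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        size = int(np.ceil(self.p_item * n))
        ss = _seed_seq(self.random_state)
        ss_sample, ss_cluster = ss.spawn(2)
        rng = np.random.default_rng(ss_sample)
        rep_seeds = ss_cluster.spawn(self.reps)

        co_cl = np.zeros((n, n), dtype=np.int64)
        co_in = np.zeros((n, n), dtype=np.int64)
        for r in range(self.reps):
            idx = np.sort(rng.choice(n, size=size, replace=False))
            sub = A[np.ix_(idx, idx)]
            sub_labels = SpectralClusterer(
                self.n_clusters, self.n_restarts, rep_seeds[r]
            ).fit(sub).labels_
            same = sub_labels[:, None] == sub_labels[None, :]
            co_cl[np.ix_(idx, idx)] += same
            co_in[np.ix_(idx, idx)] += 1

        cm = ConsensusMatrix(list(range(n)), co_cl, co_in)
        cm.check_coverage()
        self.consensus_matrix_ = cm
        self.labels_ = _consensus_labels(cm, self.n_clusters, self.linkage)
        return self


@dataclass
class GridCell:
    K: int
    alpha: float
    labels: np.ndarray | None = None
    silhouette: float = np.nan
    consensus: ConsensusMatrix | None = None
    fused: np.ndarray | None = None
    error: str | None = None


@dataclass
class HyperParameterGrid:
    K_values: tuple
    alpha_values: tuple
    cells: list[GridCell]
    best_index: int

    @property
    def best(self) -> GridCell:
        return self.cells[self.best_index]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "K": c.K,
                    "alpha": c.alpha,
                    "silhouette": c.silhouette,
                    "failed": c.error is not None,
                }
                for c in self.cells
            ]
        )


def fuse_blocks(
    blocks: list[FeatureBlock],
    K: int,
    alpha: float,
    kernel: str = "exp",
    fusion: FusionConfig | None = None,
) -> tuple[SimilarityNetwork, list[float]]:
    """Distance -> affinity -> kernels -> fused network for preprocessed blocks."""
    check_aligned(blocks)
    Ps, Ss = [], []
    for b in blocks:
        metric = "gower" if b.block_role == "mixed" else "euclidean"
        W = affinity_matrix(pairwise_distance(b, metric), K, alpha, kernel)
        Ps.append(full_kernel(W))
        Ss.append(knn_kernel(W, K))
    return fuse(Ps, Ss, fusion)


class SNFGridSearch(BaseEstimator, ClusterMixin):
    """Step 1+2 on the full sample: evaluate every K x alpha cell, retain the best.

    For each grid cell the preprocessed blocks are turned into affinities with
    that cell's (K, alpha), fused, and consensus-clustered; the cell with the
    highest average silhouette width (on the fused network) is retained. Ties
    break toward smaller K, then smaller alpha. Failed cells are recorded and
    skipped; the fit fails only if every cell fails.

    ``fit`` expects a list of *preprocessed* FeatureBlocks.
    """

    def __init__(
        self,
        n_clusters=2,
        k_values=DEFAULT_K_VALUES,
        alpha_values=DEFAULT_ALPHA_VALUES,
        reps=1000,
        p_item=0.8,
        kernel="exp",
        fusion_T=20,
        linkage="average",
        n_restarts=10,
        random_state=None,
    ):
        self.n_clusters = n_clusters
        self.k_values = k_values
        self.alpha_values = alpha_values
        self.reps = reps
        self.p_item = p_item
        self.kernel = kernel
        self.fusion_T = fusion_T
        self.linkage = linkage
        self.n_restarts = n_restarts
        self.random_state = random_state

    def fit(self, X, y=None):
        blocks: list[FeatureBlock] = X
        check_aligned(blocks)
        ss = _seed_seq(self.random_state)
        cells_params = list(itertools.product(self.k_values, self.alpha_values))
        cell_seeds = ss.spawn(len(cells_params))
        fusion = FusionConfig(T=self.fusion_T)

        cells: list[GridCell] = []
        for (K, alpha), cell_seed in zip(cells_params, cell_seeds):
            cell = GridCell(K=int(K), alpha=float(alpha))
            try:
                fused, _ = fuse_blocks(blocks, int(K), float(alpha), self.kernel, fusion)
                cc = ConsensusClusterer(
                    self.n_clusters,
                    self.reps,
                    self.p_item,
                    self.linkage,
                    self.n_restarts,
                    cell_seed,
                ).fit(fused.matrix)
                cell.labels = cc.labels_
                cell.consensus = cc.consensus_matrix_
                cell.fused = fused.matrix
                cell.silhouette = average_silhouette(cc.labels_, fused.matrix)
            except Exception as exc:  # noqa: BLE001 - cell failures are recorded
                cell.error = f"{type(exc).__name__}: {exc}"
            cells.append(cell)

        ok = [i for i, c in enumerate(cells) if c.error is None]
        if not ok:
            raise RuntimeError(
                "every grid cell failed; first error: " + cells[0].error
            )
        best = max(ok, key=lambda i: cells[i].silhouette)  # ties: first in K,alpha order
        self.grid_ = HyperParameterGrid(
            tuple(self.k_values), tuple(self.alpha_values), cells, best
        )
        self.labels_ = cells[best].labels
        self.best_fused_ = cells[best].fused
        return self


class BootstrapConsensusClusterer(BaseEstimator, ClusterMixin):
    """Outer bootstrap of the grid search, combined by global consensus.

    Each of ``n_bootstrap`` iterations draws ceil(boot_frac * n) subjects
    without replacement, re-runs the per-block standardizations on the
    subsample, runs the K x alpha grid search, and contributes the retained
    labeling to a global consensus matrix with co-inclusion accounting.
    Final labels for all subjects come from the hierarchical cut of
    1 - frequency at ``n_clusters``.

    ``fit`` expects *raw* FeatureBlocks; outlier exclusion (if enabled) is
    applied once on the full sample, standardizations per subsample.

    Attributes
    ----------
    labels_, consensus_matrix_, subject_ids_, provenance_ : fitted results;
    ``excluded_`` holds the outlier exclusion log.
    """

    def __init__(
        self,
        n_clusters=2,
        k_values=DEFAULT_K_VALUES,
        alpha_values=DEFAULT_ALPHA_VALUES,
        n_bootstrap=1000,
        boot_frac=0.8,
        reps=1000,
        p_item=0.8,
        kernel="exp",
        fusion_T=20,
        linkage="average",
        n_restarts=10,
        exclude_outliers=True,
        outlier_factor=3.0,
        random_state=None,
    ):
        self.n_clusters = n_clusters
        self.k_values = k_values
        self.alpha_values = alpha_values
        self.n_bootstrap = n_bootstrap
        self.boot_frac = boot_frac
        self.reps = reps
        self.p_item = p_item
        self.kernel = kernel
        self.fusion_T = fusion_T
        self.linkage = linkage
        self.n_restarts = n_restarts
        self.exclude_outliers = exclude_outliers
        self.outlier_factor = outlier_factor
        self.random_state = random_state

    def fit(self, X, y=None):
        blocks: list[FeatureBlock] = [b.copy() for b in X]
        if self.n_bootstrap < 1:
            raise ValueError("n_bootstrap must be >= 1")
        if not (0 < self.boot_frac <= 1):
            raise ValueError("boot_frac must be in (0, 1]")
        # screening happens once, on the full sample
        if self.exclude_outliers:
            from .preprocessing import exclude_outliers as _excl

            blocks, self.excluded_ = _excl(blocks, factor=self.outlier_factor)
        else:
            self.excluded_ = pd.DataFrame()
        ids = check_aligned(blocks)
        n = len(ids)
        size = int(np.ceil(self.boot_frac * n))

        ss = _seed_seq(self.random_state)
        ss_sample, ss_grid = ss.spawn(2)
        rng = np.random.default_rng(ss_sample)
        grid_seeds = ss_grid.spawn(self.n_bootstrap)

        co_cl = np.zeros((n, n), dtype=np.int64)
        co_in = np.zeros((n, n), dtype=np.int64)
        retained = []
        for b in range(self.n_bootstrap):
            idx = np.sort(rng.choice(n, size=size, replace=False))
            sub_blocks = [blk.subset([ids[i] for i in idx]) for blk in blocks]
            sub_pp, _ = preprocess_blocks(sub_blocks, exclude=False)
            gs = SNFGridSearch(
                self.n_clusters,
                self.k_values,
                self.alpha_values,
                self.reps,
                self.p_item,
                self.kernel,
                self.fusion_T,
                self.linkage,
                self.n_restarts,
                grid_seeds[b],
            ).fit(sub_pp)
            labels = gs.labels_
            same = labels[:, None] == labels[None, :]
            co_cl[np.ix_(idx, idx)] += same
            co_in[np.ix_(idx, idx)] += 1
            retained.append(
                {"iteration": b, "K": gs.grid_.best.K, "alpha": gs.grid_.best.alpha,
                 "silhouette": gs.grid_.best.silhouette}
            )

        cm = ConsensusMatrix(ids, co_cl, co_in)
        cm.check_coverage()
        off = co_in.copy()
        np.fill_diagonal(off, 0)
        if ((off > 0).sum(axis=1) == 0).any():
            raise ValueError("a subject has zero co-inclusion with every other subject")
        coverage = np.diag(co_in) / self.n_bootstrap
        if coverage.min() * self.n_bootstrap < 5:
            warnings.warn(
                f"low bootstrap coverage: min inclusions = {int(coverage.min() * self.n_bootstrap)}"
                f" of {self.n_bootstrap}; increase n_bootstrap",
                stacklevel=2,
            )
        self.subject_ids_ = ids
        self.consensus_matrix_ = cm
        self.labels_ = _consensus_labels(cm, self.n_clusters, self.linkage)
        self.provenance_ = {
            "retained_cells": retained,
            "n_bootstrap": self.n_bootstrap,
            "boot_frac": self.boot_frac,
            "coverage_min": float(coverage.min()),
        }
        return self


# ---------------------------------------------------------------------------
# functional wrappers


def estimate_cluster_numbers(fused, c_range=range(2, 11), top: int = 2) -> dict:
    """Rank candidate cluster numbers by eigengap and rotation cost."""
    A = _as_matrix(fused)
    c_range = list(c_range)
    if min(c_range) < 2 or max(c_range) > A.shape[0] - 1:
        raise ValueError("C range must lie within [2, n-1]")
    return rank_cluster_numbers(A, c_range, top=top)


def spectral_cluster(fused, n_clusters: int, seed=None) -> ClusterAssignment:
    """Normalized spectral clustering of a fused network."""
    est = SpectralClusterer(n_clusters, random_state=seed).fit(_as_matrix(fused))
    ids = fused.subject_ids if isinstance(fused, SimilarityNetwork) else list(
        range(est.labels_.shape[0])
    )
    return ClusterAssignment(
        ids, est.labels_, n_clusters, {"method": "spectral", "seed": repr(seed)}
    )


def consensus_cluster(
    fused,
    n_clusters: int,
    reps: int = 1000,
    p_item: float = 0.8,
    seed=None,
    linkage: str = "average",
) -> tuple[ConsensusMatrix, ClusterAssignment]:
    """Subsampled consensus clustering of one fused network."""
    est = ConsensusClusterer(n_clusters, reps, p_item, linkage, random_state=seed).fit(
        _as_matrix(fused)
    )
    ids = fused.subject_ids if isinstance(fused, SimilarityNetwork) else list(
        range(est.labels_.shape[0])
    )
    cm = ConsensusMatrix(ids, est.consensus_matrix_.co_cluster, est.consensus_matrix_.co_inclusion)
    assignment = ClusterAssignment(
        ids,
        est.labels_,
        n_clusters,
        {"method": "consensus", "reps": reps, "p_item": p_item, "seed": repr(seed)},
    )
    return cm, assignment


def average_silhouette(labels, fused) -> float:
    """Average silhouette width of a labeling on a fused similarity matrix.

    The similarity is rescaled to [0, 1] by its maximum off-diagonal entry
    and flipped to a dissimilarity (invariant to positive rescaling of the
    input). Singleton clusters contribute silhouette 0.
    """
    A = _as_matrix(fused)
    labels = np.asarray(labels if not isinstance(labels, ClusterAssignment) else labels.labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette is undefined for a single cluster")
    off = A.copy()
    np.fill_diagonal(off, -np.inf)
    mx = off.max()
    if mx <= 0:
        raise ValueError("similarity matrix has no positive off-diagonal entries")
    dis = np.clip(1.0 - A / mx, 0.0, None)
    dis = (dis + dis.T) / 2.0
    np.fill_diagonal(dis, 0.0)
    return float(silhouette_score(dis, labels, metric="precomputed"))


def grid_search(
    blocks: list[FeatureBlock],
    n_clusters: int,
    k_values=DEFAULT_K_VALUES,
    alpha_values=DEFAULT_ALPHA_VALUES,
    reps: int = 1000,
    p_item: float = 0.8,
    seed=None,
    **kwargs,
) -> HyperParameterGrid:
    """Evaluate the K x alpha grid on preprocessed blocks; retain the best cell."""
    est = SNFGridSearch(
        n_clusters, k_values, alpha_values, reps, p_item, random_state=seed, **kwargs
    ).fit(blocks)
    return est.grid_


def bootstrap_consensus(
    blocks: list[FeatureBlock],
    n_clusters: int,
    k_values=DEFAULT_K_VALUES,
    alpha_values=DEFAULT_ALPHA_VALUES,
    n_bootstrap: int = 1000,
    boot_frac: float = 0.8,
    reps: int = 1000,
    p_item: float = 0.8,
    seed=None,
    **kwargs,
) -> tuple[ConsensusMatrix, ClusterAssignment]:
    """Full two-step pipeline with outer bootstrap; returns consensus + labels."""
    est = BootstrapConsensusClusterer(
        n_clusters,
        k_values,
        alpha_values,
        n_bootstrap,
        boot_frac,
        reps,
        p_item,
        random_state=seed,
        **kwargs,
    ).fit(blocks)
    assignment = ClusterAssignment(
        est.subject_ids_,
        est.labels_,
        n_clusters,
        {"method": "final-consensus", **est.provenance_, "seed": repr(seed)},
    )
    return est.consensus_matrix_, assignment


def cross_tabulate_solutions(
    assignment_a: ClusterAssignment, assignment_b: ClusterAssignment
) -> pd.DataFrame:
    """Contingency table of two clusterings of the same subjects.

    Replaces an alluvial plot: entry (i, j) counts subjects in cluster i of
    the first solution and cluster j of the second.
    """
    if list(assignment_a.subject_ids) != list(assignment_b.subject_ids):
        raise ValueError("assignments cover different subjects")
    table = pd.crosstab(
        pd.Series(assignment_a.labels, name=f"C{assignment_a.n_clusters}"),
        pd.Series(assignment_b.labels, name=f"C{assignment_b.n_clusters}"),
    )
    return table.reindex(
        index=range(1, assignment_a.n_clusters + 1),
        columns=range(1, assignment_b.n_clusters + 1),
        fill_value=0,
    )
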