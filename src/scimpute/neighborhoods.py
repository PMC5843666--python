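"""Cell subpopulation detection: PCA, outlier cells, spectral clustering.

Imputation borrows information across *similar* cells only, so cells are
first grouped into candidate neighborhoods. The matrix is reduced by PCA
(cells as observations, genes centered, retaining the smallest number of
components explaining at least 40% of the variance); cells whose nearest
neighbor in that space is unusually far — beyond the Tukey upper fence of
the nearest-neighbor distance distribution — are flagged as outliers and
excluded from all subsequent steps; the remaining cells are partitioned
into K groups by spectral clustering. Every non-outlier cell's candidate
neighbor set is then the other cells of its group.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import SpectralClustering
from sklearn.decomposition import PCA

from .preprocess import LogMatrix

#: Cluster label assigned to outlier cells.
OUTLIER = -1

#: Minimum cumulative variance fraction the retained components must reach.
VARIANCE_TARGET = 0.40


@dataclasses.dataclass
class PCAEmbedding:
    """Retained principal-component scores of the cells.

    ``scores`` has shape (components, cells); ``variance_fractions`` gives
    each retained component's share of the total variance.
    """

    scores: np.ndarray
    variance_fractions: np.ndarray

    @property
    def n_cells(self) -> int:
        return self.scores.shape[1]


@dataclasses.dataclass
class NeighborhoodAssignment:
    """Per-cell cluster labels, outlier set and candidate neighbor sets.

    ``cluster_of[j]`` is in ``1..K`` for clustered cells and ``OUTLIER``
    (-1) for outliers. ``neighbors_of[j]`` lists the other cells of cell
    j's cluster; it is empty for outliers and never contains j itself or
    any outlier.
    """

    cluster_of: np.ndarray
    outliers: frozenset[int]
    neighbors_of: list[np.ndarray]

    @property
    def n_clusters(self) -> int:
        labels = self.cluster_of[self.cluster_of != OUTLIER]
        return int(labels.max()) if labels.size else 0

    def cells_in_cluster(self, k: int) -> np.ndarray:
        return np.flatnonzero(self.cluster_of == k)


def reduce_dimensions(logmat: LogMatrix | np.ndarray) -> PCAEmbedding:
    """PCA on the expression matrix with cells as observations.

    Genes are centered, not scaled; components are retained up to the
    smallest number explaining at least 40% of the variance.
    """
    values = logmat.values if isinstance(logmat, LogMatrix) else np.asarray(logmat)
    n_cells = values.shape[1]
    if n_cells < 3:
        raise ValueError(f"PCA needs at least 3 cells, got {n_cells}")
    pca = PCA(svd_solver="full")
    scores = pca.fit_transform(values.T)  # (cells, components)
    total = pca.explained_variance_.sum()
    if total <= 0:
        raise ValueError("matrix has zero variance; PCA is undefined")
    fractions = pca.explained_variance_ratio_
    m = int(np.searchsorted(np.cumsum(fractions), VARIANCE_TARGET) + 1)
    m = min(m, scores.shape[1])
    return PCAEmbedding(scores[:, :m].T.copy(), fractions[:m].copy())


def detect_outliers(embedding: PCAEmbedding) -> frozenset[int]:
    """Cells without a close neighbor in PC space.

    For each cell the Euclidean distance ``l_j`` to its nearest other cell
    is computed; cells with ``l_j > Q3 + 1.5 (Q3 - Q1)`` (quartiles of the
    ``l_j`` distribution, linear interpolation) are outliers. The rule is
    strict, so a zero interquartile range flags only cells strictly beyond
    the common distance.
    """
    n_cells = embedding.n_cells
    if n_cells < 4:
        raise ValueError(f"outlier detection needs at least 4 cells, got {n_cells}")
    dist = squareform(pdist(embedding.scores.T))
    np.fill_diagonal(dist, np.inf)
    nearest = dist.min(axis=1)
    q1, q3 = np.percentile(nearest, [25, 75])
    fence = q3 + 1.5 * (q3 - q1)
    return frozenset(np.flatnonzero(nearest > fence).tolist())


def _neighbor_sets(cluster_of: np.ndarray) -> list[np.ndarray]:
    sets: list[np.ndarray] = []
    for j, label in enumerate(cluster_of):
        if label == OUTLIER:
            sets.append(np.empty(0, dtype=int))
        else:
            members = np.flatnonzero(cluster_of == label)
            sets.append(members[members != j])
    return sets


def cluster_cells(
    embedding: PCAEmbedding,
    outliers: frozenset[int] | Sequence[int],
    n_clusters: int,
    random_state: int = 1,
    bandwidth: float | None = None,
) -> NeighborhoodAssignment:
    """Spectral clustering of non-outlier cells into ``n_clusters`` groups.

    The affinity is a Gaussian kernel on the PC scores whose bandwidth
    defaults to the median pairwise distance among clustered cells; the
    normalized-Laplacian embedding is partitioned by k-means with a fixed
    seed.
    """
    outliers = frozenset(int(j) for j in outliers)
    n_cells = embedding.n_cells
    keep = np.array([j for j in range(n_cells) if j not in outliers])
    if n_clusters < 1:
        raise ValueError("number of clusters must be >= 1")
    if n_clusters > keep.size:
        raise ValueError(
            f"cannot form {n_clusters} clusters from {keep.size} non-outlier cells"
        )
    cluster_of = np.full(n_cells, OUTLIER, dtype=int)
    if n_clusters == 1:
        cluster_of[keep] = 1
    else:
        points = embedding.scores.T[keep]
        if bandwidth is None:
            pair = pdist(points)
            bandwidth = float(np.median(pair))
        if bandwidth <= 0:
            bandwidth = 1.0
        model = SpectralClustering(
            n_clusters=n_clusters,
            affinity="rbf",
            gamma=1.0 / (2.0 * bandwidth**2),
            assign_labels="kmeans",
            random_state=random_state,
        )
        cluster_of[keep] = model.fit_predict(points) + 1
    return NeighborhoodAssignment(cluster_of, outliers, _neighbor_sets(cluster_of))


def assignment_from_labels(
    labels: Sequence, outliers: frozenset[int] | Sequence[int] = frozenset()
) -> NeighborhoodAssignment:
    """Build a :class:`NeighborhoodAssignment` from known cell-type labels.

    When cell types are known, clustering is skipped and each labeled
    group is imputed separately; outlier cells (detected beforehand) are
    still excluded.
    """
    outliers = frozenset(int(j) for j in outliers)
    labels = list(labels)
    distinct = sorted({lab for j, lab in enumerate(labels) if j not in outliers}, key=str)
    code = {lab: k + 1 for k, lab in enumerate(distinct)}
    cluster_of = np.array(
        [OUTLIER if j in outliers else code[lab] for j, lab in enumerate(labels)]
    )
    return NeighborhoodAssignment(cluster_of, outliers, _neighbor_sets(cluster_of))


def assign_neighborhoods(
    logmat: LogMatrix | np.ndarray,
    n_clusters: int | None = None,
    labels: Sequence | None = None,
    random_state: int = 1,
    bandwidth: float | None = None,
) -> NeighborhoodAssignment:
    """Full neighborhood step: PCA, outlier detection, grouping.

    Either ``n_clusters`` (spectral clustering) or ``labels`` (known cell
    types) must be provided; with labels, clustering is skipped but
    outlier detection still runs.
    """
    embedding = reduce_dimensions(logmat)
    outliers = detect_outliers(embedding)
    if labels is not None:
        return assignment_from_labels(labels, outliers)
    if n_clusters is None:
        raise ValueError("n_clusters is required when labels are not given")
    return cluster_cells(embedding, outliers, n_clusters, random_state, bandwidth)
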