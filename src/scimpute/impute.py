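"""Dropout imputation by non-negative least squares on similar cells.

For each non-outlier cell j the trusted genes ``B_j`` (dropout probability
below the threshold) are used to learn how well the candidate neighbor
cells predict cell j:

    beta_hat(j) = argmin_beta || X[B_j, j] - X[B_j, N_j] beta ||^2,  beta >= 0

NNLS yields sparse non-negative weights, so it effectively *selects* the
most similar cells from the candidate pool. The likely-dropout genes
``A_j`` are then rewritten as X[A_j, N_j] beta_hat(j); all other entries —
trusted genes, degenerate genes, and every entry of an outlier cell — are
passed through bit-identical, which is the method's defining property:
imputation never touches values it considers accurately measured.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import scipy.optimize
from sklearn.base import BaseEstimator, TransformerMixin

from .io import CountMatrix
from .mixture import (
    DropoutProbabilities,
    dropout_probabilities,
    fit_all_mixtures,
)
from .neighborhoods import (
    NeighborhoodAssignment,
    assign_neighborhoods,
)
from .preprocess import LogMatrix, delog_and_rescale, normalize_and_log


def learn_cell_weights(
    values: np.ndarray,
    cell: int,
    trusted_genes: np.ndarray,
    neighbors: np.ndarray,
) -> np.ndarray:
    """Non-negative least-squares weights of ``neighbors`` for one cell.

    ``values`` is the genes x cells log matrix; the regression uses only
    the ``trusted_genes`` rows. Underdetermined systems (more neighbors
    than trusted genes) are still well-posed under the non-negativity
    constraint and are solved with a warning.
    """
    trusted_genes = np.asarray(trusted_genes, dtype=int)
    neighbors = np.asarray(neighbors, dtype=int)
    if trusted_genes.size == 0 or neighbors.size == 0:
        raise ValueError("need at least one trusted gene and one neighbor")
    if trusted_genes.size < neighbors.size:
        warnings.warn(
            f"cell {cell}: NNLS is underdetermined "
            f"({trusted_genes.size} trusted genes, {neighbors.size} neighbors)"
        )
    design = values[np.ix_(trusted_genes, neighbors)]
    response = values[trusted_genes, cell]
    weights, _ = scipy.optimize.nnls(design, response)
    return weights


def impute_cell(
    values: np.ndarray,
    cell: int,
    imputable_genes: np.ndarray,
    trusted_genes: np.ndarray,
    neighbors: np.ndarray,
    weights: np.ndarray,
) -> np.ndarray:
    """Return cell ``cell``'s column with its ``imputable_genes`` rewritten.

    Trusted genes and genes outside both sets are copied unchanged; the
    imputable entries become the weighted combination of the neighbors'
    values for the same gene.
    """
    column = values[:, cell].copy()
    imputable_genes = np.asarray(imputable_genes, dtype=int)
    if imputable_genes.size:
        column[imputable_genes] = values[np.ix_(imputable_genes, neighbors)] @ weights
    return column


@dataclasses.dataclass
class ImputationResult:
    """Output of the imputation stage on the log scale."""

    imputed_log: LogMatrix
    weights: dict[int, np.ndarray]
    imputed_mask: np.ndarray

    @property
    def n_imputed(self) -> int:
        return int(self.imputed_mask.sum())


def impute_log_values(
    values: np.ndarray,
    assignment: NeighborhoodAssignment,
    dropout: DropoutProbabilities,
) -> tuple[np.ndarray, np.ndarray, dict[int, np.ndarray]]:
    """Impute every non-outlier cell of a genes x cells log matrix."""
    imputed = values.copy()
    mask = np.zeros(values.shape, dtype=bool)
    weights: dict[int, np.ndarray] = {}
    for cell in range(values.shape[1]):
        if cell in assignment.outliers:
            continue
        A = dropout.A_sets[cell]
        B = dropout.B_sets[cell]
        neighbors = assignment.neighbors_of[cell]
        if A.size == 0:
            continue
        if B.size == 0 or neighbors.size == 0:
            warnings.warn(
                f"cell {cell}: no trusted genes or no neighbors; skipped"
            )
            continue
        w = learn_cell_weights(values, cell, B, neighbors)
        imputed[:, cell] = impute_cell(values, cell, A, B, neighbors, w)
        mask[A, cell] = True
        weights[cell] = w
    return imputed, mask, weights


@dataclasses.dataclass
class ScImputeResult:
    """Everything the pipeline produced, on both scales."""

    imputed_counts: CountMatrix | None
    imputed_log: LogMatrix
    imputed_mask: np.ndarray
    weights: dict[int, np.ndarray]
    assignment: NeighborhoodAssignment
    dropout: DropoutProbabilities


class ScImpute(BaseEstimator, TransformerMixin):
    """Dropout imputation for scRNA-seq, as a scikit-learn transformer.

    The estimator consumes a cells x genes matrix (scikit-learn sample
    orientation). With ``scale="counts"`` (default) the input is a raw
    count matrix which is CPM-normalized and log10-transformed with pseudo
    count 1.01 before modeling, and the transform returns imputed counts;
    with ``scale="log"`` the input is taken as already being on that log
    scale and returned on it.

    The transform is transductive: dropout entries of the *fitted* matrix
    are imputed from its own similar cells, so ``transform`` only accepts
    the matrix that was fitted.

    Parameters
    ----------
    n_clusters : int or None
        Number of candidate cell subpopulations K. Required unless cell
        labels are passed to :meth:`fit` as ``y``.
    dropout_threshold : float
        Threshold t on the dropout probability; entries with ``d >= t``
        are imputed. Default 0.5.
    scale : {"counts", "log"}
        Interpretation of the input matrix.
    random_state : int
        Seed for the spectral-clustering step.
    bandwidth : float or None
        Gaussian affinity bandwidth override for spectral clustering.
    em_tol, em_max_iter, min_cells_per_cluster :
        EM fitting controls (see :mod:`scimpute.mixture`).

    Attributes
    ----------
    cluster_labels_ : ndarray of shape (n_cells,)
        Cluster index (1..K) per cell, -1 for outliers.
    outlier_mask_ : ndarray of bool
        True for cells excluded from (and never used for) imputation.
    dropout_probabilities_ : ndarray of shape (n_cells, n_genes)
        Posterior dropout probability of every entry.
    imputed_mask_ : ndarray of bool, shape (n_cells, n_genes)
        True where the output differs by imputation.
    result_ : ScImputeResult
        Full pipeline output in genes x cells orientation.
    """

    def __init__(
        self,
        n_clusters: int | None = None,
        dropout_threshold: float = 0.5,
        scale: str = "counts",
        random_state: int = 1,
        bandwidth: float | None = None,
        em_tol: float = 1e-6,
        em_max_iter: int = 500,
        min_cells_per_cluster: int = 10,
    ):
        self.n_clusters = n_clusters
        self.dropout_threshold = dropout_threshold
        self.scale = scale
        self.random_state = random_state
        self.bandwidth = bandwidth
        self.em_tol = em_tol
        self.em_max_iter = em_max_iter
        self.min_cells_per_cluster = min_cells_per_cluster

    def fit(self, X, y: Sequence | None = None) -> "ScImpute":
        """Run the full pipeline on a cells x genes matrix.

        ``y`` may carry known cell-type labels, in which case clustering
        is skipped and each labeled group is imputed separately.
        """
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("expected a 2-D cells x genes matrix")
        if self.scale not in ("counts", "log"):
            raise ValueError("scale must be 'counts' or 'log'")
        if y is None and self.n_clusters is None:
            raise ValueError("n_clusters is required when no labels are given")
        values = X.T  # genes x cells, the modeling orientation
        gene_ids = [f"gene{i + 1}" for i in range(values.shape[0])]
        cell_ids = [f"cell{j + 1}" for j in range(values.shape[1])]
        if self.scale == "counts":
            counts = CountMatrix(values, gene_ids, cell_ids)
            logmat = normalize_and_log(counts)
        else:
            logmat = LogMatrix(
                values, np.full(values.shape[1], np.nan), gene_ids, cell_ids
            )
        labels = list(y) if y is not None else None
        assignment = assign_neighborhoods(
            logmat,
            n_clusters=self.n_clusters,
            labels=labels,
            random_state=self.random_state,
            bandwidth=self.bandwidth,
        )
        if len(assignment.outliers) == logmat.n_cells:
            warnings.warn("all cells flagged as outliers; nothing to impute")
        fits = fit_all_mixtures(
            logmat,
            assignment,
            em_tol=self.em_tol,
            em_max_iter=self.em_max_iter,
            min_cells=self.min_cells_per_cluster,
        )
        dropout = dropout_probabilities(
            logmat, fits, assignment, threshold=self.dropout_threshold
        )
        imputed, mask, weights = impute_log_values(
            logmat.values, assignment, dropout
        )
        imputed_log = LogMatrix(
            imputed, logmat.library_sizes, logmat.gene_ids, logmat.cell_ids
        )
        imputed_counts = (
            delog_and_rescale(imputed_log) if self.scale == "counts" else None
        )
        self.result_ = ScImputeResult(
            imputed_counts, imputed_log, mask, weights, assignment, dropout
        )
        self.mixture_fits_ = fits
        self.cluster_labels_ = assignment.cluster_of.copy()
        self.outlier_mask_ = np.array(
            [j in assignment.outliers for j in range(logmat.n_cells)]
        )
        self.dropout_probabilities_ = dropout.d.T.copy()
        self.imputed_mask_ = mask.T.copy()
        self._fitted_X = X
        return self

    def transform(self, X) -> np.ndarray:
        """Return the imputed matrix for the fitted input (cells x genes)."""
        if not hasattr(self, "result_"):
            raise RuntimeError("estimator is not fitted")
        X = np.asarray(X, dtype=float)
        if X.shape != self._fitted_X.shape or not np.array_equal(X, self._fitted_X):
            raise ValueError(
                "scImpute is transductive: transform accepts only the exact "
                "matrix that was fitted"
            )
        if self.scale == "counts":
            return self.result_.imputed_counts.values.T.copy()
        return self.result_.imputed_log.values.T.copy()


def run_scimpute(
    counts: CountMatrix,
    n_clusters: int | None = None,
    dropout_threshold: float = 0.5,
    labels: Sequence | None = None,
    random_state: int = 1,
    **kwargs,
) -> ScImputeResult:
    """Run the full pipeline on a genes x cells :class:`CountMatrix`."""
    model = ScImpute(
        n_clusters=n_clusters,
        dropout_threshold=dropout_threshold,
        scale="counts",
        random_state=random_state,
        **kwargs,
    )
    model.fit(counts.values.T, y=labels)
    result = model.result_
    result.imputed_counts.gene_ids = list(counts.gene_ids)
    result.imputed_counts.cell_ids = list(counts.cell_ids)
    result.imputed_log.gene_ids = list(counts.gene_ids)
    result.imputed_log.cell_ids = list(counts.cell_ids)
    return result


def impute_log_matrix(
    values: np.ndarray,
    n_clusters: int | None = None,
    dropout_threshold: float = 0.5,
    labels: Sequence | None = None,
    random_state: int = 1,
    **kwargs,
) -> ScImputeResult:
    """Run the pipeline directly on a genes x cells log-scale matrix."""
    model = ScImpute(
        n_clusters=n_clusters,
        dropout_threshold=dropout_threshold,
        scale="log",
        random_state=random_state,
        **kwargs,
    )
    model.fit(np.asarray(values, dtype=float).T, y=labels)
    return model.result_
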