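"""Clustering agreement measures and DE precision-recall utilities.

Clustering results are scored against a reference partition with four
measures built from the contingency table between true classes U and
clusters V:

* adjusted Rand index — pair-counting agreement corrected for chance;
* Jaccard index — ``a / (a + b + c)`` over observation pairs, ignoring
  true negatives;
* normalized mutual information — ``2 I(U, V) / (H(U) + H(V))``;
* purity — fraction of observations in their cluster's majority class
  (does not penalize splitting a class across clusters).

For the simulation study, genes are ranked by a one-vs-rest differential
expression score and the ranking is summarized by the area under the
precision-recall curve against the known DE gene set.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import scipy.stats


# ---------------------------------------------------------------------------
# contingency table and clustering scores


@dataclasses.dataclass
class ContingencyTable:
    """Cross-tabulation of a reference partition against a clustering.

    ``counts[i, j]`` is the number of observations in true class i and
    cluster j; ``a``, ``b``, ``c``, ``d`` are the classical pair counts
    (same-same, different-same, same-different, different-different).
    """

    counts: np.ndarray

    @classmethod
    def from_labels(cls, true_labels: Sequence, pred_labels: Sequence) -> "ContingencyTable":
        true_labels, pred_labels = list(true_labels), list(pred_labels)
        if len(true_labels) != len(pred_labels):
            raise ValueError(
                f"label vectors differ in length: {len(true_labels)} vs {len(pred_labels)}"
            )
        if len(true_labels) < 2:
            raise ValueError("need at least two observations")
        u_levels = sorted(set(true_labels), key=str)
        v_levels = sorted(set(pred_labels), key=str)
        u_index = {u: i for i, u in enumerate(u_levels)}
        v_index = {v: j for j, v in enumerate(v_levels)}
        counts = np.zeros((len(u_levels), len(v_levels)), dtype=int)
        for u, v in zip(true_labels, pred_labels):
            counts[u_index[u], v_index[v]] += 1
        return cls(counts)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def row_margins(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_margins(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def pair_counts(self) -> tuple[int, int, int, int]:
        """(a, b, c, d) over all n(n-1)/2 observation pairs."""
        same_same = int(_comb2(self.counts).sum())
        same_cluster = int(_comb2(self.col_margins).sum())
        same_class = int(_comb2(self.row_margins).sum())
        total = self.n * (self.n - 1) // 2
        a = same_same
        b = same_cluster - same_same
        c = same_class - same_same
        d = total - a - b - c
        return a, b, c, d


def _comb2(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return x * (x - 1.0) / 2.0


@dataclasses.dataclass
class ClusteringScores:
    ari: float
    jaccard: float
    nmi: float
    purity: float

    def as_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)


def adjusted_rand_index(table: ContingencyTable) -> float:
    """ARI from the contingency-table formula."""
    sum_cells = _comb2(table.counts).sum()
    sum_rows = _comb2(table.row_margins).sum()
    sum_cols = _comb2(table.col_margins).sum()
    total = _comb2(np.array([table.n]))[0]
    expected = sum_rows * sum_cols / total
    maximum = 0.5 * (sum_rows + sum_cols)
    if maximum == expected:  # both partitions trivial
        return 1.0
    return float((sum_cells - expected) / (maximum - expected))


def jaccard_index(table: ContingencyTable) -> float:
    a, b, c, _ = table.pair_counts
    if a + b + c == 0:
        return 1.0
    return a / (a + b + c)


def normalized_mutual_information(table: ContingencyTable) -> float:
    """``2 I(U, V) / (H(U) + H(V))`` with natural logarithms."""
    n = table.n
    p_uv = table.counts / n
    p_u = table.row_margins / n
    p_v = table.col_margins / n
    nz = p_uv > 0
    mi = float(
        (p_uv[nz] * np.log(p_uv[nz] / np.outer(p_u, p_v)[nz])).sum()
    )
    h_u = float(-(p_u[p_u > 0] * np.log(p_u[p_u > 0])).sum())
    h_v = float(-(p_v[p_v > 0] * np.log(p_v[p_v > 0])).sum())
    if h_u + h_v == 0.0:  # both partitions trivial, hence identical
        return 1.0
    return 2.0 * mi / (h_u + h_v)


def purity_score(table: ContingencyTable) -> float:
    """Fraction of observations matching their cluster's majority class."""
    return float(table.counts.max(axis=0).sum() / table.n)


def clustering_scores(true_labels: Sequence, pred_labels: Sequence) -> ClusteringScores:
    """All four agreement measures between a reference and a clustering."""
    table = ContingencyTable.from_labels(true_labels, pred_labels)
    return ClusteringScores(
        ari=adjusted_rand_index(table),
        jaccard=jaccard_index(table),
        nmi=normalized_mutual_information(table),
        purity=purity_score(table),
    )


# ---------------------------------------------------------------------------
# within-cluster sum of squares on the PC plane


def within_cluster_ss(pc_scores: np.ndarray, labels: Sequence) -> float:
    """Sum over groups of squared distances to the group centroid.

    ``pc_scores`` must be the cells' coordinates on exactly the first two
    principal components, shape (cells, 2).
    """
    pc_scores = np.asarray(pc_scores, dtype=float)
    if pc_scores.ndim != 2 or pc_scores.shape[1] != 2:
        raise ValueError("expected (cells, 2) coordinates on the first two PCs")
    labels = np.asarray(labels)
    if labels.shape[0] != pc_scores.shape[0]:
        raise ValueError("one label per cell required")
    total = 0.0
    for group in np.unique(labels):
        points = pc_scores[labels == group]
        total += float(((points - points.mean(axis=0)) ** 2).sum())
    return total


def first_two_pcs(values: np.ndarray) -> np.ndarray:
    """First two PC coordinates of the cells of a genes x cells matrix."""
    values = np.asarray(values, dtype=float)
    centered = values.T - values.T.mean(axis=0)
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    return u[:, :2] * s[:2]


# ---------------------------------------------------------------------------
# DE gene ranking and precision-recall


def de_ranking_scores(
    values: np.ndarray, labels: Sequence, method: str = "mean_diff"
) -> np.ndarray:
    """Per-gene differential-expression score, higher = more likely DE.

    ``method="mean_diff"`` (default) scores each gene by the largest
    absolute one-vs-rest difference of mean log expression across the
    cell types — a log-fold-change ranking that remains informative after
    imputation. ``method="ranksum"`` scores by the smallest one-vs-rest
    Wilcoxon rank-sum p-value (as ``-log10 p``); note that within-group
    imputation can homogenize values enough to saturate rank-sum
    p-values, making this ranking unreliable on imputed matrices.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if groups.size < 2:
        raise ValueError("need at least two cell types")
    if method == "mean_diff":
        score = np.zeros(values.shape[0])
        for group in groups:
            inside = labels == group
            diff = values[:, inside].mean(axis=1) - values[:, ~inside].mean(axis=1)
            score = np.maximum(score, np.abs(diff))
        return score
    if method == "ranksum":
        p_min = np.ones(values.shape[0])
        for group in groups:
            inside = labels == group
            res = scipy.stats.mannwhitneyu(
                values[:, inside], values[:, ~inside], axis=1, alternative="two-sided"
            )
            p_min = np.minimum(p_min, res.pvalue)
        return -np.log10(np.maximum(p_min, 1e-300))
    raise ValueError(f"unknown method {method!r}")


@dataclasses.dataclass
class PRCurve:
    """Precision-recall curve over score thresholds, ties in one block."""

    precision: np.ndarray
    recall: np.ndarray
    thresholds: np.ndarray
    auc: float


def f_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall."""
    if precision + recall == 0.0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def de_pr_curve(scores: np.ndarray, truth: np.ndarray) -> PRCurve:
    """Precision-recall curve of a gene ranking against the true DE set.

    ``truth`` is either a boolean mask over genes or an index array.
    Equal scores are processed as one block; the area is the trapezoidal
    integral of precision over recall, anchored at recall 0.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth)
    if truth.dtype != bool:
        mask = np.zeros(scores.shape[0], dtype=bool)
        mask[truth] = True
        truth = mask
    if truth.sum() == 0:
        raise ValueError("the true DE gene set is empty")
    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_truth = truth[order]
    # last index of each tie block
    block_end = np.flatnonzero(np.diff(sorted_scores) != 0)
    block_end = np.append(block_end, scores.size - 1)
    cum_tp = np.cumsum(sorted_truth)[block_end]
    n_called = block_end + 1.0
    precision = cum_tp / n_called
    recall = cum_tp / truth.sum()
    auc = float(np.trapezoid(np.concatenate([[precision[0]], precision]),
                             np.concatenate([[0.0], recall])))
    return PRCurve(precision, recall, sorted_scores[block_end], auc)
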