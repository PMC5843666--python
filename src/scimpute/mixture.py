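"""Gamma-Normal mixture model for dropout identification.

Within one cell subpopulation, a gene's log expression is modeled as

    f(x) = lambda * Gamma(x; alpha, beta) + (1 - lambda) * Normal(x; mu, sigma)

where the Gamma component (shape ``alpha``, rate ``beta``) captures dropout
values piled up near zero and the Normal component the actual expression
level; ``lambda`` is the gene's dropout rate in that subpopulation. The
parameters are estimated by EM, and the dropout probability of gene i in
cell j is the posterior probability that the observed value came from the
Gamma component:

    d_ij = lambda * Gamma(x_ij) / [lambda * Gamma(x_ij) + (1 - lambda) * Normal(x_ij)]

A gene with high, stable expression assigns its zeros a high ``d`` (almost
surely dropouts); a gene with constantly low or highly variable expression
assigns them a low ``d`` (plausibly true biological zeros). Entries are
split per cell into the imputable set ``A_j = {i : d_ij >= t}`` and the
trusted set ``B_j = {i : d_ij < t}`` by a threshold ``t``.

Estimation notes
----------------
EM is run for all genes of a cluster simultaneously on stacked arrays.
Initialization is deterministic: ``lambda`` starts at the fraction of
values at the zero floor (0.01 if none), the Normal at the moments of the
upper half of the data and the Gamma at method-of-moments estimates from
the lower half. The Gamma M-step solves the weighted shape equation by
Newton iterations on ``log(alpha) - digamma(alpha)``. Because a
two-component fit of genuinely unimodal data can always buy a little
likelihood by letting the Gamma absorb the lower tail, each converged fit
is compared by BIC against a single Normal; when the single Normal wins,
the gene is declared unimodal and its dropout rate set to zero, so none
of its values can be imputed.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import numpy as np
from scipy.special import digamma, gammaln, polygamma
from sklearn.base import BaseEstimator

from .neighborhoods import OUTLIER, NeighborhoodAssignment
from .preprocess import ZERO_EXPRESSION, LogMatrix

STATUS_CONVERGED = "converged"
STATUS_MAX_ITER = "max-iter"
STATUS_DEGENERATE = "degenerate-skipped"

_LAM_MIN = 1e-6
_SIGMA_FLOOR = 1e-4
_ALPHA_RANGE = (1e-3, 1e4)


@dataclasses.dataclass
class MixtureFit:
    """Fitted mixture parameters for one gene in one subpopulation."""

    lam: float
    alpha: float
    beta: float
    mu: float
    sigma: float
    status: str
    loglik: float = np.nan
    n_iter: int = 0


@dataclasses.dataclass
class ClusterMixtureFits:
    """Per-gene mixture parameters for one cluster, as parallel arrays."""

    lam: np.ndarray
    alpha: np.ndarray
    beta: np.ndarray
    mu: np.ndarray
    sigma: np.ndarray
    status: np.ndarray  # dtype object, one of the STATUS_* strings
    loglik: np.ndarray
    n_iter: np.ndarray

    @property
    def imputable(self) -> np.ndarray:
        """Genes whose fit supports a dropout probability."""
        return self.status != STATUS_DEGENERATE

    def gene(self, i: int) -> MixtureFit:
        return MixtureFit(
            float(self.lam[i]), float(self.alpha[i]), float(self.beta[i]),
            float(self.mu[i]), float(self.sigma[i]), str(self.status[i]),
            float(self.loglik[i]), int(self.n_iter[i]),
        )


@dataclasses.dataclass
class DropoutProbabilities:
    """Dropout probabilities ``d`` (genes x cells) and the induced gene sets.

    ``A_sets[j]``/``B_sets[j]`` partition the imputable genes of cell j at
    threshold ``t``; both are empty for outlier cells. Genes whose fit was
    degenerate have ``d = 0`` and belong to neither set (passed through).
    """

    d: np.ndarray
    threshold: float
    A_sets: list[np.ndarray]
    B_sets: list[np.ndarray]


def _log_gamma_pdf(x: np.ndarray, alpha: np.ndarray, beta: np.ndarray) -> np.ndarray:
    return (
        alpha * np.log(beta) - gammaln(alpha) + (alpha - 1.0) * np.log(x) - beta * x
    )


def _log_normal_pdf(x: np.ndarray, mu: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    return -0.5 * np.log(2.0 * np.pi) - np.log(sigma) - 0.5 * ((x - mu) / sigma) ** 2


def gamma_normal_posterior(
    x: np.ndarray | float,
    lam: float,
    alpha: float,
    beta: float,
    mu: float,
    sigma: float,
) -> np.ndarray | float:
    """Posterior probability that ``x`` came from the Gamma component.

    Evaluated in log space; the boundary mixing weights 0 and 1 yield
    exactly 0 and 1.
    """
    x = np.asarray(x, dtype=float)
    if lam <= 0.0:
        return np.zeros_like(x) if x.ndim else 0.0
    if lam >= 1.0:
        return np.ones_like(x) if x.ndim else 1.0
    l1 = np.log(lam) + _log_gamma_pdf(x, alpha, beta)
    l2 = np.log1p(-lam) + _log_normal_pdf(x, mu, sigma)
    with np.errstate(over="ignore"):
        out = 1.0 / (1.0 + np.exp(l2 - l1))
    return out if x.ndim else float(out)


def _em_batch(
    X: np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 500,
    record_path: bool = False,
) -> tuple[ClusterMixtureFits, list[list[float]] | None]:
    """Run EM simultaneously for every row of ``X`` (genes x cells)."""
    G, n = X.shape
    log_x = np.log(X)
    at_floor = X <= ZERO_EXPRESSION + 1e-12
    below_mid = X <= (X.min(1, keepdims=True) + X.max(1, keepdims=True)) / 2.0

    lam = np.where(at_floor.any(1), at_floor.mean(1), 0.01)
    lam = np.clip(lam, 0.01, 1.0 - _LAM_MIN)
    upper = ~below_mid
    n_up = np.maximum(upper.sum(1), 1)
    mu = (upper * X).sum(1) / n_up
    sigma = np.sqrt(np.maximum((upper * (X - mu[:, None]) ** 2).sum(1) / n_up, 0.0))
    sigma = np.maximum(sigma, _SIGMA_FLOOR)
    w_lo = below_mid.astype(float)
    n_lo = np.maximum(w_lo.sum(1), 1)
    m_lo = (w_lo * X).sum(1) / n_lo
    v_lo = np.maximum((w_lo * (X - m_lo[:, None]) ** 2).sum(1) / n_lo, 1e-4)
    alpha = np.clip(m_lo**2 / v_lo, *_ALPHA_RANGE)
    beta = np.clip(m_lo / v_lo, 1e-6, 1e8)

    loglik = np.full(G, -np.inf)
    n_iter = np.zeros(G, dtype=int)
    active = np.ones(G, dtype=bool)
    path: list[list[float]] | None = [[] for _ in range(G)] if record_path else None

    for iteration in range(max_iter):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        Xa, lxa = X[idx], log_x[idx]
        l1 = np.log(lam[idx])[:, None] + _log_gamma_pdf(
            Xa, alpha[idx, None], beta[idx, None]
        )
        l2 = np.log1p(-lam[idx])[:, None] + _log_normal_pdf(
            Xa, mu[idx, None], sigma[idx, None]
        )
        hi = np.maximum(l1, l2)
        log_mix = hi + np.log(np.exp(l1 - hi) + np.exp(l2 - hi))
        ll_new = log_mix.sum(1)
        resp = np.exp(l1 - log_mix)  # responsibility of the Gamma component

        # M-step
        r_sum = resp.sum(1)
        lam[idx] = np.clip(r_sum / n, _LAM_MIN, 1.0 - _LAM_MIN)
        w = 1.0 - resp
        w_sum = np.maximum(w.sum(1), 1e-12)
        mu_new = (w * Xa).sum(1) / w_sum
        var_new = np.maximum((w * (Xa - mu_new[:, None]) ** 2).sum(1) / w_sum, 0.0)
        mu[idx] = mu_new
        sigma[idx] = np.maximum(np.sqrt(var_new), _SIGMA_FLOOR)
        r_safe = np.maximum(r_sum, 1e-12)
        mean_w = np.maximum((resp * Xa).sum(1) / r_safe, 1e-300)
        # weighted-likelihood shape equation: log(a) - digamma(a) = c
        c = np.maximum(np.log(mean_w) - (resp * lxa).sum(1) / r_safe, 1e-8)
        a_new = (3.0 - c + np.sqrt((c - 3.0) ** 2 + 24.0 * c)) / (12.0 * c)
        for _ in range(12):
            step = (np.log(a_new) - digamma(a_new) - c) / (
                1.0 / a_new - polygamma(1, a_new)
            )
            a_new = np.clip(a_new - step, *_ALPHA_RANGE)
        alpha[idx] = a_new
        beta[idx] = np.clip(a_new / mean_w, 1e-6, 1e8)

        if record_path:
            for row, value in zip(idx, ll_new):
                path[row].append(float(value))
        converged = np.isfinite(loglik[idx]) & (
            np.abs(ll_new - loglik[idx]) <= tol * np.abs(loglik[idx])
        )
        loglik[idx] = ll_new
        n_iter[idx] = iteration + 1
        still = active.copy()
        still[idx[converged]] = False
        active = still

    status = np.where(active, STATUS_MAX_ITER, STATUS_CONVERGED).astype(object)
    fits = ClusterMixtureFits(lam, alpha, beta, mu, sigma, status, loglik, n_iter)
    return fits, path


def _apply_unimodal_guard(fits: ClusterMixtureFits, X: np.ndarray) -> np.ndarray:
    """Set ``lam = 0`` for genes a single Normal explains better (by BIC).

    Returns the boolean mask of guarded genes.
    """
    n = X.shape[1]
    mu1 = X.mean(1)
    sd1 = np.maximum(X.std(1), _SIGMA_FLOOR)
    ll1 = _log_normal_pdf(X, mu1[:, None], sd1[:, None]).sum(1)
    bic_single = 2.0 * np.log(n) - 2.0 * ll1
    bic_mixture = 5.0 * np.log(n) - 2.0 * fits.loglik
    guard = bic_single <= bic_mixture
    fits.lam[guard] = 0.0
    return guard


def fit_gene_mixture(
    values: Sequence[float] | np.ndarray,
    em_tol: float = 1e-6,
    em_max_iter: int = 500,
    min_cells: int = 10,
) -> MixtureFit:
    """Fit the two-component mixture to one gene's values in one cluster.

    Returns a degenerate-skipped fit (``lam = 0``) when there are fewer
    than ``min_cells`` values or fewer than two distinct values, including
    the all-at-floor case.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size < min_cells or np.unique(x).size < 2:
        return MixtureFit(0.0, np.nan, np.nan, np.nan, np.nan, STATUS_DEGENERATE)
    fits, _ = _em_batch(x[None, :], tol=em_tol, max_iter=em_max_iter)
    _apply_unimodal_guard(fits, x[None, :])
    return fits.gene(0)


class GammaNormalMixture(BaseEstimator):
    """Scikit-learn style estimator for the per-gene dropout mixture.

    Fits the Gamma-Normal mixture to a one-dimensional sample of log
    expression values and exposes the dropout posterior.

    Parameters
    ----------
    em_tol : float
        Relative log-likelihood change declaring convergence.
    em_max_iter : int
        Iteration cap.
    min_cells : int
        Below this sample size the fit is refused (degenerate-skipped).

    Attributes
    ----------
    lambda_, alpha_, beta_, mu_, sigma_ : float
        Fitted mixture parameters.
    status_ : str
        Termination mode.
    loglik_path_ : list of float
        Observed-data log-likelihood after each EM iteration.
    """

    def __init__(
        self, em_tol: float = 1e-6, em_max_iter: int = 500, min_cells: int = 10
    ):
        self.em_tol = em_tol
        self.em_max_iter = em_max_iter
        self.min_cells = min_cells

    def fit(self, X, y=None) -> "GammaNormalMixture":
        x = np.asarray(X, dtype=float).ravel()
        if x.size < self.min_cells or np.unique(x).size < 2:
            self.lambda_, self.alpha_, self.beta_ = 0.0, np.nan, np.nan
            self.mu_, self.sigma_ = np.nan, np.nan
            self.status_ = STATUS_DEGENERATE
            self.loglik_path_ = []
            self.n_iter_ = 0
            return self
        fits, path = _em_batch(
            x[None, :], tol=self.em_tol, max_iter=self.em_max_iter, record_path=True
        )
        _apply_unimodal_guard(fits, x[None, :])
        fit = fits.gene(0)
        self.lambda_, self.alpha_, self.beta_ = fit.lam, fit.alpha, fit.beta
        self.mu_, self.sigma_ = fit.mu, fit.sigma
        self.status_ = fit.status
        self.loglik_path_ = path[0]
        self.n_iter_ = fit.n_iter
        return self

    def dropout_probability(self, X) -> np.ndarray:
        """Posterior dropout probability for each value in ``X``."""
        if not hasattr(self, "status_"):
            raise RuntimeError("estimator is not fitted")
        x = np.asarray(X, dtype=float).ravel()
        if self.status_ == STATUS_DEGENERATE:
            return np.zeros_like(x)
        return np.asarray(
            gamma_normal_posterior(
                x, self.lambda_, self.alpha_, self.beta_, self.mu_, self.sigma_
            )
        )

    def predict_proba(self, X) -> np.ndarray:
        """Column-stacked (Normal, Gamma) posterior probabilities."""
        d = self.dropout_probability(X)
        return np.column_stack([1.0 - d, d])


def fit_all_mixtures(
    logmat: LogMatrix | np.ndarray,
    assignment: NeighborhoodAssignment,
    em_tol: float = 1e-6,
    em_max_iter: int = 500,
    min_cells: int = 10,
) -> dict[int, ClusterMixtureFits]:
    """Fit the mixture for every (gene, cluster) pair.

    Outlier cells belong to no cluster and are excluded from every fit.
    Clusters smaller than ``min_cells`` and genes constant within a
    cluster are marked degenerate-skipped (``lam = 0``) and never imputed.
    """
    values = logmat.values if isinstance(logmat, LogMatrix) else np.asarray(logmat)
    n_genes = values.shape[0]
    fits: dict[int, ClusterMixtureFits] = {}
    labels = sorted(set(assignment.cluster_of.tolist()) - {OUTLIER})
    for k in labels:
        cells = assignment.cells_in_cluster(k)
        nan = np.full(n_genes, np.nan)
        degenerate_all = ClusterMixtureFits(
            np.zeros(n_genes), nan.copy(), nan.copy(), nan.copy(), nan.copy(),
            np.full(n_genes, STATUS_DEGENERATE, dtype=object),
            nan.copy(), np.zeros(n_genes, dtype=int),
        )
        if cells.size < min_cells:
            warnings.warn(
                f"cluster {k} has {cells.size} cells (< {min_cells}); "
                "all its genes are skipped"
            )
            fits[k] = degenerate_all
            continue
        sub = values[:, cells]
        distinct = np.ptp(sub, axis=1) > 0
        fitted, _ = _em_batch(sub[distinct], tol=em_tol, max_iter=em_max_iter)
        _apply_unimodal_guard(fitted, sub[distinct])
        out = degenerate_all
        for field in ("lam", "alpha", "beta", "mu", "sigma", "status", "loglik", "n_iter"):
            getattr(out, field)[distinct] = getattr(fitted, field)
        fits[k] = out
    return fits


def dropout_probabilities(
    logmat: LogMatrix | np.ndarray,
    fits: Mapping[int, ClusterMixtureFits],
    assignment: NeighborhoodAssignment,
    threshold: float = 0.5,
) -> DropoutProbabilities:
    """Dropout probability of every entry plus per-cell A/B gene sets.

    Entries of outlier cells and of degenerate-skipped genes get ``d = 0``
    and are never imputed.
    """
    values = logmat.values if isinstance(logmat, LogMatrix) else np.asarray(logmat)
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold t must be in (0, 1)")
    n_genes, n_cells = values.shape
    d = np.zeros((n_genes, n_cells))
    A_sets: list[np.ndarray] = [np.empty(0, dtype=int)] * n_cells
    B_sets: list[np.ndarray] = [np.empty(0, dtype=int)] * n_cells
    for k, cluster_fit in fits.items():
        cells = assignment.cells_in_cluster(k)
        if cells.size == 0:
            continue
        imputable = cluster_fit.imputable
        if imputable.any():
            sub = values[np.ix_(imputable, cells)]
            l1 = np.log(np.maximum(cluster_fit.lam[imputable, None], 1e-300)) + _log_gamma_pdf(
                sub, cluster_fit.alpha[imputable, None], cluster_fit.beta[imputable, None]
            )
            l2 = np.log1p(-np.minimum(cluster_fit.lam[imputable, None], 1.0 - 1e-16)) + _log_normal_pdf(
                sub, cluster_fit.mu[imputable, None], cluster_fit.sigma[imputable, None]
            )
            with np.errstate(over="ignore"):
                post = 1.0 / (1.0 + np.exp(l2 - l1))
            post[cluster_fit.lam[imputable] <= 0.0, :] = 0.0
            post[cluster_fit.lam[imputable] >= 1.0, :] = 1.0
            d[np.ix_(imputable, cells)] = post
        imp_idx = np.flatnonzero(imputable)
        for j, cell in enumerate(cells):
            dropout = d[imp_idx, cell] >= threshold
            A_sets[cell] = imp_idx[dropout]
            B_sets[cell] = imp_idx[~dropout]
    return DropoutProbabilities(d, threshold, A_sets, B_sets)
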