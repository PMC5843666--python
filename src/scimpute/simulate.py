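"""Synthetic three-cell-type scRNA-seq data with known dropout ground truth.

The generator produces log10-scale expression values directly. Per-gene
baseline means are drawn from Normal(1.8, 0.5) and per-gene standard
deviations from Normal(0.6, 0.1) (values chosen to mimic real mouse embryo
single-cell data). Three cell types of ``cells_per_type`` cells each are
simulated; for every type a disjoint set of ``de_per_type`` genes is
upregulated by multiplying its mean by an integer drawn uniformly from
{2, ..., 10}. Expression values are Normal(mean, sd) per gene and cell.

Dropout is then applied entry-wise: each gene drops out with probability
``exp(-coefficient * baseline_mean^2)`` (double-exponential decay in the
mean, so highly expressed genes rarely drop out), each entry zeroed by an
independent Bernoulli draw. A zeroed entry takes the log-scale value a
zero count maps to after normalization, ``log10(1.01)``, so simulated
matrices flow through the same pipeline as real data.

The default dimensions (20,000 genes, 3 x 50 cells, 3 x 270 = 810 DE
genes, coefficient 0.1) are the reference simulation-study settings; the
coefficient can be recalibrated to hit a target overall zero fraction.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .io import CountMatrix
from .preprocess import ZERO_EXPRESSION

CELL_TYPES = ("c1", "c2", "c3")

#: Floor applied to non-positive draws of per-gene standard deviations.
SD_FLOOR = 0.01


@dataclasses.dataclass
class SimulationTruth:
    """Complete and dropout-corrupted data plus every ground-truth quantity."""

    complete_log: np.ndarray
    type_of: np.ndarray  # cell labels, values from CELL_TYPES
    de_genes: np.ndarray  # structured: gene index, upregulated type, multiplier
    gene_means: np.ndarray  # baseline (pre-multiplier) means
    gene_sds: np.ndarray
    raw_log: np.ndarray | None = None
    dropout_rates: np.ndarray | None = None
    rate_coefficient: float | None = None

    @property
    def n_genes(self) -> int:
        return self.complete_log.shape[0]

    @property
    def n_cells(self) -> int:
        return self.complete_log.shape[1]

    @property
    def de_index_set(self) -> np.ndarray:
        return np.sort(self.de_genes["gene"])

    @property
    def de_mask(self) -> np.ndarray:
        mask = np.zeros(self.n_genes, dtype=bool)
        mask[self.de_genes["gene"]] = True
        return mask

    def labels(self) -> list[str]:
        return [str(t) for t in self.type_of]

    def to_count_matrix(self, which: str = "raw") -> CountMatrix:
        """Back-transform the log values to a count matrix (library 1e6)."""
        log = self.raw_log if which == "raw" else self.complete_log
        if log is None:
            raise ValueError("dropout has not been applied yet")
        counts = np.maximum(np.power(10.0, log) - 1.01, 0.0)
        gene_ids = [f"gene{i + 1}" for i in range(self.n_genes)]
        cell_ids = [f"cell{j + 1}" for j in range(self.n_cells)]
        return CountMatrix(counts, gene_ids, cell_ids)


def simulate_complete(
    n_genes: int = 20000,
    cells_per_type: int = 50,
    de_per_type: int = 270,
    mean_loc: float = 1.8,
    mean_scale: float = 0.5,
    sd_loc: float = 0.6,
    sd_scale: float = 0.1,
    multiplier_low: int = 2,
    multiplier_high: int = 10,
    seed: int = 1,
) -> SimulationTruth:
    """Generate the complete (pre-dropout) data for three cell types.

    The three per-type DE gene sets are drawn without replacement and are
    pairwise disjoint, so the total number of DE genes is exactly
    ``3 * de_per_type``.
    """
    n_types = len(CELL_TYPES)
    if n_types * de_per_type > n_genes:
        raise ValueError(
            f"{n_types} x {de_per_type} DE genes exceed {n_genes} genes"
        )
    if cells_per_type < 1:
        raise ValueError("cells_per_type must be positive")
    rng = np.random.default_rng(seed)
    means = rng.normal(mean_loc, mean_scale, n_genes)
    sds = np.maximum(rng.normal(sd_loc, sd_scale, n_genes), SD_FLOOR)
    de_idx = rng.choice(n_genes, n_types * de_per_type, replace=False)
    multipliers = rng.integers(multiplier_low, multiplier_high + 1, de_idx.size)

    n_cells = n_types * cells_per_type
    type_of = np.repeat(CELL_TYPES, cells_per_type)
    mean_matrix = np.tile(means[:, None], (1, n_cells))
    de_records = np.zeros(
        de_idx.size, dtype=[("gene", int), ("cell_type", "U8"), ("multiplier", int)]
    )
    for k, cell_type in enumerate(CELL_TYPES):
        genes = de_idx[k * de_per_type : (k + 1) * de_per_type]
        mult = multipliers[k * de_per_type : (k + 1) * de_per_type]
        cols = type_of == cell_type
        mean_matrix[np.ix_(genes, cols)] = (means[genes] * mult)[:, None]
        rows = slice(k * de_per_type, (k + 1) * de_per_type)
        de_records["gene"][rows] = genes
        de_records["cell_type"][rows] = cell_type
        de_records["multiplier"][rows] = mult

    complete = rng.normal(mean_matrix, sds[:, None])
    complete = np.maximum(complete, ZERO_EXPRESSION)
    return SimulationTruth(complete, type_of, de_records, means, sds)


def dropout_rate_from_mean(mean, coefficient: float = 0.1):
    """Double-exponential dropout rate ``exp(-coefficient * mean^2)``."""
    return np.exp(-coefficient * np.square(mean))


def apply_dropout(
    truth: SimulationTruth, rate_coefficient: float = 0.1, seed: int = 1
) -> SimulationTruth:
    """Introduce dropout zeros into a complete simulation.

    Each gene's dropout rate is ``exp(-coefficient * baseline_mean^2)``;
    every entry is zeroed by an independent Bernoulli draw at that rate,
    with "zero" represented as ``log10(1.01)``.
    """
    rng = np.random.default_rng(seed)
    rates = dropout_rate_from_mean(truth.gene_means, rate_coefficient)
    dropped = rng.random(truth.complete_log.shape) < rates[:, None]
    raw = np.where(dropped, ZERO_EXPRESSION, truth.complete_log)
    return dataclasses.replace(
        truth, raw_log=raw, dropout_rates=rates, rate_coefficient=rate_coefficient
    )


def zero_fraction(values: np.ndarray, zero_value: float = 0.0, atol: float = 1e-12) -> float:
    """Fraction of entries equal to the zero representation."""
    values = np.asarray(values)
    return float(np.isclose(values, zero_value, rtol=0.0, atol=atol).mean())


def log_zero_fraction(values: np.ndarray) -> float:
    """Fraction of log-scale entries at the zero-count floor log10(1.01)."""
    return zero_fraction(values, zero_value=ZERO_EXPRESSION)


def calibrate_dropout_coefficient(
    gene_means: np.ndarray,
    target_zero_fraction: float,
    tol: float = 0.005,
    max_iter: int = 100,
) -> float:
    """Find the rate coefficient whose expected zero fraction hits a target.

    The expected zero fraction is the mean over genes of
    ``exp(-c * mean^2)``, which decreases in ``c``; the coefficient is
    found by bisection to within ``tol`` of the target.
    """
    if not 0.0 < target_zero_fraction < 1.0:
        raise ValueError("target zero fraction must be in (0, 1)")
    means2 = np.square(np.asarray(gene_means, dtype=float))

    def expected(c: float) -> float:
        return float(np.mean(np.exp(-c * means2)))

    lo, hi = 0.0, 1.0
    while expected(hi) > target_zero_fraction:
        hi *= 2.0
        if hi > 1e6:
            raise RuntimeError("cannot reach the target zero fraction")
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        value = expected(mid)
        if abs(value - target_zero_fraction) <= tol:
            return mid
        if value > target_zero_fraction:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
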