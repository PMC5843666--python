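"""Library-size normalization and the log transform used throughout.

Counts are scaled per cell to one million reads (CPM) and transformed as
``X = log10(CPM + 1.01)``. The pseudo count 1.01 keeps zero counts strictly
positive (``log10(1.01) ~ 0.00432``), which the downstream Gamma mixture
component requires, and bounds the influence of very large counts.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .io import CountMatrix

#: Log-scale representation of a zero count after normalization.
ZERO_EXPRESSION = float(np.log10(1.01))

#: Per-cell total the normalization scales to.
LIBRARY_SCALE = 1e6


@dataclasses.dataclass
class LogMatrix:
    """Log-transformed CPM expression (genes x cells).

    ``library_sizes`` holds the original per-cell totals so the transform
    can be inverted exactly for entries that were not imputed.
    """

    values: np.ndarray
    library_sizes: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.library_sizes = np.asarray(self.library_sizes, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("log matrix must be two-dimensional")
        if self.library_sizes.shape != (self.values.shape[1],):
            raise ValueError("one library size per cell required")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]


def normalize_and_log(counts: CountMatrix) -> LogMatrix:
    """CPM-normalize ``counts`` and apply ``log10(. + 1.01)``.

    Raises
    ------
    ValueError
        If any cell has zero total reads (its id is reported).
    """
    libsize = counts.values.sum(axis=0)
    empty = np.flatnonzero(libsize <= 0)
    if empty.size:
        ids = ", ".join(counts.cell_ids[j] for j in empty[:5])
        raise ValueError(f"cells with zero total reads cannot be normalized: {ids}")
    cpm = counts.values / libsize * LIBRARY_SCALE
    return LogMatrix(
        np.log10(cpm + 1.01), libsize, list(counts.gene_ids), list(counts.cell_ids)
    )


def delog_and_rescale(logmat: LogMatrix) -> CountMatrix:
    """Invert :func:`normalize_and_log`, mapping log expression back to counts.

    Entry-wise ``max(0, 10**x - 1.01) * libsize / 1e6``; the floor at zero
    only clips numerical noise since valid log values are >= log10(1.01).
    """
    # per-cell exponent cap keeps extreme imputed values finite in float64
    cap = 300.0 - np.log10(logmat.library_sizes / LIBRARY_SCALE)
    cpm = np.maximum(np.power(10.0, np.minimum(logmat.values, cap)) - 1.01, 0.0)
    counts = cpm * logmat.library_sizes / LIBRARY_SCALE
    return CountMatrix(counts, list(logmat.gene_ids), list(logmat.cell_ids))
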