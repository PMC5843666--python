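"""Reading and writing of gene-by-cell count matrices and cell labels.

Two on-disk layouts are supported:

* dense CSV/TSV with a header row of cell ids and a first column of gene ids
  (comma vs. tab autodetected from the file extension);
* Matrix Market triplet (``.mtx``) with companion ``genes.tsv`` and
  ``barcodes.tsv`` files holding the row and column ids.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse


class CountMatrixError(ValueError):
    """Raised when a count matrix violates its contract."""


@dataclasses.dataclass
class CountMatrix:
    """A raw read-count matrix, genes in rows and cells in columns.

    Entries must be non-negative but need not be integers: imputed
    matrices carry fractional counts.
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if self.values.ndim != 2:
            raise CountMatrixError("count matrix must be two-dimensional")
        n_genes, n_cells = self.values.shape
        if n_genes < 2 or n_cells < 2:
            raise CountMatrixError(
                f"need at least 2 genes and 2 cells, got {n_genes} x {n_cells}"
            )
        if len(self.gene_ids) != n_genes:
            raise CountMatrixError(
                f"{len(self.gene_ids)} gene ids for {n_genes} rows"
            )
        if len(self.cell_ids) != n_cells:
            raise CountMatrixError(
                f"{len(self.cell_ids)} cell ids for {n_cells} columns"
            )
        if len(set(self.gene_ids)) != n_genes:
            raise CountMatrixError("duplicate gene ids")
        if len(set(self.cell_ids)) != n_cells:
            raise CountMatrixError("duplicate cell ids")
        if not np.all(np.isfinite(self.values)):
            raise CountMatrixError("non-finite count encountered")
        if np.any(self.values < 0):
            raise CountMatrixError("negative count encountered")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_ids)


def _dense_sep(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","


def _infer_format(path: Path) -> str:
    return "mtx" if path.suffix.lower() == ".mtx" else "dense"


def read_counts(
    path: str | Path,
    format: str | None = None,
    genes_path: str | Path | None = None,
    barcodes_path: str | Path | None = None,
) -> CountMatrix:
    """Read a count matrix from ``path``.

    ``format`` is ``"dense"`` or ``"mtx"``; when omitted it is inferred
    from the extension. For mtx input the companion id files default to
    ``genes.tsv`` and ``barcodes.tsv`` next to the matrix file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _infer_format(path)
    if fmt == "dense":
        try:
            frame = pd.read_csv(path, sep=_dense_sep(path), index_col=0)
        except Exception as exc:  # malformed csv/tsv
            raise CountMatrixError(f"malformed dense matrix file {path}: {exc}")
        if frame.shape[1] == 0:
            raise CountMatrixError(f"no cell columns found in {path} (malformed header?)")
        values = frame.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise CountMatrixError(f"non-numeric entries in {path} (malformed header?)")
        return CountMatrix(values, list(frame.index), list(frame.columns))
    if fmt == "mtx":
        genes_path = Path(genes_path) if genes_path else path.parent / "genes.tsv"
        barcodes_path = (
            Path(barcodes_path) if barcodes_path else path.parent / "barcodes.tsv"
        )
        mat = scipy.io.mmread(path)
        values = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=float)
        gene_ids = _read_id_column(genes_path)
        cell_ids = _read_id_column(barcodes_path)
        if len(gene_ids) != values.shape[0] or len(cell_ids) != values.shape[1]:
            raise CountMatrixError(
                f"mtx declares {values.shape[0]} x {values.shape[1]} but companion "
                f"files list {len(gene_ids)} genes and {len(cell_ids)} barcodes"
            )
        return CountMatrix(values, gene_ids, cell_ids)
    raise ValueError(f"unknown format {fmt!r} (expected 'dense' or 'mtx')")


def _read_id_column(path: Path) -> list[str]:
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        # first tab-separated field of each non-empty line
        return [line.split("\t")[0].strip() for line in fh if line.strip()]


def write_counts(
    matrix: CountMatrix,
    path: str | Path,
    format: str | None = None,
    precision: int = 6,
) -> None:
    """Write ``matrix`` to ``path`` in dense or Matrix Market form.

    Values are written with ``precision`` significant digits; fractional
    (imputed) counts are preserved, not truncated to integers.
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "dense":
        matrix.to_frame().to_csv(
            path, sep=_dense_sep(path), float_format=f"%.{precision}g"
        )
    elif fmt == "mtx":
        sparse = scipy.sparse.coo_matrix(matrix.values)
        scipy.io.mmwrite(str(path), sparse, precision=precision)
        _write_id_column(path.parent / "genes.tsv", matrix.gene_ids)
        _write_id_column(path.parent / "barcodes.tsv", matrix.cell_ids)
    else:
        raise ValueError(f"unknown format {fmt!r} (expected 'dense' or 'mtx')")


def _write_id_column(path: Path, ids: Sequence[str]) -> None:
    with open(path, "w") as fh:
        fh.writelines(f"{i}\n" for i in ids)


def read_labels(path: str | Path, cell_ids: Sequence[str] | None = None) -> list[str]:
    """Read one cell label per line; length checked against ``cell_ids``."""
    path = Path(path)
    with open(path) as fh:
        labels = [line.strip() for line in fh if line.strip()]
    if not labels:
        raise CountMatrixError(f"no labels found in {path}")
    if cell_ids is not None and len(labels) != len(cell_ids):
        raise CountMatrixError(
            f"{len(labels)} labels for {len(cell_ids)} cells in {path}"
        )
    return labels


def write_labels(labels: Sequence[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.writelines(f"{lab}\n" for lab in labels)
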