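"""Count-matrix container and plain-text I/O.

UMI count matrices arrive either as 10x-style Matrix-Market directories
(``matrix.mtx`` plus ``features.tsv``/``genes.tsv`` and ``barcodes.tsv``) or
as dense CSV with gene ids in the first column and cell ids in the header
row.  Internally the matrix is always oriented genes x cells.  Zeros are
data, not missingness: sparse files are materialized to a logical dense
matrix on read.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger(__name__)

_MTX_NAMES = ("matrix.mtx", "matrix.mtx.gz")
_FEATURE_NAMES = ("features.tsv", "features.tsv.gz", "genes.tsv", "genes.tsv.gz")
_BARCODE_NAMES = ("barcodes.tsv", "barcodes.tsv.gz")


class CountValidationError(ValueError):
    """Raised when a matrix violates the count-matrix contract."""


@dataclass(eq=False)
class CountMatrix:
    """A genes x cells matrix of non-negative integer UMI counts.

    Parameters
    ----------
    values
        Integer array of shape (G, C); rows are genes, columns are cells.
    gene_ids, cell_ids
        Unique identifiers for rows and columns.
    """

    values: np.ndarray
    gene_ids: list[str] = field(default_factory=list)
    cell_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        if arr.ndim != 2:
            raise CountValidationError(f"count matrix must be 2-D, got shape {arr.shape}")
        if not np.issubdtype(arr.dtype, np.integer):
            rounded = np.rint(arr)
            bad = np.argwhere(~np.isclose(arr, rounded, atol=1e-9))
            if bad.size:
                g, c = bad[0]
                raise CountValidationError(
                    f"non-integer count {arr[g, c]!r} at gene row {g}, cell column {c}"
                )
            arr = rounded.astype(np.int64)
        else:
            arr = arr.astype(np.int64, copy=False)
        neg = np.argwhere(arr < 0)
        if neg.size:
            g, c = neg[0]
            raise CountValidationError(
                f"negative count {arr[g, c]} at gene row {g}, cell column {c}"
            )
        self.values = arr
        if not self.gene_ids:
            self.gene_ids = [f"gene{i}" for i in range(arr.shape[0])]
        if not self.cell_ids:
            self.cell_ids = [f"cell{j}" for j in range(arr.shape[1])]
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if len(self.gene_ids) != arr.shape[0]:
            raise CountValidationError(
                f"{len(self.gene_ids)} gene ids for {arr.shape[0]} rows"
            )
        if len(self.cell_ids) != arr.shape[1]:
            raise CountValidationError(
                f"{len(self.cell_ids)} cell ids for {arr.shape[1]} columns"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise CountValidationError("duplicate gene ids (refusing to merge silently)")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise CountValidationError("duplicate cell ids (refusing to merge silently)")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @cached_property
    def cell_totals(self) -> np.ndarray:
        """Library sizes n_c = sum_g x_gc."""
        return self.values.sum(axis=0)

    @cached_property
    def gene_totals(self) -> np.ndarray:
        return self.values.sum(axis=1)

    def subset(self, gene_idx=None, cell_idx=None) -> "CountMatrix":
        """Row/column subset preserving identifier order."""
        gi = np.arange(self.n_genes) if gene_idx is None else np.asarray(gene_idx)
        ci = np.arange(self.n_cells) if cell_idx is None else np.asarray(cell_idx)
        return CountMatrix(
            self.values[np.ix_(gi, ci)],
            [self.gene_ids[i] for i in gi],
            [self.cell_ids[j] for j in ci],
        )

    def equals(self, other: "CountMatrix") -> bool:
        return (
            np.array_equal(self.values, other.values)
            and self.gene_ids == other.gene_ids
            and self.cell_ids == other.cell_ids
        )


def _find(dirpath: Path, names: Sequence[str], what: str) -> Path:
    for name in names:
        p = dirpath / name
        if p.exists():
            return p
    raise FileNotFoundError(f"no {what} file ({'/'.join(names)}) in {dirpath}")


def _read_tsv_column(path: Path) -> list[str]:
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        return [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]


def read_counts(path, format: str = "auto") -> CountMatrix:
    """Read a count matrix from disk.

    ``mtx10x`` expects a directory holding a Matrix-Market file plus
    features/barcodes TSVs (10x convention: features in rows).  ``csv``
    expects a dense table with gene ids in the first column and cell ids in
    the header.  ``auto`` picks by whether *path* is a directory.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"count input {path} does not exist")
    if format == "auto":
        format = "mtx10x" if path.is_dir() else "csv"
    if format == "mtx10x":
        mtx = _find(path, _MTX_NAMES, "Matrix-Market")
        genes = _read_tsv_column(_find(path, _FEATURE_NAMES, "features/genes"))
        barcodes = _read_tsv_column(_find(path, _BARCODE_NAMES, "barcodes"))
        mat = scipy.io.mmread(mtx)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        mat = np.asarray(mat)
        if mat.shape == (len(genes), len(barcodes)):
            pass
        elif mat.shape == (len(barcodes), len(genes)):
            logger.info("matrix stored cells x genes; transposing to genes x cells")
            mat = mat.T
        else:
            raise CountValidationError(
                f"matrix shape {mat.shape} matches neither {len(genes)} features "
                f"x {len(barcodes)} barcodes nor its transpose"
            )
        return CountMatrix(mat, genes, barcodes)
    if format == "csv":
        df = pd.read_csv(path, index_col=0)
        return CountMatrix(df.to_numpy(), [str(i) for i in df.index], [str(c) for c in df.columns])
    raise ValueError(f"unknown format {format!r} (expected 'mtx10x' or 'csv')")


def write_counts(m: CountMatrix, path, format: str = "mtx10x") -> None:
    """Write *m* so that :func:`read_counts` reproduces it exactly."""
    if m.n_genes == 0 or m.n_cells == 0:
        raise ValueError("refusing to write an empty count matrix")
    path = Path(path)
    if format == "mtx10x":
        path.mkdir(parents=True, exist_ok=True)
        sparse = scipy.sparse.coo_matrix(m.values)
        scipy.io.mmwrite(path / "matrix.mtx", sparse, field="integer")
        (path / "features.tsv").write_text("".join(f"{g}\n" for g in m.gene_ids))
        (path / "barcodes.tsv").write_text("".join(f"{c}\n" for c in m.cell_ids))
    elif format == "csv":
        pd.DataFrame(m.values, index=m.gene_ids, columns=m.cell_ids).to_csv(path)
    else:
        raise ValueError(f"unknown format {format!r} (expected 'mtx10x' or 'csv')")


def filter_counts(m: CountMatrix) -> CountMatrix:
    """Drop all-zero gene rows and all-zero cell columns (survivor order kept).

    The two-way closed form takes logs of row and column means, so zero
    totals must be removed before fitting.  Idempotent.
    """
    keep_g = np.flatnonzero(m.gene_totals > 0)
    keep_c = np.flatnonzero(m.cell_totals > 0)
    if keep_g.size == 0 or keep_c.size == 0:
        raise ValueError("no informative entries (all counts zero)")
    if keep_g.size == m.n_genes and keep_c.size == m.n_cells:
        return m
    return m.subset(keep_g, keep_c)


def read_labels(path) -> pd.Series:
    """Read a two-column TSV (cell_id, label) into a Series indexed by cell."""
    df = pd.read_csv(path, sep="\t", header=None, names=["cell_id", "label"], dtype=str)
    return df.set_index("cell_id")["label"]


def write_labels(cell_ids: Sequence[str], labels: Sequence, path) -> None:
    pd.DataFrame({"cell_id": list(cell_ids), "label": list(labels)}).to_csv(
        path, sep="\t", header=False, index=False
    )
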