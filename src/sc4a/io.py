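"""Core data containers and file I/O.

Expression tables are nonnegative gene-by-sample (or, in the single-cell
orientation, cell-by-gene) abundance matrices.  Correspondence analysis treats
the table as a two-way contingency table, so validation enforces
nonnegativity and strictly positive row/column sums; all-zero rows and
columns are dropped with a logged warning rather than rejected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger("sc4a")

LOG2_10 = float(np.log2(10.0))


class Orientation(str, Enum):
    GENES_BY_SAMPLES = "genes_by_samples"
    CELLS_BY_GENES = "cells_by_genes"


class ValidationError(ValueError):
    """Raised when an input table violates the abundance-matrix contract."""


@dataclass
class ExpressionMatrix:
    """Nonnegative abundance table with named rows and columns.

    ``values`` holds counts or floored log2 intensities; ``orientation``
    records whether rows are genes (conventional mode) or cells (SC4A mode).
    """

    values: np.ndarray
    row_ids: list[str]
    col_ids: list[str]
    orientation: Orientation = Orientation.GENES_BY_SAMPLES

    @property
    def p(self) -> int:
        return self.values.shape[0]

    @property
    def m(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_ids, columns=self.col_ids)

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.copy(), list(self.row_ids), list(self.col_ids), self.orientation
        )

    def subset_rows(self, keep: Sequence[str]) -> "ExpressionMatrix":
        idx = {r: i for i, r in enumerate(self.row_ids)}
        rows = [idx[r] for r in keep]
        return ExpressionMatrix(
            self.values[rows, :], list(keep), list(self.col_ids), self.orientation
        )

    def subset_cols(self, keep: Sequence[str]) -> "ExpressionMatrix":
        idx = {c: i for i, c in enumerate(self.col_ids)}
        cols = [idx[c] for c in keep]
        return ExpressionMatrix(
            self.values[:, cols], list(self.row_ids), list(keep), self.orientation
        )


@dataclass
class MassStructure:
    """Row/column masses of an abundance table.

    ``r`` and ``c`` are the row and column sums divided by the grand total
    ``n``; they act as the diagonal weighting operators Dr and Dc of
    correspondence analysis.
    """

    r: np.ndarray
    c: np.ndarray
    n: float

    @property
    def Dr_sqrt(self) -> np.ndarray:
        return np.sqrt(self.r)

    @property
    def Dc_sqrt(self) -> np.ndarray:
        return np.sqrt(self.c)


@dataclass
class ExplanatoryMatrix:
    """Per-row covariates Z constraining the ordination (k columns)."""

    Z: np.ndarray
    names: list[str]
    standardized: bool = False

    @property
    def k(self) -> int:
        return self.Z.shape[1]

    def standardize(self) -> "ExplanatoryMatrix":
        """Return a copy with each column scaled to mean 0, variance 1."""
        Z = np.asarray(self.Z, dtype=float)
        mu = Z.mean(axis=0)
        sd = Z.std(axis=0)
        if np.any(sd == 0):
            bad = [self.names[i] for i in np.flatnonzero(sd == 0)]
            raise ValidationError(
                f"explanatory column(s) with zero variance cannot be standardized: {bad}"
            )
        return ExplanatoryMatrix((Z - mu) / sd, list(self.names), standardized=True)


@dataclass
class GeneSet:
    name: str
    members: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.members = set(self.members)
        if not self.members:
            raise ValidationError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene: str) -> bool:
        return gene in self.members


def _check_unique(ids: Sequence[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        seen, dup = set(), set()
        for x in ids:
            (dup if x in seen else seen).add(x)
        raise ValidationError(f"duplicate {what} identifiers: {sorted(dup)[:10]}")


def validate_expression(
    values: np.ndarray,
    row_ids: Sequence[str],
    col_ids: Sequence[str],
    orientation: Orientation = Orientation.GENES_BY_SAMPLES,
) -> ExpressionMatrix:
    """Validate and build an ExpressionMatrix, dropping all-zero rows/columns.

    Raises :class:`ValidationError` on negative entries, duplicate
    identifiers, or an empty matrix after filtering.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise ValidationError("expression values must be a 2D matrix")
    row_ids = [str(x) for x in row_ids]
    col_ids = [str(x) for x in col_ids]
    if values.shape != (len(row_ids), len(col_ids)):
        raise ValidationError(
            f"shape {values.shape} does not match {len(row_ids)} row ids "
            f"x {len(col_ids)} col ids"
        )
    _check_unique(row_ids, "row")
    _check_unique(col_ids, "column")
    if not np.all(np.isfinite(values)):
        i, j = np.argwhere(~np.isfinite(values))[0]
        raise ValidationError(
            f"non-finite value at row {row_ids[i]!r}, column {col_ids[j]!r}"
        )
    neg = np.argwhere(values < 0)
    if neg.size:
        i, j = neg[0]
        raise ValidationError(
            f"negative value {values[i, j]} at row {row_ids[i]!r}, "
            f"column {col_ids[j]!r}"
        )
    # iterate: dropping a row can zero out a column and vice versa
    rows = np.ones(values.shape[0], dtype=bool)
    cols = np.ones(values.shape[1], dtype=bool)
    while True:
        sub = values[np.ix_(rows, cols)]
        rs = sub.sum(axis=1)
        cs = sub.sum(axis=0)
        dead_r = rs == 0
        dead_c = cs == 0
        if not dead_r.any() and not dead_c.any():
            break
        rows[np.flatnonzero(rows)[dead_r]] = False
        cols[np.flatnonzero(cols)[dead_c]] = False
        if not rows.any() or not cols.any():
            raise ValidationError("matrix is empty after dropping zero rows/columns")
    n_drop_r = int((~rows).sum())
    n_drop_c = int((~cols).sum())
    if n_drop_r or n_drop_c:
        logger.warning(
            "dropped %d all-zero row(s) and %d all-zero column(s)", n_drop_r, n_drop_c
        )
    return ExpressionMatrix(
        values[np.ix_(rows, cols)],
        [r for r, k in zip(row_ids, rows) if k],
        [c for c, k in zip(col_ids, cols) if k],
        orientation,
    )


def read_expression(
    path: str | Path,
    format: str = "tsv",
    orientation: Orientation = Orientation.GENES_BY_SAMPLES,
    rows_file: str | Path | None = None,
    cols_file: str | Path | None = None,
) -> ExpressionMatrix:
    """Read an expression table from TSV or MatrixMarket triplet format.

    TSV: first column = row ids, header row = column ids, tab-separated.
    MatrixMarket: standard 1-based coordinate file plus sidecar name files
    (default ``<stem>.rows.txt`` / ``<stem>.cols.txt``, one id per line).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
        return validate_expression(
            df.to_numpy(dtype=float), list(df.index), list(df.columns), orientation
        )
    if format == "mtx_triplet":
        mat = scipy.io.mmread(path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        rows_file = Path(rows_file) if rows_file else path.with_suffix("").with_suffix(".rows.txt")
        cols_file = Path(cols_file) if cols_file else path.with_suffix("").with_suffix(".cols.txt")
        row_ids = rows_file.read_text().split()
        col_ids = cols_file.read_text().split()
        return validate_expression(np.asarray(mat, dtype=float), row_ids, col_ids, orientation)
    raise ValueError(f"unknown format {format!r}")


def write_expression(X: ExpressionMatrix, path: str | Path) -> None:
    """Write a TSV round-trippable at full float precision."""
    X.to_frame().to_csv(Path(path), sep="\t", float_format="%.17g")


def read_gene_list(path: str | Path, name: str | None = None) -> GeneSet:
    path = Path(path)
    members = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
    return GeneSet(name or path.stem, set(members))


def write_gene_list(gs: GeneSet, path: str | Path) -> None:
    Path(path).write_text("\n".join(sorted(gs.members)) + "\n")


def floor_log_intensities(X: ExpressionMatrix, floor: float = LOG2_10) -> ExpressionMatrix:
    """Zero entries below ``floor`` (default log2(10)); drop rows/columns
    that become all-zero.

    Intensities on the log2 scale below the detection floor are treated as
    absent so the table keeps a nonnegative abundance interpretation.
    """
    if floor < 0:
        raise ValueError("floor must be >= 0")
    vals = X.values.copy()
    vals[vals < floor] = 0.0
    return validate_expression(vals, X.row_ids, X.col_ids, X.orientation)


def compute_masses(X: ExpressionMatrix) -> MassStructure:
    """Row masses r, column masses c and grand total n of the table."""
    n = float(X.values.sum())
    if n <= 0:
        raise ValidationError("grand total of the expression matrix is zero")
    r = X.values.sum(axis=1) / n
    c = X.values.sum(axis=0) / n
    return MassStructure(r=r, c=c, n=n)
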