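"""Labelled non-negative expression matrices and delimited-text I/O.

Genes are rows everywhere; samples, cells or cell types are columns.
All on-disk formats are plain delimited text with a header row of column
identifiers and a leading column of gene identifiers.  Tab is the
preferred delimiter; comma is accepted on input, tab is always written.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "ParseError",
    "ExpressionMatrix",
    "FractionMatrix",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_fraction_matrix",
    "read_cell_annotations",
    "align_genes",
]

UNIT_TAGS = ("counts", "cpm", "model")


class ValidationError(ValueError):
    """An input violates a structural invariant (negativity, duplicates, shape)."""


class ParseError(ValueError):
    """A delimited-text file could not be parsed as a numeric matrix."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise ValidationError(f"duplicate {what} identifier: {x!r}")
        seen.add(x)


@dataclass
class ExpressionMatrix:
    """A genes x columns matrix of non-negative expression values.

    The common currency for bulk samples B, reference profiles S, and
    inferred cell-type profiles C.  ``unit_tag`` records the scale:
    raw ``counts``, counts-per-million ``cpm``, or solver-internal
    ``model`` units.
    """

    values: np.ndarray
    gene_ids: list[str]
    column_ids: list[str]
    unit_tag: str = "counts"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.column_ids = [str(c) for c in self.column_ids]
        if self.values.ndim != 2:
            raise ValidationError("expression values must be a 2-D matrix")
        m, p = self.values.shape
        if m < 1 or p < 1:
            raise ValidationError("expression matrix must have >=1 gene and >=1 column")
        if len(self.gene_ids) != m:
            raise ValidationError(
                f"{len(self.gene_ids)} gene ids for {m} rows"
            )
        if len(self.column_ids) != p:
            raise ValidationError(
                f"{len(self.column_ids)} column ids for {p} columns"
            )
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.column_ids, "column")
        if self.unit_tag not in UNIT_TAGS:
            raise ValidationError(
                f"unit_tag must be one of {UNIT_TAGS}, got {self.unit_tag!r}"
            )
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ValidationError(
                f"non-finite value for gene {self.gene_ids[i]!r} "
                f"in column {self.column_ids[j]!r}"
            )
        if np.any(self.values < 0):
            i, j = np.argwhere(self.values < 0)[0]
            raise ValidationError(
                f"negative value {self.values[i, j]} for gene "
                f"{self.gene_ids[i]!r} in column {self.column_ids[j]!r}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_frame(cls, df: pd.DataFrame, unit_tag: str = "counts") -> "ExpressionMatrix":
        return cls(
            values=df.to_numpy(dtype=float),
            gene_ids=list(df.index.astype(str)),
            column_ids=list(df.columns.astype(str)),
            unit_tag=unit_tag,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.gene_ids, columns=self.column_ids)
        df.index.name = "gene_id"
        return df

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.copy(), list(self.gene_ids), list(self.column_ids), self.unit_tag
        )

    def with_values(self, values: np.ndarray, unit_tag: str | None = None) -> "ExpressionMatrix":
        """Same labels, new values (and optionally a new unit tag)."""
        return ExpressionMatrix(
            values, list(self.gene_ids), list(self.column_ids), unit_tag or self.unit_tag
        )

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        index = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in index]
        if missing:
            raise ValidationError(f"genes not present: {missing[:5]}")
        rows = [index[g] for g in genes]
        return ExpressionMatrix(
            self.values[rows, :], list(genes), list(self.column_ids), self.unit_tag
        )

    def equals(self, other: "ExpressionMatrix") -> bool:
        return (
            self.gene_ids == other.gene_ids
            and self.column_ids == other.column_ids
            and self.values.shape == other.values.shape
            and np.array_equal(self.values, other.values)
        )


@dataclass
class FractionMatrix:
    """Cell-type fractions: K cell types x n samples, simplex columns.

    Entries are non-negative (to solver tolerance 1e-8) and every
    column sums to one within 1e-6.
    """

    values: np.ndarray
    cell_type_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.cell_type_ids = [str(c) for c in self.cell_type_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.ndim != 2:
            raise ValidationError("fraction values must be a 2-D matrix")
        K, n = self.values.shape
        if len(self.cell_type_ids) != K or len(self.sample_ids) != n:
            raise ValidationError("fraction matrix identifier lengths do not match shape")
        _check_unique(self.cell_type_ids, "cell-type")
        _check_unique(self.sample_ids, "sample")
        if np.any(self.values < -1e-8):
            l, j = np.argwhere(self.values < -1e-8)[0]
            raise ValidationError(
                f"negative fraction {self.values[l, j]} for type "
                f"{self.cell_type_ids[l]!r}, sample {self.sample_ids[j]!r}"
            )
        sums = self.values.sum(axis=0)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            j = int(np.argmax(np.abs(sums - 1.0)))
            raise ValidationError(
                f"fractions for sample {self.sample_ids[j]!r} sum to {sums[j]}, not 1"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.cell_type_ids, columns=self.sample_ids)
        df.index.name = "cell_type"
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FractionMatrix":
        return cls(
            values=df.to_numpy(dtype=float),
            cell_type_ids=list(df.index.astype(str)),
            sample_ids=list(df.columns.astype(str)),
        )


def _detect_delimiter(path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    if "\t" in header:
        return "\t"
    if "," in header:
        return ","
    raise ParseError(f"{path}: header line contains neither tab nor comma")


def _read_labelled_frame(path) -> pd.DataFrame:
    sep = _detect_delimiter(path)
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    if df.shape[1] == 0:
        raise ParseError(f"{path}: no data columns found")
    df.index = df.index.astype(str)
    numeric = pd.DataFrame(index=df.index)
    for col in df.columns:
        try:
            # Series.astype is a correctly-rounded parser (round-trip safe),
            # unlike pd.to_numeric
            converted = df[col].astype(float)
        except (ValueError, TypeError):
            converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna()
        if bad.any():
            pos = int(np.flatnonzero(bad.to_numpy())[0])
            raw = df[col].iloc[pos]
            # line 1 is the header, data starts at line 2
            raise ParseError(
                f"{path}: non-numeric value {raw!r} in column {col!r} at line {pos + 2}"
            )
        numeric[col] = converted.to_numpy(dtype=float)
    return numeric


def read_expression_matrix(path, unit_tag: str = "counts") -> ExpressionMatrix:
    """Read a genes x columns matrix from tab- or comma-delimited text.

    The first column holds gene identifiers, the header row column
    identifiers.  The delimiter is auto-detected from the header line
    (tab preferred, comma fallback).  Raises :class:`ParseError` on
    non-numeric cells (with the offending line number) and
    :class:`ValidationError` on duplicate identifiers or negative
    entries.
    """
    df = _read_labelled_frame(path)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValidationError(f"{path}: duplicate gene identifier {dup!r}")
    return ExpressionMatrix.from_frame(df, unit_tag=unit_tag)


def _full_precision(v) -> str:
    # shortest decimal string that round-trips to the same double
    return repr(float(v))


def write_expression_matrix(mat: ExpressionMatrix, path) -> None:
    """Write a matrix as TSV at full double precision (round-trip safe)."""
    if not isinstance(mat, ExpressionMatrix):
        raise TypeError("write_expression_matrix expects an ExpressionMatrix")
    mat.to_frame().to_csv(path, sep="\t", float_format=_full_precision)


def read_fraction_matrix(path) -> FractionMatrix:
    """Read a cell-types x samples fraction matrix (simplex columns)."""
    df = _read_labelled_frame(path)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValidationError(f"{path}: duplicate cell-type identifier {dup!r}")
    return FractionMatrix.from_frame(df)


def write_fraction_matrix(frac: FractionMatrix, path) -> None:
    frac.to_frame().to_csv(path, sep="\t", float_format=_full_precision)


def read_cell_annotations(path) -> pd.Series:
    """Read a two-column (cell_id, cell_type) table with a header row.

    Returns a Series mapping cell id -> cell-type label, in file order.
    """
    sep = _detect_delimiter(path)
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: annotation table needs two columns (cell_id, cell_type)")
    cells = df.iloc[:, 0].astype(str)
    types = df.iloc[:, 1].astype(str)
    if cells.duplicated().any():
        dup = cells[cells.duplicated()].iloc[0]
        raise ValidationError(f"{path}: cell {dup!r} annotated more than once")
    ann = pd.Series(types.to_numpy(), index=cells.to_numpy(), name="cell_type")
    ann.index.name = "cell_id"
    return ann


def align_genes(
    a: ExpressionMatrix, b: ExpressionMatrix
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Restrict both matrices to their common genes, in ``a``'s row order.

    Raises :class:`ValidationError` when the gene sets are disjoint.
    """
    b_set = set(b.gene_ids)
    common = [g for g in a.gene_ids if g in b_set]
    if not common:
        raise ValidationError("no genes shared between the two matrices")
    return a.subset_genes(common), b.subset_genes(common)
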