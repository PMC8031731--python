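"""Readers, writers and alignment for DepMap-style delimited tables.

Expression comes as a genes x cell-lines RPKM table (CCLE layout: one
header row of cell-line identifiers, first column gene symbols) and is
transformed to log2(RPKM+1) on read. Dependency scores (DEMETER layout)
use the same genes x cells shape but may contain missing entries.
Annotations are a two-column table (cell_id, tissue).

CSV vs TSV is auto-detected from the file extension (``.tsv``/``.txt``
-> tab) unless ``sep`` is given explicitly.
"""

from __future__ import annotations

import os
from typing import Iterable

import numpy as np
import pandas as pd

from .datatypes import (
    CellAnnotation,
    DependencyMatrix,
    ExpressionMatrix,
    ValidationError,
)

__all__ = [
    "DEFAULT_EXCLUDED_TISSUES",
    "read_expression",
    "read_dependency",
    "read_annotation",
    "align_datasets",
    "write_expression",
    "write_dependency",
    "write_annotation",
    "AlignmentError",
]

#: Tissue labels dropped by default during alignment. Blood-derived lines
#: have a genetic background unlike solid tumours and are excluded from
#: the screen; the exact label strings vary between annotation releases,
#: so this is a config default, not a hard rule.
DEFAULT_EXCLUDED_TISSUES = frozenset(
    {
        "haematopoietic",
        "hematopoietic",
        "haematopoietic_and_lymphoid_tissue",
        "haematopoietic and lymphoid tissue",
    }
)


class AlignmentError(ValueError):
    """Raised when the input tables share no usable cell lines."""


def _sep_for(path: str, sep: str | None) -> str:
    if sep is not None:
        return sep
    ext = os.path.splitext(str(path))[1].lower()
    return "\t" if ext in {".tsv", ".txt"} else ","


def _read_numeric_table(path, sep: str | None, what: str) -> pd.DataFrame:
    frame = pd.read_csv(path, sep=_sep_for(path, sep), index_col=0)
    frame.index = frame.index.astype(str).rename(None)
    frame.columns = frame.columns.astype(str).rename(None)
    for col in frame.columns:
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = coerced.isna() & frame[col].notna()
        if bad.any():
            row = frame.index[bad.to_numpy().argmax()]
            raise ValidationError(
                f"non-numeric {what} value at row {row!r}, column {col!r}: "
                f"{frame.loc[row, col]!r}"
            )
        frame[col] = coerced
    return frame.astype(float)


def read_expression(path, already_log: bool = False, sep: str | None = None) -> ExpressionMatrix:
    """Read a genes x cells RPKM (or pre-logged) table.

    Unless ``already_log`` is set, every value x is replaced by
    log2(x + 1); negative RPKM values and duplicate gene rows are
    rejected.
    """
    frame = _read_numeric_table(path, sep, "expression")
    if not already_log:
        values = frame.to_numpy()
        if (values < 0).any():
            bad = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative RPKM at gene {frame.index[bad[0]]!r}, "
                f"cell {frame.columns[bad[1]]!r}"
            )
        frame = pd.DataFrame(
            np.log2(values + 1.0), index=frame.index, columns=frame.columns
        )
    return ExpressionMatrix(frame)


def read_dependency(path, sep: str | None = None) -> DependencyMatrix:
    """Read a genes x cells dependency-score table (NaN = missing)."""
    return DependencyMatrix(_read_numeric_table(path, sep, "dependency score"))


def read_annotation(path, sep: str | None = None) -> CellAnnotation:
    """Read a two-column (cell_id, tissue) annotation table."""
    frame = pd.read_csv(path, sep=_sep_for(path, sep))
    if frame.shape[1] < 2:
        raise ValidationError("annotation table needs (cell_id, tissue) columns")
    series = pd.Series(
        frame.iloc[:, 1].to_numpy(), index=frame.iloc[:, 0].astype(str), name="tissue"
    )
    series.index.name = "cell_id"
    return CellAnnotation(series)


def align_datasets(
    expr: ExpressionMatrix,
    dep: DependencyMatrix,
    ann: CellAnnotation,
    exclude_tissues: Iterable[str] = DEFAULT_EXCLUDED_TISSUES,
) -> tuple[ExpressionMatrix, DependencyMatrix, CellAnnotation]:
    """Restrict all three tables to shared cell lines minus excluded tissues.

    Both matrices come back with identical column order (sorted shared
    ids); the annotation is restricted to the same cells. Raises
    :class:`AlignmentError` if nothing survives.
    """
    excluded = {str(t).strip().lower() for t in exclude_tissues}
    shared = sorted(set(expr.cell_ids) & set(dep.cell_ids))
    kept = [
        c
        for c in shared
        if c in ann.tissues.index and ann.tissue_of(c) not in excluded
    ]
    if not kept:
        raise AlignmentError(
            "no cell lines shared by expression and dependency tables after "
            f"excluding tissues {sorted(excluded)}"
        )
    return (
        ExpressionMatrix(expr.data[kept]),
        DependencyMatrix(dep.data[kept]),
        ann.subset(kept),
    )


def write_expression(expr: ExpressionMatrix, path, sep: str | None = None) -> None:
    """Write log2(RPKM+1) values; re-read with ``already_log=True``."""
    expr.data.to_csv(path, sep=_sep_for(path, sep), index_label="gene")


def write_dependency(dep: DependencyMatrix, path, sep: str | None = None) -> None:
    dep.data.to_csv(path, sep=_sep_for(path, sep), index_label="gene")


def write_annotation(ann: CellAnnotation, path, sep: str | None = None) -> None:
    frame = ann.tissues.rename_axis("cell_id").reset_index()
    frame.to_csv(path, sep=_sep_for(path, sep), index=False)
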