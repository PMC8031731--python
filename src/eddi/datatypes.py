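"""Core in-memory containers for the dependency-screening pipeline.

The pipeline works on three aligned tables:

* :class:`ExpressionMatrix` — genes x cell lines, log2(RPKM+1) expression.
  This is the sole predictive feature space.
* :class:`DependencyMatrix` — genes x cell lines, RNAi dependency scores
  (DEMETER-style; more negative means the line depends more strongly on
  the gene). Missing scores are allowed and kept as NaN.
* :class:`CellAnnotation` — one tissue/lineage label per cell line.

All three are thin, validated wrappers around :class:`pandas.DataFrame` /
:class:`pandas.Series`; the frames themselves are exposed as ``.data`` so
downstream code can use ordinary pandas operations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "DependencyMatrix",
    "CellAnnotation",
    "ValidationError",
]


class ValidationError(ValueError):
    """Raised when an input table violates a container invariant."""


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dups = index[index.duplicated()].unique().tolist()[:5]
        raise ValidationError(f"duplicate {what}: {dups}")


@dataclass(frozen=True)
class ExpressionMatrix:
    """Gene x cell-line matrix of log2(RPKM+1) expression values.

    Invariants (enforced at construction): all values finite and >= 0,
    gene and cell identifiers unique.
    """

    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "gene ids")
        _check_unique(self.data.columns, "cell ids")
        values = self.data.to_numpy()
        if not np.isfinite(values).all():
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValidationError(
                "non-finite expression value at gene "
                f"{self.data.index[bad[0]]!r}, cell {self.data.columns[bad[1]]!r}"
            )
        if (values < 0).any():
            bad = np.argwhere(values < 0)[0]
            raise ValidationError(
                "negative log2(RPKM+1) value at gene "
                f"{self.data.index[bad[0]]!r}, cell {self.data.columns[bad[1]]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def cell_ids(self) -> list[str]:
        return self.data.columns.tolist()

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_cells(self) -> int:
        return self.data.shape[1]

    def gene(self, gene_id: str) -> np.ndarray:
        """Expression vector of one gene across cells, in column order."""
        return self.data.loc[gene_id].to_numpy(dtype=float)


@dataclass(frozen=True)
class DependencyMatrix:
    """Gene x cell-line matrix of dependency scores (more negative = more
    dependent). Entries may be missing (NaN); everything present is finite.
    """

    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "dependency gene ids")
        _check_unique(self.data.columns, "cell ids")
        values = self.data.to_numpy()
        if np.isinf(values).any():
            bad = np.argwhere(np.isinf(values))[0]
            raise ValidationError(
                "infinite dependency score at gene "
                f"{self.data.index[bad[0]]!r}, cell {self.data.columns[bad[1]]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def cell_ids(self) -> list[str]:
        return self.data.columns.tolist()

    def scores(self, dependency_id: str) -> np.ndarray:
        """Score vector of one dependency across cells (NaN = missing)."""
        return self.data.loc[dependency_id].to_numpy(dtype=float)


@dataclass(frozen=True)
class CellAnnotation:
    """Mapping cell line -> tissue/lineage label (lower-cased free strings)."""

    tissues: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        _check_unique(self.tissues.index, "annotated cell ids")
        object.__setattr__(
            self, "tissues", self.tissues.astype(str).str.strip().str.lower()
        )

    @property
    def cell_ids(self) -> list[str]:
        return self.tissues.index.tolist()

    def tissue_of(self, cell_id: str) -> str:
        try:
            return str(self.tissues.loc[cell_id])
        except KeyError:
            raise ValidationError(f"cell line {cell_id!r} has no tissue annotation")

    def subset(self, cell_ids) -> "CellAnnotation":
        missing = [c for c in cell_ids if c not in self.tissues.index]
        if missing:
            raise ValidationError(f"unannotated cell lines: {missing[:5]}")
        return CellAnnotation(self.tissues.loc[list(cell_ids)])
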