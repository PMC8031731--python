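"""Stage 5 — mode-of-expression labels for accepted predictor pairs.

Every predictor of a dependency that cleared the forest gate is
characterized by how its expression differs between dependent and
non-dependent cell lines:

* ``over`` / ``under`` — at least a two-fold difference (|log2 FC| >= 1)
  with Benjamini–Hochberg adjusted p < 0.05; the default differential-
  expression engine is Welch's t-test per gene on log2(RPKM+1) values
  (an externally computed DE table can be plugged in instead).
* ``suppressed_under`` — under-expression where the dependent cells are
  essentially silenced: median log2(RPKM+1) below 0.1.
* ``separable`` — an orthogonal flag: |Pearson r| >= 0.5 between the
  gene's expression and the 0/1 dependent-cell template vector.
* SEESAW direction, when the relaxed-lasso stage selected the gene.

Pairs meeting no criterion are kept in the output with an empty mode
for auditability but excluded from DDP tallies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import ExpressionMatrix

__all__ = [
    "ModeConfig",
    "DDPRecord",
    "differential_expression",
    "suppression_flag",
    "template_match",
    "assemble_ddp_records",
    "characterize_dependency",
    "ddp_records_to_frame",
]


@dataclass(frozen=True)
class ModeConfig:
    fc_threshold: float = 1.0  # |log2 FC| for the 2-fold rule
    alpha: float = 0.05  # BH-adjusted significance
    suppression_cutoff: float = 0.1  # log2(RPKM+1) silencing level
    suppression_rule: str = "median"  # or "all"
    separable_threshold: float = 0.5  # |template r|


@dataclass(frozen=True)
class DDPRecord:
    dependency_id: str
    predictor_id: str
    log2_fold_change: float = np.nan
    adj_p: float = np.nan
    mode: str | None = None  # over | under | suppressed_under
    separable: bool = False
    seesaw: str | None = None  # SEE | SAW
    template_r: float = np.nan

    @property
    def is_ddp(self) -> bool:
        """True when at least one labeling criterion was met."""
        return self.mode is not None or self.separable or self.seesaw is not None

    @property
    def label(self) -> str:
        parts = []
        if self.mode is not None:
            parts.append(("separable_" + self.mode) if self.separable and self.mode in ("over", "under") else self.mode)
        elif self.separable:
            parts.append("separable")
        if self.seesaw is not None:
            parts.append(self.seesaw)
        return "+".join(parts)


def differential_expression(
    expr: ExpressionMatrix,
    dependent_cells,
    engine: str = "welch",
    external_table: pd.DataFrame | None = None,
    dependency_id: str = "",
) -> pd.DataFrame:
    """Per-gene DE between dependent and non-dependent cells.

    Returns a frame indexed by gene with columns ``log2_fold_change``
    (mean dependent minus mean non-dependent, log2 scale), ``p`` and
    BH-adjusted ``adj_p``. ``engine='external'`` passes a user table
    through (must carry the same columns keyed by gene).
    """
    if engine == "external":
        if external_table is None:
            raise ValueError("engine='external' needs external_table")
        required = {"log2_fold_change", "p", "adj_p"}
        if not required <= set(external_table.columns):
            raise ValueError(f"external DE table must have columns {sorted(required)}")
        return external_table
    if engine != "welch":
        raise ValueError(f"unknown DE engine {engine!r}")

    dependent_cells = set(dependent_cells)
    mask = np.array([c in dependent_cells for c in expr.cell_ids])
    if mask.sum() < 2 or (~mask).sum() < 2:
        raise ValueError(
            f"dependency {dependency_id!r}: both groups need >= 2 cells "
            f"({int(mask.sum())} dependent, {int((~mask).sum())} non-dependent)"
        )
    values = expr.data.to_numpy()
    a, b = values[:, mask], values[:, ~mask]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # zero-variance genes yield NaN
        t = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.where(np.isfinite(t.pvalue), t.pvalue, 1.0)
    adj_p = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "log2_fold_change": a.mean(axis=1) - b.mean(axis=1),
            "p": p,
            "adj_p": adj_p,
        },
        index=pd.Index(expr.gene_ids, name="gene"),
    )


def suppression_flag(
    expr_dependent: np.ndarray, cutoff: float = 0.1, rule: str = "median"
) -> bool:
    """Is the gene essentially silenced in the dependent cells?"""
    v = np.asarray(expr_dependent, dtype=float)
    if v.size == 0:
        raise ValueError("empty dependent expression vector")
    if rule == "all":
        return bool((v < cutoff).all())
    if rule == "median":
        return bool(np.median(v) < cutoff)
    raise ValueError(f"unknown suppression rule {rule!r}")


def template_match(expr: np.ndarray, dependent_mask: np.ndarray) -> float:
    """Pearson r between expression and the 0/1 dependent template."""
    x = np.asarray(expr, dtype=float)
    t = np.asarray(dependent_mask, dtype=float)
    if t.sum() == 0 or t.sum() == t.size:
        raise ValueError("both classes must be nonempty")
    if np.ptp(x) == 0.0:
        warnings.warn("constant expression vector; template r set to 0")
        return 0.0
    return float(stats.pearsonr(x, t).statistic)


def assemble_ddp_records(
    dependency_id: str,
    predictors,
    de_table: pd.DataFrame,
    suppression_flags: dict[str, bool],
    template_rs: dict[str, float],
    seesaw_directions: dict[str, str],
    config: ModeConfig | None = None,
) -> list[DDPRecord]:
    """Combine the per-predictor evidence into mode-labeled records.

    ``suppressed_under`` supersedes ``under`` when the suppression flag
    holds (it implies the under-expression DE criterion by
    construction); ``separable`` and SEESAW are attached orthogonally.
    """
    if config is None:
        config = ModeConfig()
    records = []
    for gene in predictors:
        missing = [
            name
            for name, ok in [
                ("DE table", gene in de_table.index),
                ("suppression flags", gene in suppression_flags),
                ("template correlations", gene in template_rs),
            ]
            if not ok
        ]
        if missing:
            raise KeyError(f"predictor {gene!r} missing from: {missing}")
        lfc = float(de_table.loc[gene, "log2_fold_change"])
        adj_p = float(de_table.loc[gene, "adj_p"])
        mode = None
        if adj_p < config.alpha and lfc >= config.fc_threshold:
            mode = "over"
        elif adj_p < config.alpha and lfc <= -config.fc_threshold:
            mode = "suppressed_under" if suppression_flags[gene] else "under"
        r = template_rs[gene]
        records.append(
            DDPRecord(
                dependency_id=dependency_id,
                predictor_id=gene,
                log2_fold_change=lfc,
                adj_p=adj_p,
                mode=mode,
                separable=bool(abs(r) >= config.separable_threshold),
                seesaw=seesaw_directions.get(gene),
                template_r=r,
            )
        )
    return records


def characterize_dependency(
    expr: ExpressionMatrix,
    dependency_id: str,
    dependent_cells,
    predictors,
    seesaw_directions: dict[str, str] | None = None,
    config: ModeConfig | None = None,
    de_engine: str = "welch",
    external_de: pd.DataFrame | None = None,
) -> list[DDPRecord]:
    """Run DE, suppression, template matching and assembly for one dependency."""
    if config is None:
        config = ModeConfig()
    de = differential_expression(
        expr,
        dependent_cells,
        engine=de_engine,
        external_table=external_de,
        dependency_id=dependency_id,
    )
    dependent_cells = set(dependent_cells)
    mask = np.array([c in dependent_cells for c in expr.cell_ids])
    suppression = {
        g: suppression_flag(
            expr.gene(g)[mask], config.suppression_cutoff, config.suppression_rule
        )
        for g in predictors
    }
    template = {g: template_match(expr.gene(g), mask) for g in predictors}
    return assemble_ddp_records(
        dependency_id,
        predictors,
        de,
        suppression,
        template,
        seesaw_directions or {},
        config,
    )


def ddp_records_to_frame(records: list[DDPRecord]) -> pd.DataFrame:
    """Master DDP table (one row per dependency-predictor pair)."""
    return pd.DataFrame(
        {
            "dependency_id": [r.dependency_id for r in records],
            "predictor_id": [r.predictor_id for r in records],
            "log2_fold_change": [r.log2_fold_change for r in records],
            "adj_p": [r.adj_p for r in records],
            "mode": [r.mode if r.mode is not None else "" for r in records],
            "separable": [r.separable for r in records],
            "seesaw": [r.seesaw if r.seesaw is not None else "" for r in records],
            "template_r": [r.template_r for r in records],
            "is_ddp": [r.is_ddp for r in records],
            "label": [r.label for r in records],
        }
    )
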