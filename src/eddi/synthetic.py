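"""Seeded synthetic expression/dependency/annotation fixtures.

The generator emulates the three pipeline inputs — a non-negative
RPKM-scale expression matrix, a real-valued dependency-score matrix
("more negative = more dependent") and a tissue annotation including a
removable blood-lineage class — with *planted* predictor–dependency
relationships of every expression mode the pipeline can label:

``over`` / ``separable_over``
    dependent cells shifted up in log2 expression by ``effect_size``
    (the separable variant uses a shift large enough that class
    interquartile ranges cannot overlap).
``under`` / ``separable_under``
    the mirror-image down-shift.
``suppressed_under``
    dependent-cell expression pinned below 0.1 on the log2(RPKM+1)
    scale — near-complete silencing.
``seesaw_up`` / ``seesaw_down``
    dependent-cell expression linear in the dependency score; ``up``
    means expression rises with stronger dependency (the SEE direction,
    negative slope against the score), ``down`` the opposite (SAW).
``null``
    expression noise independent of every dependency.

Every planted non-null predictor additionally carries a linear dose
component within the dependent class (scaled to the mode's effect
size): the relationships being planted are dosage-based by definition,
and the screen's linearity filter requires it. Dependency scores are
bimodal by construction — dependent cells ~ Normal(-3, 0.3) truncated
below -2, non-dependent ~ Normal(0, 0.5) truncated above -2 — so
ground-truth labels are unambiguous and the -2 hard threshold used in
the strict labeling stage is exactly respected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import CellAnnotation, DependencyMatrix, ExpressionMatrix

__all__ = [
    "MODES",
    "PlantedPair",
    "SyntheticDataset",
    "ConfigurationError",
    "generate",
    "demo_planting",
]

MODES = (
    "over",
    "separable_over",
    "under",
    "separable_under",
    "suppressed_under",
    "seesaw_up",
    "seesaw_down",
    "null",
)

#: dependency-score generating distributions (hard threshold at -2)
_DEP_MEAN, _DEP_SD = -3.0, 0.3
_NONDEP_MEAN, _NONDEP_SD = 0.0, 0.5
_HARD_THRESHOLD = -2.0


class ConfigurationError(ValueError):
    """Raised for infeasible planting configurations."""


@dataclass(frozen=True)
class PlantedPair:
    """One planted (dependency, predictor) relationship."""

    dependency_id: str
    predictor_id: str
    mode: str
    effect_size: float = 2.0
    dependent_fraction: float = 0.25

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ConfigurationError(
                f"unknown mode {self.mode!r}; expected one of {MODES}"
            )
        if not 0.0 < self.dependent_fraction < 1.0:
            raise ConfigurationError("dependent_fraction must lie in (0, 1)")


@dataclass(frozen=True)
class SyntheticDataset:
    """Generated fixture plus its ground truth."""

    expression: ExpressionMatrix
    dependency: DependencyMatrix
    annotation: CellAnnotation
    truth: pd.DataFrame = field(repr=False)  # dependency, predictor, mode, ...
    dependent_cells: dict[str, frozenset] = field(repr=False)

    def write(self, directory) -> dict[str, str]:
        """Write the three input CSVs (expression on the RPKM scale, so
        ``io.read_expression`` round-trips end-to-end) plus the truth table.
        """
        import os

        from .io import write_annotation, write_dependency

        os.makedirs(directory, exist_ok=True)
        paths = {
            "expression": os.path.join(directory, "expression.csv"),
            "dependency": os.path.join(directory, "dependency.csv"),
            "annotation": os.path.join(directory, "annotation.csv"),
            "truth": os.path.join(directory, "truth.csv"),
        }
        rpkm = pd.DataFrame(
            np.exp2(self.expression.data.to_numpy()) - 1.0,
            index=self.expression.data.index,
            columns=self.expression.data.columns,
        ).clip(lower=0.0)
        rpkm.to_csv(paths["expression"], index_label="gene")
        write_dependency(self.dependency, paths["dependency"])
        write_annotation(self.annotation, paths["annotation"])
        self.truth.to_csv(paths["truth"], index=False)
        return paths


def _truncnorm(rng, mean, sd, size, upper=None, lower=None):
    a = -np.inf if lower is None else (lower - mean) / sd
    b = np.inf if upper is None else (upper - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _planted_expression(mode, effect, scores, dep_mask, noise_sd, rng, n_cells):
    """Log2-scale expression for one planted predictor."""
    expr = np.empty(n_cells)
    s_dep = scores[dep_mask]
    dose = s_dep - s_dep.mean()  # centred dependency score, sd ~ 0.3
    n_dep = dep_mask.sum()
    n_non = n_cells - n_dep
    noise = lambda n, sd: rng.normal(0.0, sd, n) if sd > 0 else np.zeros(n)

    # non-seesaw modes carry only the moderate dose trend the linearity
    # screen requires; seesaw modes are the dominant linear signals
    # (tight within-class noise), mirroring what the labels mean
    trend = 0.5 * min(effect, 2.0)
    if mode in ("over", "separable_over"):
        if mode == "separable_over":
            effect = max(effect, 2.5 + 6.0 * noise_sd)
        expr[~dep_mask] = 2.0 + noise(n_non, noise_sd)
        expr[dep_mask] = 2.0 + effect - trend * dose + noise(n_dep, noise_sd)
    elif mode in ("under", "separable_under"):
        if mode == "separable_under":
            effect = max(effect, 2.5 + 6.0 * noise_sd)
        expr[~dep_mask] = 0.8 + effect + noise(n_non, noise_sd)
        expr[dep_mask] = 0.8 + 0.5 * trend * dose + noise(n_dep, 0.4 * noise_sd)
    elif mode == "suppressed_under":
        expr[~dep_mask] = max(2.0, effect) + noise(n_non, noise_sd)
        expr[dep_mask] = np.clip(
            0.04 - 0.02 * dose + noise(n_dep, 0.02 * noise_sd), 0.0, 0.099
        )
    elif mode == "seesaw_up":
        expr[~dep_mask] = 1.0 + noise(n_non, noise_sd)
        expr[dep_mask] = 1.2 + effect - 1.2 * dose + noise(n_dep, 0.3 * noise_sd)
    elif mode == "seesaw_down":
        expr[~dep_mask] = 1.0 + noise(n_non, noise_sd)
        expr[dep_mask] = 1.2 + effect + 1.2 * dose + noise(n_dep, 0.3 * noise_sd)
    else:  # pragma: no cover - guarded by PlantedPair validation
        raise ConfigurationError(f"unknown mode {mode!r}")
    return np.clip(expr, 0.0, None)


def generate(
    n_cells: int,
    n_genes: int,
    planted: list[PlantedPair],
    noise_sd: float = 0.25,
    seed: int = 0,
    tissue_labels: tuple[str, ...] = ("skin", "lung", "breast", "pancreas", "kidney"),
    haematopoietic_fraction: float = 0.0,
    min_cluster_size: int = 20,
    correlated_dependencies: dict[str, str] | None = None,
) -> SyntheticDataset:
    """Generate one seeded fixture with the given planted relationships.

    Parameters
    ----------
    n_cells, n_genes
        Dimensions of the fixture (``n_cells >= 40``); predictors named
        in ``planted`` count toward ``n_genes``, the remainder are null
        filler genes.
    planted
        Planted relationships; pairs sharing a dependency must agree on
        ``dependent_fraction`` (one dependent-cell set per dependency).
    noise_sd
        Within-class Gaussian noise on the log2 scale. Zero gives the
        fully deterministic constructions used by closed-form tests.
    haematopoietic_fraction
        Fraction of cells labeled ``haematopoietic`` (removable during
        alignment).
    min_cluster_size
        Feasibility floor: each dependency's dependent-cell count must
        reach it, else the planted pair could never survive labeling.
    correlated_dependencies
        Mapping child -> parent dependency. A child shares the parent's
        dependent-cell set and its scores are the parent's plus small
        noise (the below/above -2 partition is preserved exactly). This
        emulates co-dependencies: predictors planted for the parent are
        genuine dosage predictors of the child too, so shared-predictor
        network structure arises.
    """
    if n_cells < 40:
        raise ConfigurationError("n_cells must be at least 40")
    rng = np.random.default_rng(seed)

    predictors = [p.predictor_id for p in planted if p.mode != "null"]
    if len(predictors) != len(set(predictors)):
        raise ConfigurationError("planted predictor ids must be unique")

    cells = [f"CL{i:04d}" for i in range(n_cells)]
    # tissue labels, optionally with a removable blood-lineage class
    n_haem = int(round(haematopoietic_fraction * n_cells))
    tissues = np.array(
        ["haematopoietic"] * n_haem
        + [tissue_labels[i % len(tissue_labels)] for i in range(n_cells - n_haem)]
    )
    rng.shuffle(tissues)
    annotation = CellAnnotation(pd.Series(tissues, index=pd.Index(cells, name="cell_id")))

    # one dependent-cell set and one score vector per dependency
    dep_ids, frac_by_dep = [], {}
    for p in planted:
        if p.dependency_id not in frac_by_dep:
            dep_ids.append(p.dependency_id)
            frac_by_dep[p.dependency_id] = p.dependent_fraction
        elif frac_by_dep[p.dependency_id] != p.dependent_fraction:
            raise ConfigurationError(
                f"conflicting dependent_fraction for {p.dependency_id!r}"
            )
    correlated_dependencies = correlated_dependencies or {}
    for child, parent in correlated_dependencies.items():
        if parent not in dep_ids:
            raise ConfigurationError(
                f"correlated dependency {child!r} names unknown parent {parent!r}"
            )
        if parent in correlated_dependencies:
            raise ConfigurationError("correlated dependencies cannot chain")
    scores_by_dep, mask_by_dep, dependent_cells = {}, {}, {}
    for dep_id in sorted(dep_ids, key=lambda d: d in correlated_dependencies):
        n_dep = int(round(frac_by_dep[dep_id] * n_cells))
        if n_dep < min_cluster_size:
            raise ConfigurationError(
                f"dependency {dep_id!r}: {n_dep} dependent cells < minimum "
                f"cluster size {min_cluster_size}"
            )
        if dep_id in correlated_dependencies:
            parent = correlated_dependencies[dep_id]
            if frac_by_dep[dep_id] != frac_by_dep[parent]:
                raise ConfigurationError(
                    f"correlated dependency {dep_id!r} must share "
                    f"{parent!r}'s dependent_fraction"
                )
            mask = mask_by_dep[parent]
            s = scores_by_dep[parent] + rng.normal(0.0, 0.15, n_cells)
            # keep the below/above -2 partition exact
            s[mask] = np.minimum(s[mask], _HARD_THRESHOLD - 0.01)
            s[~mask] = np.maximum(s[~mask], _HARD_THRESHOLD + 0.01)
        else:
            idx = rng.choice(n_cells, size=n_dep, replace=False)
            mask = np.zeros(n_cells, dtype=bool)
            mask[idx] = True
            s = np.empty(n_cells)
            s[mask] = _truncnorm(rng, _DEP_MEAN, _DEP_SD, n_dep, upper=_HARD_THRESHOLD)
            s[~mask] = _truncnorm(
                rng, _NONDEP_MEAN, _NONDEP_SD, n_cells - n_dep, lower=_HARD_THRESHOLD
            )
        scores_by_dep[dep_id], mask_by_dep[dep_id] = s, mask
        dependent_cells[dep_id] = frozenset(np.array(cells)[mask])

    # expression: planted predictors first, then null filler genes
    n_null = n_genes - len(predictors)
    if n_null < 0:
        raise ConfigurationError("n_genes smaller than the number of planted predictors")
    gene_rows, gene_ids = [], []
    for p in planted:
        if p.mode == "null":
            continue
        gene_ids.append(p.predictor_id)
        gene_rows.append(
            _planted_expression(
                p.mode,
                p.effect_size,
                scores_by_dep[p.dependency_id],
                mask_by_dep[p.dependency_id],
                noise_sd,
                rng,
                n_cells,
            )
        )
    base = rng.uniform(1.0, 6.0, size=n_null)
    for j in range(n_null):
        gene_ids.append(f"NULL{j:04d}")
        row = np.full(n_cells, base[j]) + (
            rng.normal(0.0, noise_sd, n_cells) if noise_sd > 0 else 0.0
        )
        gene_rows.append(np.clip(row, 0.0, None))

    expression = ExpressionMatrix(
        pd.DataFrame(np.asarray(gene_rows), index=gene_ids, columns=cells)
    )
    dependency = DependencyMatrix(
        pd.DataFrame(
            np.vstack([scores_by_dep[d] for d in dep_ids]), index=dep_ids, columns=cells
        )
    )
    truth = pd.DataFrame(
        {
            "dependency": [p.dependency_id for p in planted],
            "predictor": [p.predictor_id for p in planted],
            "mode": [p.mode for p in planted],
            "effect_size": [p.effect_size for p in planted],
            "dependent_fraction": [p.dependent_fraction for p in planted],
        }
    )
    return SyntheticDataset(expression, dependency, annotation, truth, dependent_cells)


def demo_study(
    n_cells: int = 200,
    n_genes: int = 60,
    noise_sd: float = 0.25,
    seed: int = 0,
    haematopoietic_fraction: float = 0.0,
) -> SyntheticDataset:
    """The standard demo study: 200 cells, 2 dependencies, 60 genes,
    the ten-pair planting of :func:`demo_planting`, with DEP2 a
    co-dependency of DEP1 (shared dependent cells, correlated scores)
    so the two dependencies share predictors and the network stage has
    structure to recover."""
    return generate(
        n_cells,
        n_genes,
        demo_planting(),
        noise_sd=noise_sd,
        seed=seed,
        haematopoietic_fraction=haematopoietic_fraction,
        correlated_dependencies={"DEP2": "DEP1"},
    )


def demo_planting(
    dependencies: tuple[str, str] = ("DEP1", "DEP2"),
    dependent_fraction: float = 0.25,
) -> list[PlantedPair]:
    """The standard ten-pair demo planting covering all seven modes.

    DEP1 carries one pair of every mode; DEP2 carries an over, a
    suppressed-under and a seesaw-down pair, so both the union rule and
    shared-mode networks are exercised.
    """
    d1, d2 = dependencies
    mk = lambda d, g, m, e: PlantedPair(d, g, m, e, dependent_fraction)
    return [
        mk(d1, "POVR1", "over", 2.0),
        mk(d1, "PSEPO1", "separable_over", 3.5),
        mk(d1, "PUND1", "under", 2.0),
        mk(d1, "PSEPU1", "separable_under", 3.5),
        mk(d1, "PSUP1", "suppressed_under", 2.5),
        mk(d1, "PSEE1", "seesaw_up", 2.0),
        mk(d1, "PSAW1", "seesaw_down", 2.0),
        mk(d2, "POVR2", "over", 2.0),
        mk(d2, "PSUP2", "suppressed_under", 2.5),
        mk(d2, "PSAW2", "seesaw_down", 2.0),
    ]
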