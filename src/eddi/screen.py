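"""Stage 1 — pairwise screen for candidate dosage-based predictors.

For every (dependency D, gene G) pair the screen

1. searches for a naive dependency-score boundary: starting from all
   cells with score < 0 labeled "dependent", a 10-fold cross-validated
   logistic regression of the labels on G's expression is scored by the
   Brier score; the least-dependent cell is dropped and the fit
   repeated until only ``min_dependent_cells`` remain. The boundary
   with the lowest CV Brier score wins (ties broken toward the more
   negative, stricter boundary);
2. requires expression-based separation between the two classes — by
   default the class interquartile ranges must not overlap;
3. requires a significant linear slope (OLS t-test, P < 0.001 by
   default) of the dependency score on expression *within* the
   dependent cells. With a single predictor the relaxed-lasso fit used
   for this test reduces exactly to OLS: the active set is either
   empty or the unpenalized fit.

Only pairs passing both filters feed the downstream stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._logistic import fit_logistic_folds, predict_proba_1d
from .datatypes import DependencyMatrix, ExpressionMatrix

__all__ = [
    "ScreenConfig",
    "PairScreenRecord",
    "BoundaryResult",
    "brier_score",
    "stratified_folds",
    "cv_brier",
    "boundary_search",
    "separation_filter",
    "slope_filter",
    "run_screen",
    "records_to_frame",
    "screened_features",
    "PairSkipped",
]


class PairSkipped(Exception):
    """Signal (not fatal) that one pair cannot be screened."""


@dataclass(frozen=True)
class ScreenConfig:
    cv_folds: int = 10
    min_dependent_cells: int = 20
    slope_p_threshold: float = 1e-3
    separation_rule: str = "nonoverlap"  # or "as_printed"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.min_dependent_cells < self.cv_folds:
            raise ValueError("min_dependent_cells must be >= cv_folds")
        if self.separation_rule not in ("nonoverlap", "as_printed"):
            raise ValueError("separation_rule must be 'nonoverlap' or 'as_printed'")


@dataclass(frozen=True)
class PairScreenRecord:
    dependency_id: str
    predictor_id: str
    boundary_score: float = np.nan
    best_brier: float = np.nan
    passed_separation: bool = False
    slope: float = np.nan
    slope_p: float = np.nan
    passed: bool = False
    skip_reason: str | None = None


@dataclass(frozen=True)
class BoundaryResult:
    boundary: float
    brier: float
    dependent_idx: np.ndarray = field(repr=False)  # positions into the input vectors
    trace: pd.DataFrame = field(repr=False)  # iteration, boundary, brier


def brier_score(probabilities: np.ndarray, labels: np.ndarray) -> float:
    """Mean squared difference between forecast probabilities and 0/1 outcomes."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=float)
    if p.shape != y.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {y.shape}")
    if p.size == 0:
        raise ValueError("empty input")
    return float(np.mean((p - y) ** 2))


def stratified_folds(labels: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Deal each class's shuffled members round-robin over k folds."""
    labels = np.asarray(labels)
    fold_ids = np.empty(labels.size, dtype=int)
    for cls in (0, 1):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        fold_ids[idx] = np.arange(idx.size) % k
    return fold_ids


def cv_brier(x: np.ndarray, labels: np.ndarray, fold_ids: np.ndarray, k: int) -> float:
    """Mean of per-fold Brier scores for the 1-D logistic model.

    All fold models are fitted in one vectorized Newton pass
    (:func:`eddi._logistic.fit_logistic_folds`).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(labels, dtype=float)
    test_masks = np.vstack([fold_ids == f for f in range(k) if (fold_ids == f).any()])
    b0, b1 = fit_logistic_folds(x, y, ~test_masks)
    probs = predict_proba_1d(b0[:, None], b1[:, None], x[None, :])
    fold_scores = ((probs - y[None, :]) ** 2 * test_masks).sum(axis=1) / test_masks.sum(axis=1)
    return float(fold_scores.mean())


def boundary_search(
    dep_scores: np.ndarray, expr: np.ndarray, config: ScreenConfig
) -> BoundaryResult:
    """Iterative Brier-minimizing boundary search for one pair.

    Fold assignment is stratified on the *initial* (score < 0) labels,
    seeded from the config, and reused at every iteration so Brier
    scores are comparable across boundaries.

    Raises :class:`PairSkipped` when fewer than ``min_dependent_cells``
    cells score below zero or the expression vector is constant.
    """
    s = np.asarray(dep_scores, dtype=float)
    x = np.asarray(expr, dtype=float)
    init_mask = s < 0.0
    n0 = int(init_mask.sum())
    if n0 < config.min_dependent_cells:
        raise PairSkipped(
            f"only {n0} cells with score < 0 (< {config.min_dependent_cells})"
        )
    if np.ptp(x) == 0.0:
        raise PairSkipped("constant expression; logistic fit degenerate")

    k = min(config.cv_folds, s.size)
    rng = np.random.default_rng(config.seed)
    fold_ids = stratified_folds(init_mask.astype(int), k, rng)
    test_masks = np.vstack([fold_ids == f for f in range(k) if (fold_ids == f).any()])
    nf = test_masks.shape[0]

    # dependent cells sorted least-dependent first: iteration t drops the
    # first t of them, so the boundary is the (t+1)-th score in this order
    dep_positions = np.flatnonzero(init_mask)
    order = dep_positions[np.argsort(-s[dep_positions], kind="stable")]
    n_iter = n0 - config.min_dependent_cells + 1
    boundaries = [float(s[order[t]]) for t in range(n_iter)]

    label_rows = np.empty((n_iter, s.size))
    labels = init_mask.astype(float)
    for t in range(n_iter):
        if t > 0:
            labels[order[t - 1]] = 0.0
        label_rows[t] = labels

    # all (iteration, fold) logistic fits in a few vectorized passes;
    # each batch row reproduces cv_brier's arithmetic exactly
    briers_arr = np.empty(n_iter)
    block = max(1, 4096 // nf)
    for start in range(0, n_iter, block):
        chunk = label_rows[start : start + block]
        nb = chunk.shape[0]
        Y = np.repeat(chunk, nf, axis=0)
        T = np.tile(test_masks, (nb, 1))
        b0, b1 = fit_logistic_folds(x, Y, ~T)
        probs = predict_proba_1d(b0[:, None], b1[:, None], x[None, :])
        fold_scores = ((probs - Y) ** 2 * T).sum(axis=1) / T.sum(axis=1)
        briers_arr[start : start + nb] = fold_scores.reshape(nb, nf).mean(axis=1)
    # ties broken toward the later iteration = the more negative boundary
    best_t = int(np.flatnonzero(briers_arr == briers_arr.min())[-1])
    trace = pd.DataFrame(
        {"iteration": np.arange(n_iter), "boundary": boundaries, "brier": briers_arr}
    )
    return BoundaryResult(
        boundary=boundaries[best_t],
        brier=float(briers_arr[best_t]),
        dependent_idx=order[best_t:].copy(),
        trace=trace,
    )


def _quartiles(v: np.ndarray) -> tuple[float, float]:
    # linear-interpolation quantile convention, fixed for reproducibility
    q25, q75 = np.percentile(v, [25.0, 75.0], method="linear")
    return float(q25), float(q75)


def separation_filter(
    expr: np.ndarray, dependent_mask: np.ndarray, rule: str = "nonoverlap"
) -> bool:
    """Quartile-based expression-separation criterion.

    ``nonoverlap`` (default): pass iff the two classes' interquartile
    ranges are disjoint. ``as_printed``: the literal mutual 75th>=25th
    comparison, which passes on IQR *overlap*.
    """
    expr = np.asarray(expr, dtype=float)
    dependent_mask = np.asarray(dependent_mask, dtype=bool)
    dep, non = expr[dependent_mask], expr[~dependent_mask]
    if dep.size == 0 or non.size == 0:
        raise ValueError("both classes must be nonempty")
    d25, d75 = _quartiles(dep)
    n25, n75 = _quartiles(non)
    if rule == "as_printed":
        return d75 >= n25 and n75 >= d25
    return d25 > n75 or n25 > d75


def slope_filter(
    dep_scores_dependent: np.ndarray,
    expr_dependent: np.ndarray,
    threshold: float = 1e-3,
) -> tuple[float, float, bool]:
    """OLS slope of score on expression over dependent cells + t-test."""
    y = np.asarray(dep_scores_dependent, dtype=float)
    x = np.asarray(expr_dependent, dtype=float)
    if y.size < 3:
        raise ValueError("need at least 3 dependent cells")
    if np.ptp(x) == 0.0:
        return 0.0, 1.0, False
    fit = stats.linregress(x, y)
    p = float(fit.pvalue)
    return float(fit.slope), p, bool(p < threshold)


def run_screen(
    expr: ExpressionMatrix,
    dep: DependencyMatrix,
    config: ScreenConfig | None = None,
    dependencies: list[str] | None = None,
    genes: list[str] | None = None,
) -> list[PairScreenRecord]:
    """Screen every (dependency, gene) combination.

    Per-pair failures are recorded (``skip_reason``), never raised.
    Cells with a missing score for a dependency are dropped for all of
    that dependency's pairs. ``dependencies``/``genes`` restrict the
    scan (the full all-pairs screen is O(genes x dependencies x
    iterations)).
    """
    if config is None:
        config = ScreenConfig()
    if expr.cell_ids != dep.cell_ids:
        raise ValueError("matrices are not aligned; run align_datasets first")
    dep_list = dependencies if dependencies is not None else dep.gene_ids
    gene_list = genes if genes is not None else expr.gene_ids

    records: list[PairScreenRecord] = []
    expr_values = expr.data.to_numpy()
    gene_pos = {g: i for i, g in enumerate(expr.gene_ids)}
    for dep_id in dep_list:
        s_full = dep.scores(dep_id)
        valid = np.isfinite(s_full)
        s = s_full[valid]
        for gene in gene_list:
            x = expr_values[gene_pos[gene]][valid]
            try:
                result = boundary_search(s, x, config)
            except PairSkipped as exc:
                records.append(
                    PairScreenRecord(dep_id, gene, skip_reason=str(exc))
                )
                continue
            mask = np.zeros(s.size, dtype=bool)
            mask[result.dependent_idx] = True
            sep = separation_filter(x, mask, rule=config.separation_rule)
            slope, slope_p, slope_ok = slope_filter(
                s[mask], x[mask], config.slope_p_threshold
            )
            records.append(
                PairScreenRecord(
                    dependency_id=dep_id,
                    predictor_id=gene,
                    boundary_score=result.boundary,
                    best_brier=result.brier,
                    passed_separation=sep,
                    slope=slope,
                    slope_p=slope_p,
                    passed=bool(sep and slope_ok),
                )
            )
    return records


def records_to_frame(records: list[PairScreenRecord]) -> pd.DataFrame:
    """Tabulate screen records (one row per pair) for CSV export."""
    return pd.DataFrame(
        {
            "dependency_id": [r.dependency_id for r in records],
            "predictor_id": [r.predictor_id for r in records],
            "boundary_score": [r.boundary_score for r in records],
            "best_brier": [r.best_brier for r in records],
            "passed_separation": [r.passed_separation for r in records],
            "slope": [r.slope for r in records],
            "slope_p": [r.slope_p for r in records],
            "passed": [r.passed for r in records],
            "skip_reason": [r.skip_reason for r in records],
        }
    )


def screened_features(records: list[PairScreenRecord]) -> dict[str, list[str]]:
    """Passing predictor genes per dependency, in screen order."""
    out: dict[str, list[str]] = {}
    for r in records:
        if r.passed:
            out.setdefault(r.dependency_id, []).append(r.predictor_id)
    return out
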