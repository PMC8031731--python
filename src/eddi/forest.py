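"""Stage 3 — per-dependency random-forest classification.

One random forest per dependency, using the screened predictor genes
as features and the strict dependent labels as the target. The number
of features tried at each split (m) is tuned by a stepwise
out-of-bag-error search (doubling/halving from sqrt(p), accepted while
the error improves by a relative tolerance), mirroring the classical
``tuneRF`` routine. Performance is assessed by repeated stratified
cross-validation with the minority (dependent) class up-sampled with
replacement inside each training split only; the mean held-out ROC AUC
gates the dependency at 0.7. Feature importance is the mean decrease
in Gini impurity from a final forest fit on all (up-sampled) data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import RepeatedStratifiedKFold

__all__ = [
    "ForestConfig",
    "ForestResult",
    "tune_m",
    "evaluate_dependency",
    "rank_antisense_pairs",
    "infer_antisense_map",
]


@dataclass(frozen=True)
class ForestConfig:
    n_trees: int = 500
    min_node_size: int = 1
    cv_folds: int = 10
    cv_repeats: int = 5
    auc_gate: float = 0.7
    step_factor: float = 2.0
    improve_tol: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if not 0.5 < self.auc_gate <= 1.0:
            raise ValueError("auc_gate must lie in (0.5, 1]")


@dataclass(frozen=True)
class ForestResult:
    dependency_id: str
    fold_aucs: np.ndarray = field(repr=False)
    repeat_aucs: np.ndarray = field(repr=False)
    mean_auc: float = np.nan
    chosen_m: int = 1
    importances: pd.Series = field(default=None, repr=False)
    passed_gate: bool = False
    n_skipped_folds: int = 0


def _upsample(
    X: np.ndarray, y: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Duplicate minority-class rows (with replacement) up to majority count."""
    n1 = int(y.sum())
    n0 = y.size - n1
    if n1 == 0 or n0 == 0 or n1 == n0:
        return X, y
    minority = 1 if n1 < n0 else 0
    deficit = abs(n0 - n1)
    pool = np.flatnonzero(y == minority)
    extra = rng.choice(pool, size=deficit, replace=True)
    idx = np.concatenate([np.arange(y.size), extra])
    return X[idx], y[idx]


def _forest(m: int, config: ForestConfig, seed: int, oob: bool = False):
    return RandomForestClassifier(
        n_estimators=config.n_trees,
        max_features=m,
        min_samples_leaf=config.min_node_size,
        oob_score=oob,
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    )


def _oob_error(X, y, m, config, seed) -> float:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # small forests may miss some OOB rows
        rf = _forest(m, config, seed, oob=True).fit(X, y)
    return float(1.0 - rf.oob_score_)


def tune_m(
    features: np.ndarray,
    labels: np.ndarray,
    config: ForestConfig | None = None,
    return_path: bool = False,
):
    """Stepwise OOB search for the per-split feature count m.

    Starts at floor(sqrt(p)); doubles (then halves) by ``step_factor``
    while the OOB error improves by more than ``improve_tol`` relative
    to the current best. Returns the m with the lowest OOB error, or
    ``(m, path)`` with the searched (m, oob_error) pairs.
    """
    if config is None:
        config = ForestConfig()
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels).astype(int)
    p = X.shape[1]
    if p == 1:
        return (1, [(1, np.nan)]) if return_path else 1

    rng = np.random.default_rng(config.seed)
    Xu, yu = _upsample(X, y, rng)
    m0 = max(1, int(np.sqrt(p)))
    path = [(m0, _oob_error(Xu, yu, m0, config, config.seed))]
    best_m, best_err = path[0]
    for direction in (config.step_factor, 1.0 / config.step_factor):
        m, err = m0, path[0][1]
        while True:
            m_next = int(np.floor(m * direction)) if direction < 1 else int(np.ceil(m * direction))
            if m_next == m or not 1 <= m_next <= p:
                break
            err_next = _oob_error(Xu, yu, m_next, config, config.seed)
            path.append((m_next, err_next))
            if err_next < best_err:
                best_m, best_err = m_next, err_next
            if err - err_next <= config.improve_tol * max(err, 1e-12):
                break
            m, err = m_next, err_next
    return (best_m, path) if return_path else best_m


def evaluate_dependency(
    features: pd.DataFrame,
    labels: np.ndarray,
    config: ForestConfig | None = None,
    dependency_id: str = "",
    instrument: Callable[[dict], None] | None = None,
) -> ForestResult:
    """Repeated stratified CV with in-fold minority up-sampling.

    ``features`` is cells x predictors (column names become importance
    keys). Folds whose test split contains a single class are skipped
    and counted. ``instrument``, if given, receives a dict per fold
    (train/test indices and post-up-sampling training size) — used by
    tests to assert the test split is never resampled.
    """
    if config is None:
        config = ForestConfig()
    X = features.to_numpy(dtype=float)
    y = np.asarray(labels).astype(int)
    minority = int(min(y.sum(), y.size - y.sum()))
    if minority < 2:
        raise ValueError(
            f"dependency {dependency_id!r}: need both classes with >= 2 cells"
        )
    n_splits = min(config.cv_folds, minority)
    if n_splits < config.cv_folds:
        warnings.warn(
            f"dependency {dependency_id!r}: folds reduced to {n_splits} "
            f"(minority class has {minority} cells)"
        )

    chosen_m = tune_m(X, y, config)
    splitter = RepeatedStratifiedKFold(
        n_splits=n_splits, n_repeats=config.cv_repeats, random_state=config.seed
    )
    fold_aucs, fold_repeat = [], []
    n_skipped = 0
    for fold_i, (train, test) in enumerate(splitter.split(X, y)):
        if len(np.unique(y[test])) < 2:
            n_skipped += 1
            continue
        rng = np.random.default_rng([config.seed, fold_i])
        X_tr, y_tr = _upsample(X[train], y[train], rng)
        if instrument is not None:
            instrument(
                {
                    "fold": fold_i,
                    "train_idx": train,
                    "test_idx": test,
                    "n_train_after_upsampling": y_tr.size,
                    "n_test": test.size,
                }
            )
        rf = _forest(chosen_m, config, config.seed).fit(X_tr, y_tr)
        proba = rf.predict_proba(X[test])[:, list(rf.classes_).index(1)]
        fold_aucs.append(roc_auc_score(y[test], proba))
        fold_repeat.append(fold_i // n_splits)

    fold_aucs = np.asarray(fold_aucs)
    repeat_aucs = np.asarray(
        [
            fold_aucs[np.asarray(fold_repeat) == r].mean()
            for r in range(config.cv_repeats)
            if (np.asarray(fold_repeat) == r).any()
        ]
    )
    mean_auc = float(fold_aucs.mean()) if fold_aucs.size else np.nan

    rng = np.random.default_rng([config.seed, 10_000_019])
    X_all, y_all = _upsample(X, y, rng)
    rf_final = _forest(chosen_m, config, config.seed).fit(X_all, y_all)
    importances = pd.Series(
        rf_final.feature_importances_, index=features.columns, name="gini_decrease"
    )
    return ForestResult(
        dependency_id=dependency_id,
        fold_aucs=fold_aucs,
        repeat_aucs=repeat_aucs,
        mean_auc=mean_auc,
        chosen_m=chosen_m,
        importances=importances,
        passed_gate=bool(mean_auc >= config.auc_gate),
        n_skipped_folds=n_skipped,
    )


def infer_antisense_map(predictor_ids) -> dict[str, str]:
    """Default naming convention: FOO-AS1/FOO-AS2 pairs with FOO."""
    ids = set(predictor_ids)
    out = {}
    for pid in predictor_ids:
        for suffix in ("-AS1", "-AS2"):
            if pid.endswith(suffix) and pid[: -len(suffix)] in ids:
                out[pid] = pid[: -len(suffix)]
    return out


def rank_antisense_pairs(
    result: ForestResult, antisense_map: dict[str, str] | None = None
) -> pd.DataFrame:
    """Importance ranks of coding genes vs their antisense transcripts.

    Ranks are over the dependency's full importance list, 1 = most
    important, ties share the smallest (min) rank. Pairs with a missing
    member are omitted.
    """
    imp = result.importances
    if antisense_map is None:
        antisense_map = infer_antisense_map(imp.index)
    ranks = pd.Series(
        rankdata(-imp.to_numpy(), method="min").astype(int), index=imp.index
    )
    rows = []
    for antisense, coding in sorted(antisense_map.items()):
        if antisense not in imp.index or coding not in imp.index:
            continue
        rows.append(
            {
                "dependency_id": result.dependency_id,
                "coding": coding,
                "antisense": antisense,
                "coding_rank": int(ranks[coding]),
                "antisense_rank": int(ranks[antisense]),
                "coding_gini": float(imp[coding]),
                "antisense_gini": float(imp[antisense]),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "dependency_id",
            "coding",
            "antisense",
            "coding_rank",
            "antisense_rank",
            "coding_gini",
            "antisense_gini",
        ],
    )
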