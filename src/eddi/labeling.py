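"""Stage 2 — strict dependent-cell-line definition.

The screen's per-pair boundaries only locate candidate pairs; the
downstream classifiers need one defensible dependent/non-dependent
labeling per dependency. Each surviving (dependency, gene) pair is
clustered with k-means (k=2, minimum cluster size 20) on the z-scored
(expression, score) plane; the cluster holding more cells with scores
below the -2 hard threshold is the dependent cluster, and only its
members *below -2* are labeled dependent. The final dependent set of a
dependency is the union over its pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

__all__ = ["DependentSet", "cluster_pair", "union_dependent", "label_dependencies"]

HARD_THRESHOLD = -2.0


@dataclass(frozen=True)
class DependentSet:
    dependency_id: str
    dependent_cells: frozenset = field(default_factory=frozenset)
    contributing_pairs: tuple[str, ...] = ()


def cluster_pair(
    dep_scores: np.ndarray,
    expr: np.ndarray,
    cell_ids: Sequence[str],
    k: int = 2,
    min_cluster: int = 20,
    hard_threshold: float = HARD_THRESHOLD,
    seed: int = 0,
    n_restarts: int = 10,
    features: str = "both",
) -> frozenset:
    """Dependent cells contributed by one screened pair.

    k-means (``n_restarts`` seeded initialisations, best inertia kept)
    on z-scored (expression, score) points — or score only with
    ``features='score'``. Returns the empty set when either cluster is
    smaller than ``min_cluster``, when the "most cells below the
    threshold" vote ties, or when nothing in the dependent cluster
    scores below the threshold.
    """
    s = np.asarray(dep_scores, dtype=float)
    x = np.asarray(expr, dtype=float)
    if s.size != x.size or s.size != len(cell_ids):
        raise ValueError("scores, expression and cell_ids must align")
    if s.size < 2 * min_cluster:
        return frozenset()

    cols = [s] if features == "score" else [x, s]
    pts = np.column_stack(cols)
    sd = pts.std(axis=0, ddof=0)
    sd[sd == 0.0] = 1.0
    pts = (pts - pts.mean(axis=0)) / sd

    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    assign = km.fit_predict(pts)

    below = s < hard_threshold
    counts = [int((below & (assign == c)).sum()) for c in range(k)]
    sizes = [int((assign == c).sum()) for c in range(k)]
    if min(sizes) < min_cluster:
        return frozenset()
    best = int(np.argmax(counts))
    if counts.count(counts[best]) > 1:  # ambiguous dependent cluster
        return frozenset()
    members = below & (assign == best)
    return frozenset(np.asarray(cell_ids, dtype=object)[members])


def union_dependent(
    dependency_id: str, per_pair_sets: dict[str, Iterable[str]]
) -> DependentSet:
    """Union of the per-pair dependent sets; keyed by predictor id."""
    cells: set[str] = set()
    contributing = []
    for predictor_id, cell_set in per_pair_sets.items():
        cell_set = set(cell_set)
        if cell_set:
            contributing.append(predictor_id)
            cells |= cell_set
    return DependentSet(dependency_id, frozenset(cells), tuple(contributing))


def label_dependencies(
    expr,
    dep,
    features_by_dependency: dict[str, list[str]],
    min_cluster: int = 20,
    hard_threshold: float = HARD_THRESHOLD,
    seed: int = 0,
    cluster_features: str = "both",
) -> dict[str, DependentSet]:
    """Run the per-pair clustering and union rule for every dependency.

    ``features_by_dependency`` is the screen's output (predictors that
    passed, per dependency). Cells missing a score for a dependency are
    excluded from that dependency's clustering.
    """
    out: dict[str, DependentSet] = {}
    cells = np.asarray(expr.cell_ids, dtype=object)
    for dep_id, predictors in features_by_dependency.items():
        s_full = dep.scores(dep_id)
        valid = np.isfinite(s_full)
        per_pair = {}
        for gene in predictors:
            per_pair[gene] = cluster_pair(
                s_full[valid],
                expr.gene(gene)[valid],
                cells[valid],
                min_cluster=min_cluster,
                hard_threshold=hard_threshold,
                seed=seed,
                features=cluster_features,
            )
        out[dep_id] = union_dependent(dep_id, per_pair)
    return out


def dependent_sets_to_frame(sets: dict[str, DependentSet]) -> pd.DataFrame:
    """Long (dependency_id, cell_id) table of the final labels."""
    rows = [
        {"dependency_id": d, "cell_id": c}
        for d, ds in sorted(sets.items())
        for c in sorted(ds.dependent_cells)
    ]
    return pd.DataFrame(rows, columns=["dependency_id", "cell_id"])
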