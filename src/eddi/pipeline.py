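"""End-to-end orchestration: io → screen → labeling → forest → seesaw →
modes → network, with per-stage CSV artifacts and a JSON manifest.

Every stage's randomness is seeded from the master seed through a
fixed :class:`numpy.random.SeedSequence` derivation, so a rerun with an
identical config reproduces every artifact byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import io as eddi_io
from .datatypes import CellAnnotation, DependencyMatrix, ExpressionMatrix
from .forest import ForestConfig, evaluate_dependency, rank_antisense_pairs
from .labeling import dependent_sets_to_frame, label_dependencies
from .modes import ModeConfig, characterize_dependency, ddp_records_to_frame
from .network import (
    build_network,
    mode_profile_clustering,
    tissue_composition,
)
from .screen import ScreenConfig, records_to_frame, run_screen, screened_features
from .seesaw import fit_relaxed_lasso, seesaw_labels

logger = logging.getLogger("eddi")

__all__ = ["PipelineConfig", "run_pipeline", "run_pipeline_data"]


@dataclass
class PipelineConfig:
    expression_path: str = ""
    dependency_path: str = ""
    annotation_path: str = ""
    already_log: bool = False
    exclude_tissues: list[str] = field(
        default_factory=lambda: sorted(eddi_io.DEFAULT_EXCLUDED_TISSUES)
    )
    dependencies: list[str] | None = None  # restrict the screen; None = all
    genes: list[str] | None = None
    seed: int = 0
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    forest: ForestConfig = field(default_factory=ForestConfig)
    modes: ModeConfig = field(default_factory=ModeConfig)
    min_cluster_size: int = 20
    cluster_features: str = "both"  # or "score"
    gamma_grid: tuple = (0.0, 0.25, 0.5, 0.75, 1.0)
    n_lambdas: int = 100

    def __post_init__(self) -> None:
        # sub-seeds derive deterministically from the master seed
        state = np.random.SeedSequence(self.seed).generate_state(4) % (2**31)
        self.screen = dataclasses.replace(self.screen, seed=int(state[0]))
        self.forest = dataclasses.replace(self.forest, seed=int(state[1]))
        self._label_seed = int(state[2])

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out.pop("_label_seed", None)
        out["gamma_grid"] = list(self.gamma_grid)
        return out

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        for key, sub in (("screen", ScreenConfig), ("forest", ForestConfig), ("modes", ModeConfig)):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = sub(**raw[key])
        raw["gamma_grid"] = tuple(raw.get("gamma_grid", (0.0, 0.25, 0.5, 0.75, 1.0)))
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as handle:
            yaml.safe_dump(self.to_dict(), handle, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as handle:
            return cls.from_dict(yaml.safe_load(handle))


def _write(frame: pd.DataFrame, out_dir: str, name: str, manifest: dict) -> str:
    path = os.path.join(out_dir, name)
    frame.to_csv(path, index=False)
    manifest["artifacts"][name] = {"rows": int(frame.shape[0])}
    return path


def run_pipeline(config: PipelineConfig, out_dir: str) -> dict:
    """Read the configured inputs and run the full pipeline."""
    expr = eddi_io.read_expression(config.expression_path, already_log=config.already_log)
    dep = eddi_io.read_dependency(config.dependency_path)
    ann = eddi_io.read_annotation(config.annotation_path)
    return run_pipeline_data(expr, dep, ann, config, out_dir)


def run_pipeline_data(
    expr: ExpressionMatrix,
    dep: DependencyMatrix,
    ann: CellAnnotation,
    config: PipelineConfig,
    out_dir: str,
) -> dict:
    """Run all stages on in-memory inputs; returns the manifest dict."""
    os.makedirs(out_dir, exist_ok=True)
    manifest: dict = {"artifacts": {}, "counts": {}, "seed": config.seed}

    expr, dep, ann = eddi_io.align_datasets(
        expr, dep, ann, exclude_tissues=config.exclude_tissues
    )
    manifest["counts"]["aligned_cells"] = expr.n_cells
    logger.info("aligned %d cell lines", expr.n_cells)

    if config.dependencies is not None and not config.dependencies:
        logger.warning("empty dependency list; writing empty outputs")
        _write(records_to_frame([]), out_dir, "screen.csv", manifest)
        _write(ddp_records_to_frame([]), out_dir, "ddp_table.csv", manifest)
        manifest["counts"].update({"screened_pairs": 0, "ddp_pairs": 0})
        with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        return manifest

    # stage 1: pairwise screen
    records = run_screen(
        expr, dep, config.screen, dependencies=config.dependencies, genes=config.genes
    )
    _write(records_to_frame(records), out_dir, "screen.csv", manifest)
    features = screened_features(records)
    manifest["counts"]["screened_pairs"] = sum(len(v) for v in features.values())
    manifest["counts"]["screened_dependencies"] = len(features)
    logger.info(
        "screen: %d/%d pairs passed", manifest["counts"]["screened_pairs"], len(records)
    )

    # stage 2: strict dependent-cell labeling
    dependent_sets = label_dependencies(
        expr,
        dep,
        features,
        min_cluster=config.min_cluster_size,
        seed=config._label_seed,
        cluster_features=config.cluster_features,
    )
    _write(dependent_sets_to_frame(dependent_sets), out_dir, "dependent_cells.csv", manifest)

    # stage 3: random-forest gate
    forest_rows, auc_rows, importance_rows, antisense_frames = [], [], [], []
    gated, ddp_records = {}, []
    for dep_id in sorted(features):
        ds = dependent_sets[dep_id]
        labels = np.array([c in ds.dependent_cells for c in expr.cell_ids], dtype=int)
        n_dep = int(labels.sum())
        if n_dep < 2 or labels.size - n_dep < 2:
            logger.warning("%s: too few dependent cells (%d); forest skipped", dep_id, n_dep)
            continue
        feat_frame = pd.DataFrame(
            {g: expr.gene(g) for g in features[dep_id]}, index=expr.cell_ids
        )
        result = evaluate_dependency(
            feat_frame, labels, config.forest, dependency_id=dep_id
        )
        forest_rows.append(
            {
                "dependency_id": dep_id,
                "mean_auc": result.mean_auc,
                "chosen_m": result.chosen_m,
                "n_dependent": n_dep,
                "passed_gate": result.passed_gate,
            }
        )
        for i, auc in enumerate(result.fold_aucs):
            auc_rows.append({"dependency_id": dep_id, "fold": i, "auc": auc})
        ranks = result.importances.rank(ascending=False, method="min").astype(int)
        for g in result.importances.index:
            importance_rows.append(
                {
                    "dependency_id": dep_id,
                    "predictor_id": g,
                    "gini_decrease": result.importances[g],
                    "rank": ranks[g],
                }
            )
        antisense = rank_antisense_pairs(result)
        if not antisense.empty:
            antisense_frames.append(antisense)
        if result.passed_gate:
            gated[dep_id] = result

    _write(pd.DataFrame(forest_rows), out_dir, "forest_summary.csv", manifest)
    _write(pd.DataFrame(auc_rows), out_dir, "forest_fold_aucs.csv", manifest)
    _write(pd.DataFrame(importance_rows), out_dir, "forest_importances.csv", manifest)
    _write(
        pd.concat(antisense_frames, ignore_index=True)
        if antisense_frames
        else pd.DataFrame(
            columns=["dependency_id", "coding", "antisense", "coding_rank", "antisense_rank"]
        ),
        out_dir,
        "antisense_ranks.csv",
        manifest,
    )
    manifest["counts"]["gated_dependencies"] = len(gated)

    # stages 4+5: relaxed lasso (SEESAW) and mode characterization
    seesaw_rows = []
    for dep_id in sorted(gated):
        ds = dependent_sets[dep_id]
        dep_cells = sorted(ds.dependent_cells)
        directions: dict[str, str] = {}
        if len(dep_cells) >= 3 and len(features[dep_id]) >= 1:
            cell_idx = [expr.cell_ids.index(c) for c in dep_cells]
            feat_frame = pd.DataFrame(
                {g: expr.gene(g)[cell_idx] for g in features[dep_id]}, index=dep_cells
            )
            scores = dep.scores(dep_id)[cell_idx]
            try:
                model = fit_relaxed_lasso(
                    feat_frame,
                    scores,
                    gamma_grid=config.gamma_grid,
                    dependency_id=dep_id,
                    n_lambdas=config.n_lambdas,
                )
            except ValueError as exc:
                logger.warning("%s: relaxed lasso skipped (%s)", dep_id, exc)
            else:
                directions = dict(seesaw_labels(model))
                for g, coef in model.coefficients.items():
                    seesaw_rows.append(
                        {
                            "dependency_id": dep_id,
                            "predictor_id": g,
                            "coefficient": coef,
                            "direction": directions.get(g, ""),
                            "lambda": model.lambda_,
                            "gamma": model.gamma,
                            "loocv_rmse": model.loocv_rmse,
                            "r_squared": model.r_squared,
                            "train_r_squared": model.train_r_squared,
                        }
                    )
        ddp_records.extend(
            characterize_dependency(
                expr,
                dep_id,
                dependent_sets[dep_id].dependent_cells,
                features[dep_id],
                seesaw_directions=directions,
                config=config.modes,
            )
        )
    _write(pd.DataFrame(seesaw_rows), out_dir, "seesaw_models.csv", manifest)
    ddp_frame = ddp_records_to_frame(ddp_records)
    _write(ddp_frame, out_dir, "ddp_table.csv", manifest)
    manifest["counts"]["ddp_pairs"] = int(ddp_frame["is_ddp"].sum()) if len(ddp_frame) else 0

    # stage 6: systems layer
    _write(
        tissue_composition(dependent_sets.values(), ann),
        out_dir,
        "tissue_composition.csv",
        manifest,
    )
    labeled = [r for r in ddp_records if r.is_ddp]
    if labeled:
        try:
            net = build_network(ddp_records)
        except ValueError:
            net = None
        if net is not None and net.ddp_nodes:
            net.write_graphml(os.path.join(out_dir, "network.graphml"))
            net.write_edgelist(os.path.join(out_dir, "network_edges.csv"))
            net.write_projection(os.path.join(out_dir, "network_projection.csv"))
            manifest["artifacts"]["network.graphml"] = {
                "dependency_nodes": len(net.dependency_nodes),
                "ddp_nodes": len(net.ddp_nodes),
            }
        clustering = mode_profile_clustering(ddp_records)
        clustering.matrix.to_csv(os.path.join(out_dir, "mode_matrix.csv"))
        with open(os.path.join(out_dir, "mode_dendrograms.nwk"), "w") as fh:
            fh.write(clustering.newick("dependencies") + "\n")
            fh.write(clustering.newick("ddps") + "\n")
        manifest["artifacts"]["mode_matrix.csv"] = {
            "rows": int(clustering.matrix.shape[0])
        }

    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
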