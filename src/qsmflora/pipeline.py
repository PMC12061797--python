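"""End-to-end orchestration: simulate -> subsample -> fit -> upscale ->
tree models -> resource budgets.

`run_all` executes the whole chain on supplied inputs or on a synthetic
forest, writing every intermediate table under an output directory along
with provenance metadata (config, seeds).  Each stage failure is re-raised
with the stage name; partial outputs written so far are kept.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import constants
from .branch_data import (
    records_to_frame,
    trees_to_frame,
    write_branch_csv,
)
from .errors import ConfigError
from .hurdle import fit_hurdle
from .qsm import derive_tree_metrics, metrics_to_frame
from .resources import NectarParams, PollenParams, bootstrap_mc_ci, default_species
from .subsampling import farthest_distance_sample
from .synthetic import SyntheticForestSpec, generate_branch_dataset, generate_forest
from .tree_model import fit_tree_model, screen_predictors
from .upscaling import aggregate_tree, upscale_replicate

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Options for a full pipeline run."""

    seed: int = 1
    simulate: bool = True
    n_trees: int = 12
    n_replicates: int = 5
    noise_sd: float = 0.05
    cutoffs_per_tree: int = 6
    random_effects: bool = False
    sample_counts: bool = False
    unit_threshold_mm: float = 30.0
    layer_depth_m: float = 2.0
    slice_height_m: float = 0.5
    alpha_m: float = 1.0
    bootstrap_B: int = 200
    dbh_grid: list[float] = field(default_factory=lambda: [10.0, 25.0])
    branch_csv: str | None = None
    cylinder_csv: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        for name in ("unit_threshold_mm", "layer_depth_m", "slice_height_m", "alpha_m"):
            if getattr(cfg, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        return cfg


def run_all(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run the full pipeline and return the result bundle.

    Writes branch/cylinder inputs (when simulated), the subsampled branch
    list, fitted-model JSON, per-tree flower estimates, tree-model JSON and
    the resource-budget table under ``out_dir``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "configure"
    bundle: dict = {}
    try:
        stage = "simulate"
        if config.simulate:
            spec = SyntheticForestSpec(
                n_trees=config.n_trees,
                n_replicates=config.n_replicates,
                noise_sd=config.noise_sd,
                cutoffs_per_tree=config.cutoffs_per_tree,
            )
            records, trees, truth = generate_branch_dataset(spec, seed=config.seed)
            tree_df, qsms = generate_forest(spec, seed=config.seed)
            write_branch_csv(records, out / "branches.csv", out / "measurements.csv")
            trees_to_frame(trees).to_csv(out / "trees.csv", index=False)
        else:
            if not config.branch_csv or not Path(config.branch_csv).exists():
                raise ConfigError(f"missing branch table: {config.branch_csv!r}")
            if not config.cylinder_csv or not Path(config.cylinder_csv).exists():
                raise ConfigError(f"missing cylinder table: {config.cylinder_csv!r}")
            from .branch_data import read_branch_csv
            from .qsm import read_cylinder_csv

            records = read_branch_csv(config.branch_csv)
            all_qsms = read_cylinder_csv(config.cylinder_csv)
            qsms = {}
            for q in all_qsms:
                qsms.setdefault(q.tree_id, []).append(q)
            trees = None

        stage = "subsample"
        if trees is None:
            raise ConfigError("external runs must supply a tree table with dbh")
        selected = farthest_distance_sample(records, trees)
        pd.Series(selected, name="branch_id").to_csv(out / "subsample.csv", index=False)
        frame = records_to_frame(records)
        sub = frame[frame["branch_id"].isin(selected)]

        stage = "fit-branch"
        fit = fit_hurdle(sub, trees_to_frame(trees), random_effects=config.random_effects)
        fit.to_json(out / "branch_model.json")
        coefs = fit.coefficients()

        stage = "upscale"
        est_rows = []
        metrics_by_tree = {}
        estimates = []
        for tree_id, reps in qsms.items():
            totals = []
            for q in reps:
                m = derive_tree_metrics(q, alpha=config.alpha_m)
                rng = np.random.default_rng([config.seed % (2**31), q.replicate_id])
                total = upscale_replicate(
                    q,
                    coefs,
                    m,
                    rng,
                    d_max_mm=config.unit_threshold_mm,
                    sample_counts=config.sample_counts,
                    layer_depth_m=config.layer_depth_m,
                    slice_height_m=config.slice_height_m,
                )
                totals.append(total)
                est_rows.append(
                    {"tree_id": tree_id, "replicate_id": q.replicate_id, "total": total}
                )
            estimates.append(aggregate_tree(tree_id, totals))
            metrics_by_tree[tree_id] = derive_tree_metrics(reps[0], alpha=config.alpha_m)
        pd.DataFrame(est_rows).to_csv(out / "replicate_totals.csv", index=False)

        stage = "fit-tree"
        mdf = metrics_to_frame(metrics_by_tree).rename(
            columns={
                "dbh_cm": "dbh",
                "height_m": "height",
                "crown_diameter_m": "crown_diameter",
                "crown_projection_area_m2": "crown_projection_area",
                "crown_volume_m3": "crown_volume",
            }
        )
        med = pd.DataFrame(
            {"tree_id": [e.tree_id for e in estimates], "flowers": [e.median_total for e in estimates]}
        )
        tree_table = mdf.merge(med, on="tree_id")
        tree_table.to_csv(out / "tree_table.csv", index=False)
        corr, collin = screen_predictors(tree_table)
        corr.to_csv(out / "predictor_screening.csv", index=False)
        dbh_model = fit_tree_model(tree_table, predictor="dbh")
        dbh_model.to_json(out / "tree_model_dbh.json")
        cv_model = fit_tree_model(tree_table, predictor="crown_volume")
        cv_model.to_json(out / "tree_model_crown_volume.json")

        stage = "resources"
        budgets = bootstrap_mc_ci(
            tree_table,
            config.dbh_grid,
            PollenParams(),
            NectarParams(),
            default_species(),
            B=config.bootstrap_B,
            seed=config.seed,
        )
        budgets.to_csv(out / "resource_budgets.csv", index=False)

        stage = "report"
        meta = {
            "seed": config.seed,
            "config": dataclasses.asdict(config),
            "conventions": {
                "layer_buffer": "2 m inward erosion of the slice hull",
                "abundance_link": "ln(mu) of the untruncated NB",
                "upscaled_counts": "fractional ZTNB expectations (no rounding)",
            },
        }
        (out / "run_metadata.json").write_text(json.dumps(meta, indent=2, default=str))
        bundle = {
            "branch_fit": fit,
            "estimates": estimates,
            "tree_table": tree_table,
            "screening": (corr, collin),
            "dbh_model": dbh_model,
            "crown_volume_model": cv_model,
            "budgets": budgets,
        }
    except Exception as e:
        raise type(e)(f"[stage: {stage}] {e}") from e
    return bundle
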