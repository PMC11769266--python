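"""End-to-end orchestration: one config in, a reproducible report out.

``run_pipeline`` executes generate (or load) -> mask -> polygons -> zonal ->
feature table -> split -> per-stage fits -> metrics -> selection ->
comparison statistics, writing per-stage CSV feature tables, JSON metrics and
a MANIFEST declaring every output file.  Two runs with the same config are
identical up to the floating-point determinism of the fitting backends.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__, models, study
from .models import FeatureTable, ModelConfig
from .synthetic import ScenarioConfig, generate_field

log = logging.getLogger("canopy_yield")


@dataclass
class RunConfig:
    """Everything governing one pipeline run (synthetic scenario for now;
    user-supplied rasters enter through the CLI's file-based subcommands)."""

    scenario: ScenarioConfig
    output_dir: str | Path = "canopy_yield_run"
    mask_threshold: float | str = "auto"
    area_bounds: tuple[float, float] = study.DEFAULT_AREA_BOUNDS
    roundness_max: float = study.DEFAULT_ROUNDNESS_MAX
    drop_edges: bool = True
    model_kinds: tuple[str, ...] = ("MLR", "RF", "GBR", "XGB")
    split_ratio: float = 0.8
    seed: int = 0
    do_selection: bool = True
    selection_kind: str = "RF"
    vif_cut: float = 10.0
    importance_floor: float = 0.005
    do_soil_test: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.split_ratio < 1:
            raise ValueError("split_ratio must be in (0, 1)")
        for kind in self.model_kinds:
            if kind not in models.MODEL_KINDS:
                raise ValueError(f"unknown model kind {kind!r}")


@dataclass
class RunReport:
    output_dir: Path
    metrics: dict
    selected_features: dict
    comparison: dict
    manifest: dict


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=float))


def run_pipeline(config: RunConfig) -> RunReport:
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[str] = []

    log.info("stage 1/6: generating synthetic field (seed=%d)", config.scenario.seed)
    field_data = generate_field(config.scenario)
    log.info("  %d harvest points", field_data.points.n)

    log.info("stage 2/6: masking, polygons, zonal features")
    tables, funnel = study.build_feature_tables(
        field_data,
        mask_threshold=config.mask_threshold,
        area_bounds=config.area_bounds,
        roundness_max=config.roundness_max,
        drop_edges=config.drop_edges,
    )
    log.info(
        "  %d polygons -> %d retained", funnel["polygons"], funnel["polygons_retained"]
    )

    stage_files = []
    for table in tables:
        safe = table.stage_label.replace("/", "-")
        csv_path = out_dir / f"features_{safe}.csv"
        table.data.to_csv(csv_path, index_label="polygon_id")
        schema = {
            "stage_label": table.stage_label,
            "dap": table.dap,
            "target": table.target,
            "predictors": table.predictors,
            "n_rows": table.n,
        }
        _write_json(out_dir / f"features_{safe}.schema.json", schema)
        written += [csv_path.name, f"features_{safe}.schema.json"]
        stage_files.append(csv_path.name)

    log.info("stage 3/6: train/test split and model fits")
    metrics: dict[str, dict] = {}
    rmse_matrix: dict[str, list[float]] = {k: [] for k in config.model_kinds}
    reduced_full_pairs: list[tuple[float, float]] = []
    for table in tables:
        n_before = table.n
        scores = study.fit_and_score(
            table, config.model_kinds, config.split_ratio, config.seed
        )
        metrics[table.stage_label] = {
            kind: {"r2": m.r2, "rmse": m.rmse, "n_test": m.n, "n_rows": n_before}
            for kind, m in scores.items()
        }
        for kind, m in scores.items():
            rmse_matrix[kind].append(m.rmse)
        if config.do_soil_test:
            ens = [k for k in config.model_kinds if k != "MLR"]
            if ens:
                red = study.fit_and_score(
                    table, ens, config.split_ratio, config.seed, reduced=True
                )
                for kind in ens:
                    reduced_full_pairs.append((scores[kind].rmse, red[kind].rmse))

    log.info("stage 4/6: iterative feature selection (%s)", config.selection_kind)
    selected: dict[str, dict] = {}
    if config.do_selection:
        for table in tables:
            train, test = models.split_train_test(table, config.split_ratio, config.seed)
            sel, history = models.iterative_feature_selection(
                train,
                test,
                ModelConfig(kind=config.selection_kind, seed=config.seed),
                vif_cut=config.vif_cut,
                importance_floor=config.importance_floor,
            )
            selected[table.stage_label] = {
                "selected": sel,
                "n_iterations": len(history),
                "rmse_per_iteration": [h.rmse for h in history],
            }

    log.info("stage 5/6: comparison statistics")
    comparison: dict = {}
    if len(tables) >= 2 and len(config.model_kinds) >= 2:
        anova_p, letters = models.compare_methods(rmse_matrix)
        comparison["anova_p"] = anova_p
        comparison["lsd_letters"] = letters
    if reduced_full_pairs and len(reduced_full_pairs) >= 2:
        full = [a for a, _ in reduced_full_pairs]
        red = [b for _, b in reduced_full_pairs]
        comparison["soil_inclusion_p"] = models.soil_inclusion_test(full, red)

    log.info("stage 6/6: writing report")
    _write_json(out_dir / "metrics.json", metrics)
    _write_json(out_dir / "selected_features.json", selected)
    _write_json(out_dir / "comparison.json", comparison)
    _write_json(out_dir / "funnel.json", funnel)
    written += ["metrics.json", "selected_features.json", "comparison.json", "funnel.json"]

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "scenario_seed": config.scenario.seed,
        "model_kinds": list(config.model_kinds),
        "split_ratio": config.split_ratio,
        "stages": [t.stage_label for t in tables],
        "files": sorted(written) + ["MANIFEST.json"],
    }
    _write_json(out_dir / "MANIFEST.json", manifest)

    return RunReport(
        output_dir=out_dir,
        metrics=metrics,
        selected_features=selected,
        comparison=comparison,
        manifest=manifest,
    )


__all__ = ["RunConfig", "RunReport", "run_pipeline"]
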