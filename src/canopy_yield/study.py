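"""Desk-scale synthetic studies: end-to-end scenario runs and the method /
soil-contribution comparisons.

These helpers chain the full analysis — generate a field, mask bare ground,
build Thiessen polygons, extract zonal features, fit models — at a problem
size a single CPU handles in minutes (144 m x 144 m grid, ~1000 polygons,
two growth stages), and summarize the comparisons the pipeline reports:
method ranking by test RMSE and the paired soil/slope-inclusion test.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import geometry, models, raster_ops
from .grid import GridSpec
from .models import FeatureTable, Metrics, ModelConfig
from .spectral import BandVector, compute_indices, index_names
from .synthetic import ScenarioConfig, SyntheticField, generate_field

#: The five predictors removed for the reduced ("spectral-only") models.
SOIL_SLOPE_FEATURES = ("sand", "silt", "clay", "om", "slope")

#: Polygon filter for the default 4.2 m x 4.0 m harvester cells.
DEFAULT_AREA_BOUNDS = (12.0, 22.0)
DEFAULT_ROUNDNESS_MAX = 1.5


def study_scenario(
    seed: int,
    *,
    nonlinearity: str = "threshold-interaction",
    soil_effect_weight: float = 1.0,
    slope_effect_weight: float = 0.7,
    grid_n: int = 144,
    covers: tuple[float, ...] = (0.5, 0.7),
    stage_labels: tuple[str, ...] = ("V9", "V14/VT"),
    daps: tuple[int, ...] = (64, 83),
) -> ScenarioConfig:
    """Desk-scale scenario config used by the comparison studies."""
    return ScenarioConfig(
        seed=seed,
        grid=GridSpec(grid_n, grid_n, 1.0),
        soil_effect_weight=soil_effect_weight,
        slope_effect_weight=slope_effect_weight,
        nonlinearity=nonlinearity,
        n_stages=len(covers),
        canopy_cover_by_stage=covers,
        stage_labels=stage_labels,
        daps=daps,
    )


def build_feature_tables(
    field_data: SyntheticField,
    mask_threshold: float | str = "auto",
    area_bounds: tuple[float, float] = DEFAULT_AREA_BOUNDS,
    roundness_max: float = DEFAULT_ROUNDNESS_MAX,
    drop_edges: bool = True,
) -> tuple[list[FeatureTable], dict]:
    """Polygon feature tables for every growth stage of a generated field.

    Per stage: NDVIre bare-ground masking, zonal means of the masked bands
    and the soil/slope rasters over the filtered Thiessen polygons, then all
    registry indices computed from the zonal band means (zonal averaging
    first, index arithmetic second).  Rows with any missing predictor are
    dropped and counted.  Returns the tables plus a funnel log.
    """
    cfg = field_data.config
    polys = geometry.thiessen_polygons(field_data.points, cfg.boundary)
    kept = geometry.filter_polygons(
        polys, area_bounds=area_bounds, roundness_max=roundness_max, drop_edges=drop_edges
    )
    funnel = {
        "points": int(field_data.points.n),
        "polygons": len(polys),
        "polygons_retained": len(kept),
        "rows_dropped_by_stage": {},
        "mask_threshold_by_stage": {},
    }
    yields = pd.Series(field_data.points.yield_value, index=field_data.points.point_id)

    soil_rasters = dict(field_data.soil.soil_rasters())
    soil_rasters["slope"] = field_data.soil.slope
    soil_recs = geometry.zonal_means(soil_rasters, kept)

    tables: list[FeatureTable] = []
    for stack in field_data.stacks:
        mask = raster_ops.ndvire_mask(stack.rededge, stack.red, threshold=mask_threshold)
        masked = raster_ops.apply_mask(stack, mask)
        band_recs = geometry.zonal_means(masked.bands(), kept)

        rows = {}
        for p, brec, srec in zip(kept, band_recs, soil_recs):
            rows[p.polygon_id] = {**brec.means, **srec.means}
        df = pd.DataFrame.from_dict(rows, orient="index")

        bv = BandVector(
            blue=df["blue"].to_numpy(),
            green=df["green"].to_numpy(),
            red=df["red"].to_numpy(),
            rededge=df["rededge"].to_numpy(),
            nir=df["nir"].to_numpy(),
        )
        for name, vals in compute_indices(bv).items():
            df[name] = vals
        df["yield_mg_ha"] = yields.reindex(df.index)

        table = FeatureTable(data=df, stage_label=stack.stage_label, dap=stack.dap)
        table, n_dropped = table.dropna()
        funnel["rows_dropped_by_stage"][stack.stage_label] = n_dropped
        funnel["mask_threshold_by_stage"][stack.stage_label] = mask.threshold_used
        tables.append(table)
    return tables, funnel


def fit_and_score(
    table: FeatureTable,
    kinds: Sequence[str],
    split_ratio: float = 0.8,
    seed: int = 0,
    reduced: bool = False,
) -> dict[str, Metrics]:
    """Split one stage table and fit/evaluate the requested model kinds.

    ``reduced=True`` drops the soil/slope predictors first (the
    spectral-only contrast)."""
    if reduced:
        keep = [p for p in table.predictors if p not in SOIL_SLOPE_FEATURES]
        table = table.subset(keep)
    train, test = models.split_train_test(table, split_ratio, seed)
    out = {}
    for kind in kinds:
        fit = models.fit_model(ModelConfig(kind=kind, seed=seed), train)
        out[kind] = models.evaluate(fit, test)
    return out


def run_method_study(
    seeds: Iterable[int],
    *,
    nonlinearity: str = "threshold-interaction",
    soil_effect_weight: float = 1.0,
    slope_effect_weight: float = 0.7,
    kinds: Sequence[str] = ("MLR", "RF", "GBR", "XGB"),
    with_reduced: bool = True,
    grid_n: int = 144,
) -> pd.DataFrame:
    """Run the scenario across seeds; one row per (seed, stage, method) with
    full-model test RMSE and, for the ensemble methods, the reduced-model
    RMSE without soil/slope predictors."""
    ensemble = [k for k in kinds if k != "MLR"]
    records = []
    for seed in seeds:
        cfg = study_scenario(
            seed,
            nonlinearity=nonlinearity,
            soil_effect_weight=soil_effect_weight,
            slope_effect_weight=slope_effect_weight,
            grid_n=grid_n,
        )
        field_data = generate_field(cfg)
        tables, _ = build_feature_tables(field_data)
        for table in tables:
            full = fit_and_score(table, kinds, seed=seed)
            red = (
                fit_and_score(table, ensemble, seed=seed, reduced=True)
                if with_reduced and ensemble
                else {}
            )
            for kind in kinds:
                records.append(
                    {
                        "seed": seed,
                        "stage": table.stage_label,
                        "method": kind,
                        "rmse": full[kind].rmse,
                        "r2": full[kind].r2,
                        "rmse_reduced": red[kind].rmse if kind in red else np.nan,
                    }
                )
    return pd.DataFrame.from_records(records)


def mean_rmse_by_method(results: pd.DataFrame) -> pd.Series:
    return results.groupby("method")["rmse"].mean()


def soil_inclusion_pvalue(results: pd.DataFrame) -> float:
    """Paired one-tailed t-test over the (ensemble method x stage) pairs of
    seed-averaged full vs reduced RMSEs."""
    ens = results.dropna(subset=["rmse_reduced"])
    pairs = ens.groupby(["method", "stage"])[["rmse", "rmse_reduced"]].mean()
    return models.soil_inclusion_test(pairs["rmse"].to_numpy(), pairs["rmse_reduced"].to_numpy())


def null_rejection_rate(seeds: Iterable[int], alpha: float = 0.05, grid_n: int = 144) -> float:
    """Fraction of seeds whose per-seed soil-inclusion test rejects at
    ``alpha`` under the null scenario (no soil or slope pathway to yield)."""
    rejections = 0
    seeds = list(seeds)
    for seed in seeds:
        res = run_method_study(
            [seed],
            nonlinearity="linear",
            soil_effect_weight=0.0,
            slope_effect_weight=0.0,
            kinds=("RF", "GBR", "XGB"),
            grid_n=grid_n,
        )
        pairs = res.dropna(subset=["rmse_reduced"])
        p = models.soil_inclusion_test(
            pairs["rmse"].to_numpy(), pairs["rmse_reduced"].to_numpy()
        )
        if p < alpha:
            rejections += 1
    return rejections / len(seeds)


__all__ = [
    "SOIL_SLOPE_FEATURES",
    "study_scenario",
    "build_feature_tables",
    "fit_and_score",
    "run_method_study",
    "mean_rmse_by_method",
    "soil_inclusion_pvalue",
    "null_rejection_rate",
]
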