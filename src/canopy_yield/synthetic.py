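"""Seed-reproducible synthetic fields: soil, terrain, canopy reflectance, yield.

The generator emulates the statistical structure of a rain-fed
production-scale corn field on vertic clay soils: two smoothly interlocking
soil bodies (a heavy smectitic clay and a silty carbonatic clay), a gently
sloping DEM with ~8 m total relief and a diagonal ridge, multispectral canopy
reflectance whose greenness tracks a latent vigor field driven by soil and
slope, interspersed bare-soil pixels, and harvester yield points on parallel
transects with yield = f(vigor, soil, slope) + noise around a configurable
mean (~10.19 Mg/ha, CV ~12%).

Every generated dataset exposes its truths — latent vigor, canopy masks and
yield-generating coefficients — so downstream recovery tests can read them.
"""

from __future__ import annotations

import datetime as dt
import tomllib
from dataclasses import dataclass
from importlib import resources

import numpy as np
from scipy import ndimage
from shapely.geometry import Polygon, box

from .grid import GridSpec, GridMismatchError, InvalidGridError, Raster
from .raster_ops import EmptyOutputError, slope_from_dem

BAND_NAMES = ("blue", "green", "red", "rededge", "nir")

#: Yields are clipped at this positive floor (Mg/ha) to avoid non-physical
#: values in deep low-vigor pockets.
YIELD_FLOOR = 1.5

#: Default growth-stage schedule: label, days after planting, canopy cover.
DEFAULT_STAGES = ("V4", "V5", "V6", "V7", "V9", "V12", "V14/VT")
DEFAULT_DAPS = (20, 27, 43, 55, 64, 78, 83)
DEFAULT_COVERS = (0.15, 0.25, 0.40, 0.55, 0.70, 0.80, 0.85)

#: Fixed blend defining the soil quality score entering the vigor field:
#: organic matter dominates, then plant-available water, then clay content.
SOIL_SCORE_WEIGHTS = {"om": 0.5, "awc": 0.3, "clay": 0.2}


def load_endmembers() -> dict[str, dict[str, float]]:
    """Endmember spectra (healthy canopy, stressed canopy, bare soil)."""
    with resources.files("canopy_yield.data").joinpath("endmembers.toml").open("rb") as fh:
        return tomllib.load(fh)


@dataclass(frozen=True)
class ScenarioConfig:
    """Everything that defines one synthetic study scenario.

    ``soil_effect_weight`` and ``slope_effect_weight`` scale both the soil /
    slope contribution to the latent vigor field and their direct terms in
    the yield response, so setting one to zero severs that pathway entirely.
    """

    seed: int = 0
    grid: GridSpec = GridSpec(300, 300, 1.0)
    soil_effect_weight: float = 1.0
    slope_effect_weight: float = 0.7
    vigor_noise_sd: float = 0.6
    yield_mean: float = 10.19
    yield_cv: float = 0.1211
    nonlinearity: str = "linear"  # "linear" | "threshold-interaction"
    n_stages: int = 7
    canopy_cover_by_stage: tuple[float, ...] = DEFAULT_COVERS
    stage_labels: tuple[str, ...] = DEFAULT_STAGES
    daps: tuple[int, ...] = DEFAULT_DAPS
    transect_spacing: float = 4.2
    point_spacing: float = 4.0
    relief_m: float = 8.0
    yield_noise_sd: float = 0.35
    band_noise_sd: float = 0.004
    correlation_length: float = 18.0  # meters; soil autocorrelation scale
    boundary_margin: float = 2.0  # meters kept free of points at field edges
    planting_date: dt.date = dt.date(2023, 2, 28)

    def __post_init__(self) -> None:
        if self.grid.n_rows < 1 or self.grid.n_cols < 1:
            raise InvalidGridError("non-positive grid dimensions")
        if not self.yield_mean > 0:
            raise ValueError("yield_mean must be > 0")
        if not 0 <= self.yield_cv < 1:
            raise ValueError("yield_cv must be in [0, 1)")
        if self.soil_effect_weight < 0 or self.slope_effect_weight < 0:
            raise ValueError("effect weights must be >= 0")
        covers = self.canopy_cover_by_stage[: self.n_stages]
        if any(c < 0 or c > 1 for c in covers):
            raise ValueError("canopy cover must be in [0, 1]")
        if any(b > a for a, b in zip(covers[1:], covers[:-1])):
            raise ValueError("canopy cover must be non-decreasing across stages")
        if self.nonlinearity not in ("linear", "threshold-interaction"):
            raise ValueError(f"unknown nonlinearity {self.nonlinearity!r}")

    @property
    def stages(self) -> list[tuple[str, int, float]]:
        return list(
            zip(
                self.stage_labels[: self.n_stages],
                self.daps[: self.n_stages],
                self.canopy_cover_by_stage[: self.n_stages],
            )
        )

    @property
    def boundary(self) -> Polygon:
        return box(*self.grid.bounds)


@dataclass
class SoilTerrainStack:
    """Soil-property rasters plus DEM and derived slope on one grid."""

    sand: Raster
    silt: Raster
    clay: Raster
    om: Raster
    bd: Raster
    awc: Raster
    dem: Raster
    slope: Raster
    grid: GridSpec
    zone: np.ndarray | None = None  # truth: 1 = heavy-clay body, 0 = silty body

    def soil_rasters(self) -> dict[str, Raster]:
        return {
            "sand": self.sand,
            "silt": self.silt,
            "clay": self.clay,
            "om": self.om,
            "bd": self.bd,
            "awc": self.awc,
        }


@dataclass
class ReflectanceStack:
    """Co-registered 5-band reflectance for one flight / growth stage."""

    blue: Raster
    green: Raster
    red: Raster
    rededge: Raster
    nir: Raster
    stage_label: str
    dap: int
    grid: GridSpec
    flight_date: dt.date | None = None
    canopy_mask: np.ndarray | None = None  # truth mask (1 = canopy)

    def bands(self) -> dict[str, Raster]:
        return {name: getattr(self, name) for name in BAND_NAMES}


@dataclass
class HarvestPointSet:
    """Cleaned yield-monitor records: position and yield per point."""

    point_id: np.ndarray
    x: np.ndarray
    y: np.ndarray
    yield_value: np.ndarray
    harvested_area_per_point: float

    def __post_init__(self) -> None:
        if len(np.unique(self.point_id)) != len(self.point_id):
            raise ValueError("point ids must be unique")

    @property
    def n(self) -> int:
        return len(self.point_id)


@dataclass
class SyntheticField:
    """A full generated dataset plus its generating truths."""

    config: ScenarioConfig
    soil: SoilTerrainStack
    stacks: list[ReflectanceStack]
    points: HarvestPointSet
    vigor: Raster
    truth: dict


def _smooth_field(rng: np.random.Generator, grid: GridSpec, corr_len_m: float) -> np.ndarray:
    """Zero-mean, unit-variance Gaussian random field with the given
    autocorrelation length (meters)."""
    sigma = max(corr_len_m / grid.pixel_size, 0.5)
    f = ndimage.gaussian_filter(rng.standard_normal(grid.shape), sigma=sigma, mode="nearest")
    sd = f.std()
    return (f - f.mean()) / (sd if sd > 0 else 1.0)


def _z(a: np.ndarray) -> np.ndarray:
    sd = np.nanstd(a)
    return (a - np.nanmean(a)) / (sd if sd > 0 else 1.0)


def make_soil_terrain(config: ScenarioConfig) -> SoilTerrainStack:
    """Generate soil property rasters, DEM and slope for one scenario.

    Sand/silt/clay start as smoothed Gaussian random fields anchored to two
    interlocking soil bodies and are closed (renormalized to sum exactly 100).
    The DEM is a gentle diagonal ridge plus smooth noise rescaled so that
    ``max - min`` equals the relief target exactly.  Identical seed + config
    give bit-identical output.
    """
    grid = config.grid
    rng = np.random.default_rng([config.seed, 101])

    # Two smoothly interlocking soil bodies from a thresholded smooth field.
    zone_field = _smooth_field(rng, grid, config.correlation_length * 2.0)
    zone = (zone_field > np.median(zone_field)).astype(float)
    zone_s = ndimage.gaussian_filter(zone, sigma=2.0 / grid.pixel_size, mode="nearest")

    def comp(base_a, base_b, noise_sd):
        f = base_b + (base_a - base_b) * zone_s
        f = f + noise_sd * _smooth_field(rng, grid, config.correlation_length)
        return f

    # zone 1: heavy smectitic clay; zone 0: fine-silty carbonatic clay.
    sand = np.clip(comp(15.0, 10.0, 2.5), 1.0, None)
    silt = np.clip(comp(30.0, 45.0, 3.0), 1.0, None)
    clay = np.clip(comp(55.0, 45.0, 3.0), 1.0, None)
    total = sand + silt + clay
    sand, silt, clay = 100.0 * sand / total, 100.0 * silt / total, 100.0 * clay / total

    om = np.clip(comp(3.2, 2.4, 0.30), 0.5, 8.0)
    bd = np.clip(comp(1.25, 1.35, 0.05), 0.9, 1.8)
    awc = np.clip(comp(0.16, 0.13, 0.015), 0.03, 0.35)

    # DEM: ridge along the NW-SE diagonal, highest near the center, falling
    # toward the NE and SW corners, plus smooth noise; exact relief rescale.
    xn = (np.arange(grid.n_cols) + 0.5) / grid.n_cols
    yn = (np.arange(grid.n_rows) + 0.5) / grid.n_rows
    X, Y = np.meshgrid(xn, yn)
    u = (X - Y) / np.sqrt(2.0)  # signed distance from the main diagonal
    dem_raw = 1.0 - 2.0 * u**2 + 0.15 * _smooth_field(rng, grid, config.correlation_length * 2.5)
    rngv = dem_raw.max() - dem_raw.min()
    dem = 192.0 + (dem_raw - dem_raw.min()) / (rngv if rngv > 0 else 1.0) * config.relief_m

    mk = lambda v, name: Raster(values=v, grid=grid, name=name)
    dem_r = mk(dem, "dem")
    return SoilTerrainStack(
        sand=mk(sand, "sand"),
        silt=mk(silt, "silt"),
        clay=mk(clay, "clay"),
        om=mk(om, "om"),
        bd=mk(bd, "bd"),
        awc=mk(awc, "awc"),
        dem=dem_r,
        slope=slope_from_dem(dem_r),
        grid=grid,
        zone=zone.astype(np.uint8),
    )


def soil_quality_score(soil: SoilTerrainStack) -> np.ndarray:
    """Fixed linear blend of standardized OM, AWC and clay rasters."""
    w = SOIL_SCORE_WEIGHTS
    return (
        w["om"] * _z(soil.om.values)
        + w["awc"] * _z(soil.awc.values)
        + w["clay"] * _z(soil.clay.values)
    )


def latent_vigor(soil: SoilTerrainStack, config: ScenarioConfig) -> Raster:
    """Standardized latent crop-vigor field: soil score, negative slope and
    spatially smooth noise, weighted by the scenario's effect weights."""
    rng = np.random.default_rng([config.seed, 202])
    noise = config.vigor_noise_sd * _smooth_field(rng, config.grid, 6.0)
    raw = (
        config.soil_effect_weight * _z(soil_quality_score(soil))
        + config.slope_effect_weight * _z(-soil.slope.values)
        + noise
    )
    return Raster(values=_z(raw), grid=config.grid, name="vigor")


def mixing_weight(vigor: np.ndarray, steepness: float = 1.5) -> np.ndarray:
    """Logistic map from standardized vigor to the healthy-endmember fraction."""
    return 1.0 / (1.0 + np.exp(-steepness * np.asarray(vigor, dtype=float)))


def canopy_mask_for_cover(
    config: ScenarioConfig, cover: float, rng: np.random.Generator
) -> np.ndarray:
    """Canopy mask at a given areal cover fraction, grown outward from
    planting rows (every third pixel row) by distance-transform thresholding."""
    grid = config.grid
    if cover <= 0:
        return np.zeros(grid.shape, dtype=np.uint8)
    if cover >= 1:
        return np.ones(grid.shape, dtype=np.uint8)
    rows = np.zeros(grid.shape, dtype=bool)
    rows[1::3, :] = True
    dist = ndimage.distance_transform_edt(~rows, sampling=grid.pixel_size)
    score = dist + 0.25 * rng.random(grid.shape)  # random tie-break within rings
    thr = np.quantile(score, cover)
    return (score <= thr).astype(np.uint8)


def make_reflectance_series(
    soil: SoilTerrainStack, config: ScenarioConfig
) -> list[ReflectanceStack]:
    """Per-stage 5-band reflectance from the two-endmember mixing model.

    Canopy pixels mix the healthy and stressed canopy endmembers by the
    vigor-driven weight; non-canopy pixels carry the bare-soil endmember.
    A small additive band noise (``band_noise_sd``) is applied and values are
    clipped to [0, 1].
    """
    if soil.grid != config.grid:
        raise GridMismatchError("soil stack grid does not match scenario grid")
    vigor = latent_vigor(soil, config)
    m = mixing_weight(vigor.values)
    em = load_endmembers()
    rng = np.random.default_rng([config.seed, 303])

    stacks: list[ReflectanceStack] = []
    for stage_label, dap, cover in config.stages:
        mask = canopy_mask_for_cover(config, cover, rng)
        bands: dict[str, Raster] = {}
        for bname in BAND_NAMES:
            canopy_val = m * em["healthy_canopy"][bname] + (1.0 - m) * em["stressed_canopy"][bname]
            vals = np.where(mask == 1, canopy_val, em["bare_soil"][bname])
            if config.band_noise_sd > 0:
                vals = vals + config.band_noise_sd * rng.standard_normal(config.grid.shape)
            bands[bname] = Raster(
                values=np.clip(vals, 0.0, 1.0), grid=config.grid, name=bname
            )
        stacks.append(
            ReflectanceStack(
                **bands,
                stage_label=stage_label,
                dap=dap,
                grid=config.grid,
                flight_date=config.planting_date + dt.timedelta(days=dap),
                canopy_mask=mask,
            )
        )
    return stacks


def _transect_points(config: ScenarioConfig) -> tuple[np.ndarray, np.ndarray]:
    """Harvester point positions on parallel (east-west) transects."""
    x0, y0, x1, y1 = config.boundary.bounds
    margin = config.boundary_margin
    ys = np.arange(y1 - margin - config.transect_spacing / 2.0, y0 + margin, -config.transect_spacing)
    xs = np.arange(x0 + margin + config.point_spacing / 2.0, x1 - margin, config.point_spacing)
    if len(ys) == 0 or len(xs) == 0:
        raise EmptyOutputError("transect spacing larger than the field")
    X, Y = np.meshgrid(xs, ys)
    return X.ravel(), Y.ravel()


def make_harvest_points(
    soil: SoilTerrainStack, vigor_final: Raster, config: ScenarioConfig
) -> tuple[HarvestPointSet, dict]:
    """Yield points on parallel transects plus the generating truths.

    ``yield = yield_mean * (1 + yield_cv * standardized_response)`` clipped at
    a positive floor.  The standardized response is linear in per-point
    z-scores of vigor, soil score and (negative) slope when
    ``nonlinearity="linear"``; the threshold-interaction variant adds a
    clay x slope interaction and a vigor threshold (hinge) term.  The truth
    dict stores the design columns and the effective coefficients in Mg/ha
    per unit z-score so recovery tests can read them.
    """
    if vigor_final.grid != soil.grid:
        raise GridMismatchError("vigor raster grid does not match soil grid")
    x, y = _transect_points(config)
    rng = np.random.default_rng([config.seed, 404])

    zv = _z(vigor_final.sample(x, y))
    zs = _z(Raster(soil_quality_score(soil), soil.grid).sample(x, y))
    zt = _z(-soil.slope.sample(x, y))
    zc = _z(soil.clay.sample(x, y))

    b = {"vigor": 0.8, "soil": 0.35 * config.soil_effect_weight, "neg_slope": 0.35 * config.slope_effect_weight}
    raw = b["vigor"] * zv + b["soil"] * zs + b["neg_slope"] * zt
    nonlin = {}
    if config.nonlinearity == "threshold-interaction":
        nonlin = {
            "clay_x_negslope": 0.5 * np.sqrt(config.soil_effect_weight * config.slope_effect_weight),
            "vigor_hinge": 0.6,
            "hinge_knot": 0.4,
        }
        raw = raw + nonlin["clay_x_negslope"] * zc * zt
        raw = raw + nonlin["vigor_hinge"] * np.maximum(zv - nonlin["hinge_knot"], 0.0)
    eps = rng.standard_normal(x.size)
    raw = raw + config.yield_noise_sd * eps

    mu, s = raw.mean(), raw.std()
    response = (raw - mu) / (s if s > 0 else 1.0)
    yields = np.maximum(config.yield_mean * (1.0 + config.yield_cv * response), YIELD_FLOOR)

    points = HarvestPointSet(
        point_id=np.arange(1, x.size + 1),
        x=x,
        y=y,
        yield_value=yields,
        harvested_area_per_point=config.transect_spacing * config.point_spacing,
    )
    scale = config.yield_mean * config.yield_cv / (s if s > 0 else 1.0)
    truth = {
        "design": {"vigor": zv, "soil": zs, "neg_slope": zt, "clay": zc},
        "raw_coefficients": b,
        "effective_coefficients": {k: scale * v for k, v in b.items()},
        "effective_intercept": config.yield_mean * (1.0 - config.yield_cv * mu / (s if s > 0 else 1.0)),
        "noise_sd_mg_ha": scale * config.yield_noise_sd,
        "nonlinear_terms": nonlin,
        "response_scale": scale,
    }
    return points, truth


def generate_field(config: ScenarioConfig) -> SyntheticField:
    """Generate a complete synthetic dataset (soil, reflectance, points)."""
    soil = make_soil_terrain(config)
    stacks = make_reflectance_series(soil, config)
    vigor = latent_vigor(soil, config)
    points, truth = make_harvest_points(soil, vigor, config)
    return SyntheticField(
        config=config, soil=soil, stacks=stacks, points=points, vigor=vigor, truth=truth
    )


__all__ = [
    "BAND_NAMES",
    "YIELD_FLOOR",
    "SOIL_SCORE_WEIGHTS",
    "ScenarioConfig",
    "SoilTerrainStack",
    "ReflectanceStack",
    "HarvestPointSet",
    "SyntheticField",
    "load_endmembers",
    "make_soil_terrain",
    "make_reflectance_series",
    "make_harvest_points",
    "generate_field",
    "latent_vigor",
    "soil_quality_score",
    "mixing_weight",
    "canopy_mask_for_cover",
]
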