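"""Grid-level operations: bare-ground masking, nearest resampling, slope.

Bare ground is separated from canopy on the NDVIre raster: pixels below a
threshold are soil, at or above it vegetation.  The threshold is either a
per-flight value chosen by the analyst or, by default, Otsu's
between-class-variance maximizer over a 256-bin histogram of the finite
NDVIre values.  Masked-out pixels become nodata rather than zero reflectance,
so zonal statistics later average vegetation pixels only.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .grid import GridSpec, GridMismatchError, InvalidGridError, Raster
from .spectral import BandVector, compute_index


class EmptyOutputError(ValueError):
    """An operation produced no output (disjoint extents, oversized spacing...)."""


@dataclass
class BinaryMask:
    """0/1 vegetation mask plus the threshold that produced it."""

    values: np.ndarray
    threshold_used: float
    grid: GridSpec

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != self.grid.shape:
            raise GridMismatchError("mask shape does not match grid")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("mask values must be strictly 0 or 1")

    @property
    def n_vegetation(self) -> int:
        return int(self.values.sum())

    @property
    def n_soil(self) -> int:
        return int(self.values.size - self.values.sum())


def otsu_threshold(values: np.ndarray, nbins: int = 256) -> float:
    """Otsu's threshold: exhaustive scan of the between-class variance
    over an ``nbins``-bin histogram of the finite values.

    Returns the center of the bin maximizing the between-class variance
    (first maximum on ties).
    """
    v = np.asarray(values, dtype=float).ravel()
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise EmptyOutputError("no finite values to threshold")
    if v.min() == v.max():
        return float(v.min())
    hist, edges = np.histogram(v, bins=nbins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    p = hist.astype(float) / hist.sum()
    omega = np.cumsum(p)
    mu = np.cumsum(p * centers)
    mu_t = mu[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b2 = (mu_t * omega - mu) ** 2 / (omega * (1.0 - omega))
    sigma_b2[~np.isfinite(sigma_b2)] = 0.0
    return float(centers[int(np.argmax(sigma_b2))])


def ndvire_mask(rededge: Raster, red: Raster, threshold: float | str = "auto") -> BinaryMask:
    """Vegetation mask from the NDVIre raster.

    Pixel -> 1 iff ``NDVIre >= threshold``, else 0; nodata pixels -> 0.
    ``threshold="auto"`` selects Otsu's threshold over the finite NDVIre
    histogram; ``threshold_used`` records the value applied.
    """
    if rededge.grid != red.grid:
        raise GridMismatchError("rededge and red rasters are on different grids")
    ndvire = compute_index("NDVIre", BandVector(red=red.values, rededge=rededge.values))
    if threshold == "auto":
        thr = otsu_threshold(ndvire)
    else:
        thr = float(threshold)
    with np.errstate(invalid="ignore"):
        mask = (ndvire >= thr) & np.isfinite(ndvire)
    return BinaryMask(values=mask.astype(np.uint8), threshold_used=thr, grid=rededge.grid)


def apply_mask(stack, mask: BinaryMask):
    """Set masked-out (soil) pixels of every band to nodata.

    Vegetation pixels are unchanged; the operation is idempotent.  Accepts a
    :class:`~canopy_yield.synthetic.ReflectanceStack` (returns a new stack) or
    a single :class:`Raster`.
    """
    if isinstance(stack, Raster):
        if stack.grid != mask.grid:
            raise GridMismatchError("raster and mask are on different grids")
        return stack.copy(values=np.where(mask.values == 1, stack.values, np.nan))
    if stack.grid != mask.grid:
        raise GridMismatchError("stack and mask are on different grids")
    bands = {
        name: np.where(mask.values == 1, getattr(stack, name).values, np.nan)
        for name in ("blue", "green", "red", "rededge", "nir")
    }
    return dataclasses.replace(
        stack,
        **{name: getattr(stack, name).copy(values=v) for name, v in bands.items()},
    )


def resample_nearest(raster: Raster, target: GridSpec) -> Raster:
    """Nearest-neighbor resampling onto ``target``.

    Each target pixel takes the value of the source pixel containing its
    center, so the output value set is a subset of the input value set (no
    new values are invented).  Target pixels outside the source extent are
    nodata; fully disjoint extents raise :class:`EmptyOutputError`.
    """
    x, y = target.pixel_centers()
    row, col = raster.grid.rowcol_of(x, y)
    ok = (
        (row >= 0)
        & (row < raster.grid.n_rows)
        & (col >= 0)
        & (col < raster.grid.n_cols)
    )
    if not ok.any():
        raise EmptyOutputError("target grid does not overlap the source raster")
    out = np.full(target.shape, np.nan)
    out[ok] = raster.values[row[ok], col[ok]]
    return Raster(values=out, grid=target, name=raster.name)


def slope_from_dem(dem: Raster) -> Raster:
    """Slope in degrees by Horn's 3x3 finite-difference method.

    ``slope = atan(sqrt(gx^2 + gy^2))`` with the Horn weights (1, 2, 1) on
    each flank of the 3x3 window; edge pixels use edge-replication padding.
    """
    if not dem.grid.pixel_size > 0:
        raise InvalidGridError("pixel_size must be > 0")
    px = dem.grid.pixel_size
    p = np.pad(dem.values, 1, mode="edge")
    a, b, c = p[:-2, :-2], p[:-2, 1:-1], p[:-2, 2:]
    d, f = p[1:-1, :-2], p[1:-1, 2:]
    g, h, i = p[2:, :-2], p[2:, 1:-1], p[2:, 2:]
    gx = ((c + 2 * f + i) - (a + 2 * d + g)) / (8.0 * px)
    gy = ((g + 2 * h + i) - (a + 2 * b + c)) / (8.0 * px)
    slope = np.degrees(np.arctan(np.hypot(gx, gy)))
    return Raster(values=slope, grid=dem.grid, name="slope")


__all__ = [
    "BinaryMask",
    "EmptyOutputError",
    "otsu_threshold",
    "ndvire_mask",
    "apply_mask",
    "resample_nearest",
    "slope_from_dem",
]
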