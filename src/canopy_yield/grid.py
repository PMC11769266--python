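"""Analysis grids and in-memory rasters.

A :class:`GridSpec` describes a regular, north-up, projected-metric grid with
its origin at the *top-left corner*; a pixel's value refers to its full square
footprint (area convention).  Rasters are plain ``float64`` numpy arrays with
``NaN`` as the in-memory nodata sentinel; on disk the sentinel is ``-9999``
and rasters are written as ESRI ASCII grids (plain-text, georeferenced).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

#: On-disk nodata sentinel for raster files.
NODATA = -9999.0


class GridMismatchError(ValueError):
    """Two rasters that must share a grid do not."""


class InvalidGridError(ValueError):
    """A grid specification violates its invariants."""


@dataclass(frozen=True)
class GridSpec:
    """Regular metric grid, row-major, origin at the top-left corner.

    The center of pixel ``(row, col)`` sits at
    ``(origin_x + (col + 0.5) * pixel_size, origin_y - (row + 0.5) * pixel_size)``.
    """

    n_rows: int
    n_cols: int
    pixel_size: float
    origin_x: float = 0.0
    origin_y: float = 0.0
    crs_label: str = "local-metric"

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise InvalidGridError(
                f"grid dimensions must be >= 1, got {self.n_rows}x{self.n_cols}"
            )
        if not self.pixel_size > 0:
            raise InvalidGridError(f"pixel_size must be > 0, got {self.pixel_size}")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def width(self) -> float:
        """Field width in meters."""
        return self.n_cols * self.pixel_size

    @property
    def height(self) -> float:
        """Field height in meters."""
        return self.n_rows * self.pixel_size

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the grid footprint."""
        return (
            self.origin_x,
            self.origin_y - self.height,
            self.origin_x + self.width,
            self.origin_y,
        )

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Arrays ``(x, y)`` of shape ``(n_rows, n_cols)`` with pixel centers."""
        cols = np.arange(self.n_cols)
        rows = np.arange(self.n_rows)
        x = self.origin_x + (cols + 0.5) * self.pixel_size
        y = self.origin_y - (rows + 0.5) * self.pixel_size
        return np.meshgrid(x, y)

    def rowcol_of(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Row/col of the pixel whose footprint contains each point (may be out of range)."""
        col = np.floor((np.asarray(x) - self.origin_x) / self.pixel_size).astype(int)
        row = np.floor((self.origin_y - np.asarray(y)) / self.pixel_size).astype(int)
        return row, col


@dataclass
class Raster:
    """A single-band raster: float values on a :class:`GridSpec`, NaN = nodata."""

    values: np.ndarray
    grid: GridSpec
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise GridMismatchError(
                f"raster shape {self.values.shape} does not match grid {self.grid.shape}"
            )

    def copy(self, values: np.ndarray | None = None, name: str | None = None) -> "Raster":
        return Raster(
            values=self.values.copy() if values is None else np.asarray(values, float),
            grid=self.grid,
            name=self.name if name is None else name,
        )

    def sample(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Values of the pixels containing the given points; NaN outside the grid."""
        row, col = self.grid.rowcol_of(x, y)
        out = np.full(np.shape(row), np.nan)
        ok = (row >= 0) & (row < self.grid.n_rows) & (col >= 0) & (col < self.grid.n_cols)
        out[ok] = self.values[row[ok], col[ok]]
        return out


def same_grid(*rasters: Raster) -> GridSpec:
    """Return the shared grid or raise :class:`GridMismatchError`."""
    grids = {r.grid for r in rasters}
    if len(grids) != 1:
        raise GridMismatchError(f"rasters are on {len(grids)} different grids")
    return rasters[0].grid


def write_ascii_grid(raster: Raster, path: str | Path) -> Path:
    """Write a raster as an ESRI ASCII grid (text; nodata = -9999)."""
    path = Path(path)
    g = raster.grid
    vals = np.where(np.isfinite(raster.values), raster.values, NODATA)
    header = (
        f"ncols {g.n_cols}\n"
        f"nrows {g.n_rows}\n"
        f"xllcorner {g.origin_x!r}\n"
        f"yllcorner {g.origin_y - g.height!r}\n"
        f"cellsize {g.pixel_size!r}\n"
        f"NODATA_value {NODATA}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, vals, fmt="%.8g")
    return path


def read_ascii_grid(path: str | Path, name: str = "", crs_label: str = "local-metric") -> Raster:
    """Read an ESRI ASCII grid written by :func:`write_ascii_grid`."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        values = np.loadtxt(fh, ndmin=2)
    nodata = header.get("nodata_value", NODATA)
    values = np.where(values == nodata, np.nan, values)
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    grid = GridSpec(
        n_rows=n_rows,
        n_cols=n_cols,
        pixel_size=header["cellsize"],
        origin_x=header["xllcorner"],
        origin_y=header["yllcorner"] + n_rows * header["cellsize"],
        crs_label=crs_label,
    )
    return Raster(values=values, grid=grid, name=name or path.stem)


__all__ = [
    "NODATA",
    "GridSpec",
    "Raster",
    "GridMismatchError",
    "InvalidGridError",
    "same_grid",
    "write_ascii_grid",
    "read_ascii_grid",
]
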