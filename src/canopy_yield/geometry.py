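"""Thiessen (Voronoi) polygons around harvester points and zonal statistics.

Each yield-monitor record gets the region of the field nearer to it than to
any other record; polygons are clipped to the field boundary, measured
(area, perimeter, roundness) and filtered before raster zonal means are
extracted over them.

Roundness is the isoperimetric ratio ``P^2 / (4 pi A)``: exactly 1 for a
circle, larger for less round shapes (square ~1.273).  The pixel-in-zone rule
is pixel-center containment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import shapely
from shapely.geometry import MultiPoint, Point, Polygon

from .grid import Raster


class DuplicatePointError(ValueError):
    """Two or more generating points coincide."""


class InvalidPolygonError(ValueError):
    """A polygon is degenerate (fewer than 3 vertices) or not simple."""


@dataclass
class FieldPolygon:
    """A filtered Thiessen cell keyed to its generating harvest point."""

    polygon_id: int
    geometry: Polygon
    area: float = 0.0
    perimeter: float = 0.0
    roundness: float = float("nan")
    is_edge: bool = False

    @property
    def vertices(self) -> list[tuple[float, float]]:
        return list(self.geometry.exterior.coords)


def shape_metrics(polygon: Polygon | FieldPolygon) -> tuple[float, float, float]:
    """(area, perimeter, roundness) of a simple polygon.

    Area by the shoelace formula, perimeter as the vertex-chain length and
    roundness as the isoperimetric ratio ``P^2 / (4 pi A)``.
    """
    geom = polygon.geometry if isinstance(polygon, FieldPolygon) else polygon
    coords = list(geom.exterior.coords)
    if len(coords) < 4:  # closed ring repeats the first vertex
        raise InvalidPolygonError("polygon needs at least 3 distinct vertices")
    if not geom.is_valid:
        raise InvalidPolygonError("polygon is not simple")
    area = geom.area
    perimeter = geom.exterior.length
    if area <= 0:
        raise InvalidPolygonError("polygon area must be > 0")
    roundness = perimeter**2 / (4.0 * np.pi * area)
    return area, perimeter, roundness


def thiessen_polygons(points, boundary: Polygon) -> list[FieldPolygon]:
    """Voronoi diagram of the harvest points clipped to the field boundary.

    ``points`` is anything exposing ``point_id``, ``x`` and ``y`` arrays (a
    :class:`~canopy_yield.synthetic.HarvestPointSet`) or an ``(ids, x, y)``
    triple.  Each cell is tagged with its generating ``point_id``; cells
    touching the boundary ring are flagged ``is_edge``.
    """
    if isinstance(points, tuple):
        ids, x, y = points
    else:
        ids, x, y = points.point_id, points.x, points.y
    ids = np.asarray(ids)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 points for a Voronoi diagram")

    coords = np.column_stack([x, y])
    _, inverse, counts = np.unique(coords, axis=0, return_inverse=True, return_counts=True)
    if (counts > 1).any():
        dup_ids = sorted(
            int(i) for grp in np.where(counts > 1)[0] for i in ids[inverse == grp]
        )
        raise DuplicatePointError(f"coincident points with ids {dup_ids}")

    cells = shapely.voronoi_polygons(
        MultiPoint(coords), extend_to=boundary.buffer(2.0 * max(boundary.bounds[2] - boundary.bounds[0], boundary.bounds[3] - boundary.bounds[1])).envelope
    )
    # voronoi_polygons does not preserve input order: map cells back to their
    # generating points by containment.
    cell_geoms = list(cells.geoms)
    tree = shapely.STRtree(cell_geoms)
    pt_geoms = shapely.points(coords)
    idx_pts, idx_cells = tree.query(pt_geoms, predicate="intersects")
    cell_of_point = np.full(len(coords), -1, dtype=int)
    # On ties (point on a cell edge cannot happen for generators) keep first.
    for pi, ci in zip(idx_pts, idx_cells):
        if cell_of_point[pi] == -1:
            cell_of_point[pi] = ci
    if (cell_of_point == -1).any():
        missing = ids[cell_of_point == -1].tolist()
        raise ValueError(f"no Voronoi cell found for points {missing}")

    out: list[FieldPolygon] = []
    boundary_ring = boundary.exterior
    for k in range(len(coords)):
        clipped = cell_geoms[cell_of_point[k]].intersection(boundary)
        if clipped.is_empty:
            continue
        if clipped.geom_type == "MultiPolygon":  # keep the part holding the point
            pt = Point(coords[k])
            clipped = max(clipped.geoms, key=lambda gm: (gm.contains(pt), gm.area))
        area, perimeter, roundness = shape_metrics(clipped)
        out.append(
            FieldPolygon(
                polygon_id=int(ids[k]),
                geometry=clipped,
                area=area,
                perimeter=perimeter,
                roundness=roundness,
                is_edge=bool(clipped.exterior.intersects(boundary_ring)),
            )
        )
    return out


def filter_polygons(
    polys: Sequence[FieldPolygon],
    area_bounds: tuple[float, float] = (0.0, float("inf")),
    roundness_max: float = 3.0,
    drop_edges: bool = True,
) -> list[FieldPolygon]:
    """Retain polygons inside the area bounds, below the roundness cap and,
    if ``drop_edges``, not touching the field boundary.  Order-preserving."""
    lo, hi = area_bounds
    if lo > hi:
        raise ValueError(f"area bounds inverted: {area_bounds}")
    return [
        p
        for p in polys
        if lo <= p.area <= hi
        and p.roundness <= roundness_max
        and not (drop_edges and p.is_edge)
    ]


@dataclass
class ZonalRecord:
    """Per-polygon raster means (NaN where a zone had no valid pixel)."""

    polygon_id: int
    means: dict[str, float] = field(default_factory=dict)
    n_valid_pixels: dict[str, int] = field(default_factory=dict)

    @property
    def empty(self) -> bool:
        return all(n == 0 for n in self.n_valid_pixels.values())


def _pixel_assignment(grid, polys: Sequence[FieldPolygon]) -> tuple[np.ndarray, np.ndarray]:
    """Map pixel centers to polygons: returns (flat pixel index, polygon index)."""
    x, y = grid.pixel_centers()
    pts = shapely.points(np.column_stack([x.ravel(), y.ravel()]))
    tree = shapely.STRtree([p.geometry for p in polys])
    # 'within' is strict containment, so a center exactly on a shared cell
    # edge belongs to no zone; a pixel inside several (overlapping) polygons
    # counts once per polygon.
    idx_pix, idx_poly = tree.query(pts, predicate="within")
    return idx_pix, idx_poly


def zonal_mean(raster: Raster, polys: Sequence[FieldPolygon]) -> list[ZonalRecord]:
    """Mean of raster pixels whose centers fall in each polygon (NaN ignored)."""
    recs = zonal_means({raster.name or "value": raster}, polys)
    return recs


def zonal_means(
    rasters: Mapping[str, Raster], polys: Sequence[FieldPolygon]
) -> list[ZonalRecord]:
    """Zonal means of several co-registered rasters over the same polygons.

    The pixel-to-polygon assignment is computed once per grid and reused, so
    this is the preferred entry point for full raster stacks.
    """
    records = [ZonalRecord(polygon_id=p.polygon_id) for p in polys]
    by_grid: dict = {}
    for name, raster in rasters.items():
        if raster.grid not in by_grid:
            by_grid[raster.grid] = _pixel_assignment(raster.grid, polys)
        idx_pix, idx_poly = by_grid[raster.grid]
        vals = raster.values.ravel()[idx_pix]
        finite = np.isfinite(vals)
        sums = np.zeros(len(polys))
        counts = np.zeros(len(polys), dtype=int)
        np.add.at(sums, idx_poly[finite], vals[finite])
        np.add.at(counts, idx_poly[finite], 1)
        with np.errstate(invalid="ignore"):
            means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        for k, rec in enumerate(records):
            rec.means[name] = float(means[k])
            rec.n_valid_pixels[name] = int(counts[k])
    return records


# ---------------------------------------------------------------------------
# GeoJSON I/O
# ---------------------------------------------------------------------------

def polygons_to_geojson(polys: Sequence[FieldPolygon], path: str | Path | None = None) -> dict:
    """FeatureCollection with polygon_id, area, perimeter, roundness, is_edge."""
    features = [
        {
            "type": "Feature",
            "geometry": shapely.geometry.mapping(p.geometry),
            "properties": {
                "polygon_id": p.polygon_id,
                "area": p.area,
                "perimeter": p.perimeter,
                "roundness": p.roundness,
                "is_edge": p.is_edge,
            },
        }
        for p in polys
    ]
    fc = {"type": "FeatureCollection", "features": features}
    if path is not None:
        Path(path).write_text(json.dumps(fc))
    return fc


def polygons_from_geojson(source: str | Path | dict) -> list[FieldPolygon]:
    if not isinstance(source, dict):
        source = json.loads(Path(source).read_text())
    out = []
    for feat in source["features"]:
        props = feat["properties"]
        out.append(
            FieldPolygon(
                polygon_id=int(props["polygon_id"]),
                geometry=shapely.geometry.shape(feat["geometry"]),
                area=float(props["area"]),
                perimeter=float(props["perimeter"]),
                roundness=float(props["roundness"]),
                is_edge=bool(props["is_edge"]),
            )
        )
    return out


__all__ = [
    "FieldPolygon",
    "ZonalRecord",
    "DuplicatePointError",
    "InvalidPolygonError",
    "thiessen_polygons",
    "shape_metrics",
    "filter_polygons",
    "zonal_mean",
    "zonal_means",
    "polygons_to_geojson",
    "polygons_from_geojson",
]
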