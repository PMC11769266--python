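"""Vegetation indices, color-space indices and red-edge wavelengths.

The registry holds every index computed by the analysis: 26 core vegetation /
color-space entries plus a text-named extension set (NDVI, NDRE, GNDVI, WDRVI,
TrVI, SAT, INT, REP, REIP).  All formulas are frozen in ``docs/FORMULAS.md``
with their canonical literature sources.

Conventions
-----------
* Inputs are surface reflectances in ``[0, 1]`` (scalar or numpy array).
* Any nodata (NaN) band, and any zero denominator, yields NaN — never an
  exception and never ``inf`` — so downstream zonal means stay finite.
* HUE is in degrees ``[0, 360)``; REP/REIP are wavelengths in nm, clamped to
  ``[690, 750]``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable

import numpy as np

#: Band centers (nm) of the 5-band sensor: midpoints of the passbands
#: blue 459-491, green 546.5-573.5, red 661-675, red-edge 711-723,
#: NIR 813.5-870.5.
BAND_CENTERS = {
    "blue": 475.0,
    "green": 560.0,
    "red": 668.0,
    "rededge": 717.0,
    "nir": 842.0,
}

#: Weighting coefficient of the wide dynamic range vegetation index.
WDRVI_ALPHA = 0.2


class UnknownIndexError(KeyError):
    """Requested acronym is not in the registry."""


@dataclass(frozen=True)
class BandVector:
    """Reflectance of the five bands at one pixel (or co-registered arrays)."""

    blue: float | np.ndarray = np.nan
    green: float | np.ndarray = np.nan
    red: float | np.ndarray = np.nan
    rededge: float | np.ndarray = np.nan
    nir: float | np.ndarray = np.nan


@dataclass(frozen=True)
class IndexDefinition:
    acronym: str
    full_name: str
    category: str  # "VI" | "CSI" | "WV"
    source: str  # "table2" | "text-named"
    func: Callable[..., np.ndarray]


def _div(num, den):
    """Elementwise num/den with zero denominators mapped to NaN."""
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(den == 0, np.nan, num / den)
    return out


def _sqrt(x):
    x = np.asarray(x, dtype=float)
    with np.errstate(invalid="ignore"):
        return np.where(x < 0, np.nan, np.sqrt(np.clip(x, 0, None)))


# ---------------------------------------------------------------------------
# Core formulas (see docs/FORMULAS.md for derivations and sources)
# ---------------------------------------------------------------------------

def _evi(b, g, r, re, n):
    return _div(2.5 * (n - r), n + 6.0 * r - 7.5 * b + 1.0)


def _savi(b, g, r, re, n):
    return _div(1.5 * (n - r), n + r + 0.5)


def _bgi(b, g, r, re, n):
    return _div(b, g)


def _tvi(b, g, r, re, n):
    return 0.5 * (120.0 * (np.asarray(n, float) - g) - 200.0 * (np.asarray(r, float) - g))


def _mcari(b, g, r, re, n):
    return ((re - r) - 0.2 * (re - g)) * _div(re, r)


def _crei(b, g, r, re, n):
    return _div(n, re) - 1.0


def _ppr(b, g, r, re, n):
    return _div(g - b, g + b)


def _gci(b, g, r, re, n):
    return _div(n, g) - 1.0


def _gndre(b, g, r, re, n):
    return _div(re - g, re + g)


def _ari(b, g, r, re, n):
    return _div(1.0, g) - _div(1.0, r)


def _ndre(b, g, r, re, n):
    return _div(n - re, n + re)


def _ndvi(b, g, r, re, n):
    return _div(n - r, n + r)


def _ccci(b, g, r, re, n):
    return _div(_ndre(b, g, r, re, n), _ndvi(b, g, r, re, n))


def _ndvire(b, g, r, re, n):
    return _div(re - r, re + r)


def _mcci(b, g, r, re, n):
    return _ndvire(b, g, r, re, n) - _gndre(b, g, r, re, n)


def _sr(b, g, r, re, n):
    return _div(n, r)


def _nppr(b, g, r, re, n):
    return _div(g, b + r)


def _gari(b, g, r, re, n):
    gbr = np.asarray(g, float) - (np.asarray(b, float) - np.asarray(r, float))
    return _div(n - gbr, n + gbr)


def _npci(b, g, r, re, n):
    return _div(r - b, r + b)


def _varig(b, g, r, re, n):
    return _div(g - r, g + r - b)


def _evire(b, g, r, re, n):
    return _div(2.5 * (re - r), re + 6.0 * r - 7.5 * b + 1.0)


def _savire(b, g, r, re, n):
    return _div(1.5 * (re - r), re + r + 0.5)


def _sipi(b, g, r, re, n):
    return _div(n - b, n - r)


def _mresr(b, g, r, re, n):
    return _div(n - b, re - b)


def _rri(b, g, r, re, n):
    return _div(re, r)


def _mcari2(b, g, r, re, n):
    return ((n - re) - 0.2 * (n - g)) * _div(n, re)


def _tgi(b, g, r, re, n):
    return -0.5 * (190.0 * (np.asarray(r, float) - g) - 120.0 * (np.asarray(r, float) - b))


def _gndvi(b, g, r, re, n):
    return _div(n - g, n + g)


def _wdrvi(b, g, r, re, n):
    return _div(WDRVI_ALPHA * np.asarray(n, float) - r, WDRVI_ALPHA * np.asarray(n, float) + r)


def _trvi(b, g, r, re, n):
    return _sqrt(_ndvi(b, g, r, re, n) + 0.5)


# -- HSI color space --------------------------------------------------------

def hsi_transform(bands: BandVector) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Hue (degrees), saturation and intensity from RGB reflectance.

    Hue follows the arccos form
    ``theta = arccos(0.5 * ((R-G) + (R-B)) / sqrt((R-G)^2 + (R-B)(G-B)))``
    reflected to ``360 - theta`` when ``B > G`` (the arccos alone cannot
    exceed 180 degrees; the reflection is the standard HSI completion).
    ``R = G = B`` is the achromatic axis: hue and saturation are defined as 0.
    All-zero RGB yields NaN everywhere.
    """
    r = np.asarray(bands.red, dtype=float)
    g = np.asarray(bands.green, dtype=float)
    b = np.asarray(bands.blue, dtype=float)

    total = r + g + b
    intensity = total / 3.0
    saturation = 1.0 - _div(3.0 * np.minimum(np.minimum(r, g), b), total)

    num = 0.5 * ((r - g) + (r - b))
    den2 = (r - g) ** 2 + (r - b) * (g - b)  # = a^2 + ab + b^2 >= 0
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(den2 > 0, num / np.sqrt(np.where(den2 > 0, den2, 1.0)), np.nan)
        theta = np.degrees(np.arccos(np.clip(ratio, -1.0, 1.0)))
    hue = np.where(b > g, 360.0 - theta, theta)
    hue = np.where(hue == 360.0, 0.0, hue)

    achromatic = (den2 == 0) & (total > 0)
    hue = np.where(achromatic, 0.0, hue)
    saturation = np.where(achromatic, 0.0, saturation)

    allzero = total == 0
    hue = np.where(allzero, np.nan, hue)
    saturation = np.where(allzero, np.nan, saturation)
    intensity = np.where(allzero, np.nan, intensity)

    nodata = ~(np.isfinite(r) & np.isfinite(g) & np.isfinite(b))
    hue = np.where(nodata, np.nan, hue)
    saturation = np.where(nodata, np.nan, saturation)
    intensity = np.where(nodata, np.nan, intensity)
    return hue, saturation, intensity


def _hue(b, g, r, re, n):
    return hsi_transform(BandVector(blue=b, green=g, red=r))[0]


def _sat(b, g, r, re, n):
    return hsi_transform(BandVector(blue=b, green=g, red=r))[1]


def _int(b, g, r, re, n):
    return hsi_transform(BandVector(blue=b, green=g, red=r))[2]


# -- Red-edge wavelengths ---------------------------------------------------

_REP_CLAMP = (690.0, 750.0)


def _interp_at(lam, lam0, v0, lam1, v1):
    """Linear interpolation of reflectance at wavelength lam between two bands."""
    t = (lam - lam0) / (lam1 - lam0)
    return v0 + t * (np.asarray(v1, float) - v0)


def red_edge_position(bands: BandVector) -> np.ndarray:
    """Red-edge position (nm) by 4-band linear interpolation (Guyot-Baret form).

    ``REP = 700 + 40 * (R_infl - R700) / (R740 - R700)`` with
    ``R_infl = (Red + NIR) / 2`` and R700/R740 linearly interpolated from the
    red (668 nm), red-edge (717 nm) and NIR (842 nm) band centers.  A flat
    spectrum (``R740 == R700``) is degenerate and yields NaN.  The result is
    clamped to [690, 750] nm.
    """
    r = np.asarray(bands.red, dtype=float)
    re = np.asarray(bands.rededge, dtype=float)
    n = np.asarray(bands.nir, dtype=float)
    r700 = _interp_at(700.0, BAND_CENTERS["red"], r, BAND_CENTERS["rededge"], re)
    r740 = _interp_at(740.0, BAND_CENTERS["rededge"], re, BAND_CENTERS["nir"], n)
    r_infl = 0.5 * (r + n)
    rep = 700.0 + 40.0 * _div(r_infl - r700, r740 - r700)
    return np.clip(rep, *_REP_CLAMP)


def red_edge_inflection_point(bands: BandVector) -> np.ndarray:
    """Red-edge inflection point (nm): where the piecewise-linear spectrum
    through the red (668 nm), red-edge (717 nm) and NIR (842 nm) band centers
    crosses the half-amplitude level ``(Red + NIR) / 2``.

    This is the documented alternative inflection estimate to
    :func:`red_edge_position`; both are clamped to [690, 750] nm and a flat
    spectrum yields NaN.
    """
    r = np.asarray(bands.red, dtype=float)
    re = np.asarray(bands.rededge, dtype=float)
    n = np.asarray(bands.nir, dtype=float)
    target = 0.5 * (r + n)

    lam_r, lam_re, lam_n = (
        BAND_CENTERS["red"],
        BAND_CENTERS["rededge"],
        BAND_CENTERS["nir"],
    )
    # Crossing within red->rededge segment when the red-edge band already
    # reaches the target; otherwise within rededge->NIR.
    lam1 = lam_r + (lam_re - lam_r) * _div(target - r, re - r)
    lam2 = lam_re + (lam_n - lam_re) * _div(target - re, n - re)
    in_first = re >= target
    reip = np.where(in_first, lam1, lam2)
    flat = (n == r) & (re == r)
    reip = np.where(flat, np.nan, reip)
    return np.clip(reip, *_REP_CLAMP)


def _rep(b, g, r, re, n):
    return red_edge_position(BandVector(red=r, rededge=re, nir=n))


def _reip(b, g, r, re, n):
    return red_edge_inflection_point(BandVector(red=r, rededge=re, nir=n))


# ---------------------------------------------------------------------------
# Registry
# ---------------------------------------------------------------------------

def _defs() -> list[IndexDefinition]:
    t2 = [
        ("EVI", "Enhanced Vegetation Index", "VI", _evi),
        ("SAVI", "Soil-Adjusted Vegetation Index", "VI", _savi),
        ("BGI", "Blue Green Pigment Index", "VI", _bgi),
        ("TVI", "Triangular Vegetation Index", "VI", _tvi),
        ("MCARI", "Modified Chlorophyll Absorption in Reflectance Index (red)", "VI", _mcari),
        ("CREI", "Chlorophyll Red-Edge Index", "VI", _crei),
        ("PPR", "Plant Pigment Ratio", "VI", _ppr),
        ("GCI", "Green Chlorophyll Index", "VI", _gci),
        ("GNDRE", "Green Normalized Difference Red Edge Index", "VI", _gndre),
        ("ARI", "Anthocyanin Reflectance Index", "VI", _ari),
        ("CCCI", "Canopy Chlorophyll Content Index", "VI", _ccci),
        ("MCCI", "Modified Chlorophyll Content Index", "VI", _mcci),
        ("SR", "Simple Ratio", "VI", _sr),
        ("NPPR", "Normalized Plant Pigment Ratio", "VI", _nppr),
        ("GARI", "Green Atmospherically Resistant Vegetation Index", "VI", _gari),
        ("NPCI", "Normalized Pigment Chlorophyll Index", "VI", _npci),
        ("VARIg", "Visible Atmospherically Resistant Index Green", "VI", _varig),
        ("EVIre", "Enhanced Vegetation Index red-edge", "VI", _evire),
        ("SAVIre", "Soil-Adjusted Vegetation Index red-edge", "VI", _savire),
        ("SIPI", "Structure Insensitive Pigment Index", "VI", _sipi),
        ("MRESR", "Modified Red Edge Simple Ratio", "VI", _mresr),
        ("RRI", "Red Edge Ratio Index", "VI", _rri),
        ("NDVIre", "Normalized Difference Vegetation Index Red Edge", "VI", _ndvire),
        ("MCARI2", "Modified Chlorophyll Absorption in Reflectance Index (red-edge)", "VI", _mcari2),
        ("TGI", "Triangular Greenness Index", "VI", _tgi),
        ("HUE", "Hue", "CSI", _hue),
    ]
    extra = [
        ("NDVI", "Normalized Difference Vegetation Index", "VI", _ndvi),
        ("NDRE", "Normalized Difference Red Edge Index", "VI", _ndre),
        ("GNDVI", "Green Normalized Difference Vegetation Index", "VI", _gndvi),
        ("WDRVI", "Wide Dynamic Range Vegetation Index", "VI", _wdrvi),
        ("TrVI", "Transformed Vegetation Index", "VI", _trvi),
        ("SAT", "Saturation", "CSI", _sat),
        ("INT", "Intensity", "CSI", _int),
        ("REP", "Red Edge Position", "WV", _rep),
        ("REIP", "Red Edge Inflection Point", "WV", _reip),
    ]
    out = [
        IndexDefinition(a, name, cat, "table2", f) for a, name, cat, f in t2
    ] + [
        IndexDefinition(a, name, cat, "text-named", f) for a, name, cat, f in extra
    ]
    return out


_REGISTRY: dict[str, IndexDefinition] = {d.acronym: d for d in _defs()}

#: Normalized-difference family: values lie in [-1, 1] for any valid bands.
NORMALIZED_DIFFERENCE_INDICES = (
    "GNDRE", "NDVIre", "NDVI", "NDRE", "GNDVI", "PPR", "NPCI",
)

#: Ratio-form indices: invariant to multiplying all bands by c > 0.
SCALE_INVARIANT_INDICES = (
    "SR", "RRI", "BGI", "GCI", "CREI", "CCCI",
) + NORMALIZED_DIFFERENCE_INDICES


def list_indices() -> list[IndexDefinition]:
    """All registered index definitions, core set first."""
    return list(_REGISTRY.values())


def index_names(source: str | None = None) -> list[str]:
    return [d.acronym for d in _REGISTRY.values() if source is None or d.source == source]


def compute_index(acronym: str, bands: BandVector) -> np.ndarray:
    """Evaluate one registered index on a band vector (scalar or arrays).

    Nodata (NaN) in any band used by the formula, and zero denominators,
    propagate to NaN.
    """
    try:
        definition = _REGISTRY[acronym]
    except KeyError:
        raise UnknownIndexError(
            f"unknown index {acronym!r}; known: {sorted(_REGISTRY)}"
        ) from None
    return definition.func(bands.blue, bands.green, bands.red, bands.rededge, bands.nir)


def compute_indices(bands: BandVector, acronyms: Iterable[str] | None = None) -> dict[str, np.ndarray]:
    """Evaluate several (default: all) indices on the same band vector."""
    names = list(acronyms) if acronyms is not None else list(_REGISTRY)
    return {a: compute_index(a, bands) for a in names}


__all__ = [
    "BAND_CENTERS",
    "WDRVI_ALPHA",
    "BandVector",
    "IndexDefinition",
    "UnknownIndexError",
    "list_indices",
    "index_names",
    "compute_index",
    "compute_indices",
    "hsi_transform",
    "red_edge_position",
    "red_edge_inflection_point",
    "NORMALIZED_DIFFERENCE_INDICES",
    "SCALE_INVARIANT_INDICES",
]
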