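"""Independent brute-force oracles, written formula-by-formula before the
registry build and kept free of any canopy_yield.spectral internals.

Each index is coded directly from its frozen algebraic form using scalar
``math`` operations; the Horn stencil and zonal-mean oracles enumerate
pixels one by one.
"""

from __future__ import annotations

import math

import numpy as np

NAN = float("nan")


def _d(num: float, den: float) -> float:
    return NAN if den == 0 else num / den


def index_oracle(acronym: str, b: float, g: float, r: float, re: float, n: float) -> float:
    """Scalar evaluation of one index; NaN for zero denominators."""
    if acronym == "EVI":
        return _d(2.5 * (n - r), n + 6 * r - 7.5 * b + 1)
    if acronym == "SAVI":
        return _d((1 + 0.5) * (n - r), n + r + 0.5)
    if acronym == "BGI":
        return _d(b, g)
    if acronym == "TVI":
        return 0.5 * (120 * (n - g) - 200 * (r - g))
    if acronym == "MCARI":
        return ((re - r) - 0.2 * (re - g)) * _d(re, r)
    if acronym == "CREI":
        return _d(n, re) - 1
    if acronym == "PPR":
        return _d(g - b, g + b)
    if acronym == "GCI":
        return _d(n, g) - 1
    if acronym == "GNDRE":
        return _d(re - g, re + g)
    if acronym == "ARI":
        return _d(1, g) - _d(1, r)
    if acronym == "CCCI":
        ndre = _d(n - re, n + re)
        ndvi = _d(n - r, n + r)
        return _d(ndre, ndvi) if not (math.isnan(ndre) or math.isnan(ndvi)) else NAN
    if acronym == "MCCI":
        return _d(re - r, re + r) - _d(re - g, re + g)
    if acronym == "SR":
        return _d(n, r)
    if acronym == "NPPR":
        return _d(g, b + r)
    if acronym == "GARI":
        gbr = g - (b - r)
        return _d(n - gbr, n + gbr)
    if acronym == "NPCI":
        return _d(r - b, r + b)
    if acronym == "VARIg":
        return _d(g - r, g + r - b)
    if acronym == "EVIre":
        return _d(2.5 * (re - r), re + 6 * r - 7.5 * b + 1)
    if acronym == "SAVIre":
        return _d((1 + 0.5) * (re - r), re + r + 0.5)
    if acronym == "SIPI":
        return _d(n - b, n - r)
    if acronym == "MRESR":
        return _d(n - b, re - b)
    if acronym == "RRI":
        return _d(re, r)
    if acronym == "NDVIre":
        return _d(re - r, re + r)
    if acronym == "MCARI2":
        return ((n - re) - 0.2 * (n - g)) * _d(n, re)
    if acronym == "TGI":
        return -0.5 * (190 * (r - g) - 120 * (r - b))
    if acronym == "HUE":
        return hsi_oracle(r, g, b)[0]
    if acronym == "NDVI":
        return _d(n - r, n + r)
    if acronym == "NDRE":
        return _d(n - re, n + re)
    if acronym == "GNDVI":
        return _d(n - g, n + g)
    if acronym == "WDRVI":
        return _d(0.2 * n - r, 0.2 * n + r)
    if acronym == "TrVI":
        ndvi = _d(n - r, n + r)
        if math.isnan(ndvi) or ndvi + 0.5 < 0:
            return NAN
        return math.sqrt(ndvi + 0.5)
    if acronym == "SAT":
        return hsi_oracle(r, g, b)[1]
    if acronym == "INT":
        return hsi_oracle(r, g, b)[2]
    if acronym == "REP":
        return rep_oracle(r, re, n)
    if acronym == "REIP":
        return reip_oracle(r, re, n)
    raise KeyError(acronym)


def hsi_oracle(r: float, g: float, b: float) -> tuple[float, float, float]:
    total = r + g + b
    if total == 0:
        return NAN, NAN, NAN
    intensity = total / 3
    saturation = 1 - 3 * min(r, g, b) / total
    den2 = (r - g) ** 2 + (r - b) * (g - b)
    if den2 == 0:  # achromatic
        return 0.0, 0.0, intensity
    theta = math.degrees(math.acos(max(-1.0, min(1.0, 0.5 * ((r - g) + (r - b)) / math.sqrt(den2)))))
    hue = 360 - theta if b > g else theta
    if hue == 360:
        hue = 0.0
    return hue, saturation, intensity


# Band centers of the 5-band sensor (nm), re-derived from the passbands.
_LR, _LE, _LN = 668.0, 717.0, 842.0


def rep_oracle(r: float, re: float, n: float) -> float:
    r700 = r + (700.0 - _LR) / (_LE - _LR) * (re - r)
    r740 = re + (740.0 - _LE) / (_LN - _LE) * (n - re)
    if r740 - r700 == 0:
        return NAN
    rep = 700.0 + 40.0 * ((r + n) / 2.0 - r700) / (r740 - r700)
    return min(750.0, max(690.0, rep))


def reip_oracle(r: float, re: float, n: float) -> float:
    target = (r + n) / 2.0
    if re == r and n == r:
        return NAN
    if re >= target:
        if re - r == 0:
            return NAN
        lam = _LR + (_LE - _LR) * (target - r) / (re - r)
    else:
        if n - re == 0:
            return NAN
        lam = _LE + (_LN - _LE) * (target - re) / (n - re)
    return min(750.0, max(690.0, lam))


def horn_slope_oracle(dem: np.ndarray, pixel_size: float) -> np.ndarray:
    """Direct per-pixel Horn 3x3 stencil with edge replication."""
    nr, nc = dem.shape
    out = np.zeros_like(dem, dtype=float)
    for i in range(nr):
        for j in range(nc):
            def z(ii, jj):
                return dem[min(max(ii, 0), nr - 1), min(max(jj, 0), nc - 1)]

            gx = (
                (z(i - 1, j + 1) + 2 * z(i, j + 1) + z(i + 1, j + 1))
                - (z(i - 1, j - 1) + 2 * z(i, j - 1) + z(i + 1, j - 1))
            ) / (8 * pixel_size)
            gy = (
                (z(i + 1, j - 1) + 2 * z(i + 1, j) + z(i + 1, j + 1))
                - (z(i - 1, j - 1) + 2 * z(i - 1, j) + z(i - 1, j + 1))
            ) / (8 * pixel_size)
            out[i, j] = math.degrees(math.atan(math.hypot(gx, gy)))
    return out


def zonal_mean_oracle(values: np.ndarray, grid, polygon) -> tuple[float, int]:
    """O(pixels) point-in-polygon enumeration of one zone's mean."""
    from shapely.geometry import Point

    total, count = 0.0, 0
    for i in range(grid.n_rows):
        for j in range(grid.n_cols):
            x = grid.origin_x + (j + 0.5) * grid.pixel_size
            y = grid.origin_y - (i + 0.5) * grid.pixel_size
            if polygon.contains(Point(x, y)) and np.isfinite(values[i, j]):
                total += values[i, j]
                count += 1
    return (total / count if count else NAN), count


def otsu_oracle(values: np.ndarray, nbins: int = 256) -> float:
    """Exhaustive scan of all candidate thresholds maximizing the
    between-class variance, coded from the definition."""
    v = np.asarray(values, float).ravel()
    v = v[np.isfinite(v)]
    hist, edges = np.histogram(v, bins=nbins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    best, best_var = centers[0], -1.0
    n = hist.sum()
    for k in range(nbins):
        w0 = hist[: k + 1].sum() / n
        w1 = 1 - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (hist[: k + 1] * centers[: k + 1]).sum() / (hist[: k + 1].sum())
        mu1 = (hist[k + 1 :] * centers[k + 1 :]).sum() / max(hist[k + 1 :].sum(), 1)
        var = w0 * w1 * (mu0 - mu1) ** 2
        if var > best_var:
            best, best_var = centers[k], var
    return float(best)
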