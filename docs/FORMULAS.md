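# Index formula ledger

Frozen algebraic definitions of every registry entry, re-derived from the
canonical literature source of each index.  Symbols: `B, G, R, RE, N` are the
blue, green, red, red-edge and NIR surface reflectances in [0, 1].  Any zero
denominator, and any nodata input band, yields nodata (NaN).

## Core set

| Acronym | Formula | Canonical source |
|---|---|---|
| EVI | `2.5 (N − R) / (N + 6R − 7.5B + 1)` | Huete et al. 2002 |
| SAVI | `1.5 (N − R) / (N + R + 0.5)` | Huete 1988 (L = 0.5) |
| BGI | `B / G` | Zarco-Tejada et al. 2005 |
| TVI | `0.5 [120 (N − G) − 200 (R − G)]` | Broge & Leblanc 2001 |
| MCARI | `[(RE − R) − 0.2 (RE − G)] (RE / R)` | Daughtry et al. 2000 |
| CREI | `N / RE − 1` | Gitelson et al. 2003 (red-edge chlorophyll index) |
| PPR | `(G − B) / (G + B)` | Metternicht 2003 |
| GCI | `N / G − 1` | Gitelson et al. 2003 (green chlorophyll index) |
| GNDRE | `(RE − G) / (RE + G)` | green/red-edge normalized difference |
| ARI | `1/G − 1/R` | Gitelson et al. 2001 |
| CCCI | `NDRE / NDVI` = `[(N − RE)/(N + RE)] / [(N − R)/(N + R)]` | Barnes et al. 2000 |
| MCCI | `(RE − R)/(RE + R) − (RE − G)/(RE + G)` = NDVIre − GNDRE | difference of the two red-edge normalized differences |
| SR | `N / R` | Jordan 1969 |
| NPPR | `G / (B + R)` | plant pigment ratio, normalized form |
| GARI | `[N − (G − (B − R))] / [N + (G − (B − R))]` | Gitelson et al. 1996 |
| NPCI | `(R − B) / (R + B)` | Peñuelas et al. 1994 |
| VARIg | `(G − R) / (G + R − B)` | Gitelson et al. 2002 |
| EVIre | `2.5 (RE − R) / (RE + 6R − 7.5B + 1)` | EVI with the red-edge band substituted for NIR |
| SAVIre | `1.5 (RE − R) / (RE + R + 0.5)` | SAVI with the red-edge band substituted for NIR |
| SIPI | `(N − B) / (N − R)` | Peñuelas et al. 1995 |
| MRESR | `(N − B) / (RE − B)` | Sims & Gamon 2002 (mND705 ratio family) |
| RRI | `RE / R` | red-edge simple ratio |
| NDVIre | `(RE − R) / (RE + R)` | Gitelson & Merzlyak 1994 |
| MCARI2 | `[(N − RE) − 0.2 (N − G)] (N / RE)` | Wu et al. 2008 (red-edge MCARI) |
| TGI | `−0.5 [190 (R − G) − 120 (R − B)]` | Hunt et al. 2013 |
| HUE | `arccos{0.5 [(R−G) + (R−B)] / sqrt[(R−G)² + (R−B)(G−B)]}` in degrees, reflected to `360° − θ` when `B > G`; 0 on the achromatic axis | standard RGB→HSI conversion |

Notes:

* The denominator of HUE satisfies `(R−G)² + (R−B)(G−B) = a² + ab + b²` with
  `a = R−G`, `b = G−B`, which is non-negative and vanishes only for
  `R = G = B`; the argument of `arccos` is therefore always in [−1, 1].
* MCCI is an exact linear combination of NDVIre and GNDRE; the collinearity
  screen flags all three together, by design.

## Extension set

| Acronym | Formula | Canonical source |
|---|---|---|
| NDVI | `(N − R) / (N + R)` | Rouse et al. 1974 |
| NDRE | `(N − RE) / (N + RE)` | Barnes et al. 2000 |
| GNDVI | `(N − G) / (N + G)` | Gitelson et al. 1996 |
| WDRVI | `(0.2 N − R) / (0.2 N + R)` | Gitelson 2004, α = 0.2 |
| TrVI | `sqrt(NDVI + 0.5)` | Rouse et al. 1974 (transformed VI) |
| SAT | `1 − 3 min(R, G, B) / (R + G + B)` | standard HSI saturation |
| INT | `(R + G + B) / 3` | standard HSI intensity |
| REP | `700 + 40 (R_i − R700) / (R740 − R700)` with `R_i = (R + N)/2`; R700, R740 linearly interpolated from the band centers 668 / 717 / 842 nm; clamped to [690, 750] nm | Guyot & Baret 1988, adapted to the 5-band sensor |
| REIP | wavelength where the piecewise-linear spectrum through the 668 / 717 / 842 nm band centers crosses `(R + N)/2`; clamped to [690, 750] nm | half-amplitude inflection estimate |

Band centers are the midpoints of the sensor passbands: blue 475 nm, green
560 nm, red 668 nm, red-edge 717 nm, NIR 842 nm.
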