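# canopy-yield

Field-scale corn (*Zea mays* L.) yield prediction from drone multispectral
imagery, gridded soil properties and terrain — a tested, reusable
implementation of the full analysis chain used in precision-agriculture
yield studies, for agronomists, remote-sensing researchers and crop
consultants.

A combine's yield monitor produces thousands of georeferenced point yield
records; a 5-band multispectral sensor (blue, green, red, red-edge, NIR)
produces reflectance rasters at several vegetative growth stages; gridded
soil databases provide sand/silt/clay/OM/BD/AWC and a DEM provides slope.
The package turns these into one modeling table and compares four
regressors:

1. **Bare-ground masking** — soil pixels are removed where
   NDVIre = (RE − R)/(RE + R) falls below a per-flight threshold
   (analyst-supplied or Otsu's automatic 256-bin threshold).
2. **Thiessen (Voronoi) polygons** — each yield point gets its cell of the
   field, filtered by area, roundness P²/(4πA) and an edge flag.
3. **Zonal features** — per-polygon means of the masked bands, soil
   properties and slope; 35 vegetation / color-space / wavelength indices
   (GNDRE, TGI, HUE, NDVIre, REP, …) computed from the zonal band means.
4. **Models** — multiple linear regression (OLS), random forest, gradient
   boosting and XGBoost, evaluated on a seeded 80:20 split by
   R² = 1 − SSres/SStot and RMSE = √(Σ(yᵢ − ŷᵢ)²/n), with iterative
   VIF + importance feature selection, ANOVA + Fisher's-LSD method
   comparison and a paired one-tailed t-test for the soil/slope
   contribution.

Because yield-monitor campaigns are rarely public, the package ships a
seed-reproducible **synthetic field generator**: two interlocking clay soil
bodies, an 8 m-relief ridged DEM, canopy reflectance mixed from healthy /
stressed endmembers by a latent vigor field driven by soil and slope, and
harvester transect points with yield = f(vigor, soil, slope) + noise around
10.19 Mg/ha at 12.1 % CV.  Every generated dataset exposes its truths
(vigor field, canopy masks, generating coefficients) for recovery tests.

## Worked example

```python
from canopy_yield import study

# one seed of the desk-scale scenario: 144 m x 144 m, 1155 yield points,
# ~1020 retained Thiessen polygons, 47 predictors, two growth stages
results = study.run_method_study([1])
print(results[["stage", "method", "rmse", "r2", "rmse_reduced"]])
```

prints (RMSE in Mg/ha; `rmse_reduced` is the same model without the five
soil/slope predictors):

```
    stage method      rmse        r2  rmse_reduced
0      V9    MLR  0.382414  0.901204           NaN
1      V9     RF  0.332582  0.925275      0.371995
2      V9    GBR  0.342734  0.920643      0.378085
3      V9    XGB  0.322143  0.929892      0.356983
4  V14/VT    MLR  0.398656  0.892634           NaN
5  V14/VT     RF  0.341653  0.921143      0.375014
6  V14/VT    GBR  0.333184  0.925004      0.382947
7  V14/VT    XGB  0.323988  0.929087      0.357025
```

Read it as: the tree ensembles beat the linear baseline on this
threshold-interaction scenario (RF 0.33 vs MLR 0.38 Mg/ha at V9), and every
ensemble loses accuracy when soil and slope are withheld (e.g. RF 0.333 →
0.372) — the two qualitative findings the comparison statistics formalize
across seeds.

The same chain is scriptable from the shell:

```sh
canopy-yield simulate --seed 1 --grid-n 120 --stages 2 --out field/
canopy-yield mask --rededge field/V5_rededge.asc --red field/V5_red.asc \
                  --threshold auto --out mask.asc
canopy-yield polygons --points field/yield_points.csv \
                      --bounds 0,-120,120,0 --out polys.geojson
canopy-yield run --seed 1 --grid-n 150 --stages 2 --out run/   # full report
```

Rasters are plain-text ESRI ASCII grids (nodata −9999); polygons and points
are GeoJSON/CSV; reports are JSON plus a MANIFEST declaring every output.

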