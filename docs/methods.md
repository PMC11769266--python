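# Methods

## The analysis

`canopy-yield` implements a production-scale corn yield prediction pipeline
that fuses three data sources on one metric grid:

1. **5-band surface reflectance** (blue, green, red, red-edge, NIR) from a
   multispectral sensor, one co-registered stack per vegetative growth stage
   (V4 through V14/VT);
2. **soil-property rasters** — sand, silt and clay percentages, organic
   matter (OM, %), bulk density (BD, g/cm³) and available water capacity
   (AWC, fraction) — of the kind distributed by gridded soil databases at
   ~30 m resolution, resampled to the analysis grid by nearest neighbor so
   that no new values are invented and the texture closure
   (sand + silt + clay = 100) survives resampling;
3. **harvester yield points** (x, y, yield in Mg/ha) from a combine-mounted
   yield monitor, the ground truth.

The chain is: bare-ground masking → Thiessen polygons → zonal means →
feature table → model comparison.

**Bare-ground masking.** Soil pixels are separated from canopy on the NDVIre
raster, NDVIre = (RE − R)/(RE + R).  Pixels below a threshold are soil; the
threshold is a per-flight analyst value or, by default, Otsu's
between-class-variance maximizer over a 256-bin histogram of the finite
NDVIre values.  Masked-out pixels become *nodata*, not zero reflectance: a
literal zero would silently drag every zonal mean toward the soil line,
whereas nodata makes the zonal stage average vegetation pixels only, which is
the evident intent of masking.

**Thiessen polygons.** Each harvest point receives its Voronoi cell clipped
to the field boundary — the footprint of that yield record.  Cells are
measured (shoelace area, perimeter, roundness) and filtered by area bounds,
a roundness cap and an edge flag.  Roundness is the isoperimetric ratio
P²/(4πA): exactly 1 for a circle, 4/π ≈ 1.273 for a square, larger for less
compact shapes.  No standard circularity definition reproduces a "very
uniform" value near 2.4 for near-square harvester cells, so the definition is
fixed to the isoperimetric ratio and the filter threshold is configuration
(default 3.0; the desk-scale studies use 1.5 for their 4.2 m × 4.0 m cells).

**Zonal statistics.** The pixel-in-zone rule is pixel-center containment
(strict: a center exactly on a shared cell edge belongs to no zone), nodata
ignored, empty zones flagged rather than fatal.  Zonal band means are
computed first and the 35 spectral indices are evaluated on those means —
averaging then index arithmetic — matching standard zonal feature-extraction
practice for polygon-level modeling.

**Spectral features.** The registry holds 26 core indices (EVI … HUE) plus a
text-named extension set (NDVI, NDRE, GNDVI, WDRVI with α = 0.2, TrVI,
saturation, intensity, REP, REIP); every formula is frozen with its canonical
literature source in `FORMULAS.md`.  Zero denominators and nodata bands
propagate NaN rather than raising or producing ±inf.  HUE uses the arccos
form reflected to 360° − θ when B > G (the arccos alone cannot exceed 180°).
REP is the Guyot–Baret 4-band linear interpolation on the sensor's band
centers (668/717/842 nm), REIP the half-amplitude crossing of the
piecewise-linear spectrum; both are clamped to [690, 750] nm and degenerate
(flat) spectra yield nodata.

**Slope.** Horn's 3×3 finite-difference method (the algorithm of the common
GIS slope tool), slope = atan(√(gx² + gy²)) in degrees, edge-replication
padding at the raster border.

**Models.** Four regressors on the polygon feature table: multiple linear
regression (closed-form OLS; rank-deficient designs — which arise by
construction because TVI, TGI, intensity and MCCI are exact linear
combinations of other predictors — fall back to the minimum-norm
pseudo-inverse with a warning), random forest, gradient boosting and
XGBoost.  Default hyperparameters are pinned to the tuned values (RF:
max_depth 21, max_features 11, n_estimators 500; XGB: colsample_bytree 0.9,
gamma 0.30, learning_rate 0.05, max_depth 6, n_estimators 200, subsample
0.7; GBR: learning_rate 0.1, max_depth 5, n_estimators 200, subsample 0.7)
so desk runs skip the grid search; a different map can be supplied per
model.  `n_jobs` is fixed at 1: it is not a statistical hyperparameter and
single-threaded fits keep seeded runs deterministic.  The 80:20 split takes
`round(0.8 n)` training rows (8581 → 6865/1716), seeded and exhaustive.
Accuracy is R² = 1 − SSres/SStot about the test mean, and RMSE.

**Feature selection.** Each round fits the model, evaluates test RMSE, and
drops the worst variance-inflation-factor offender above the cut (default
10) plus every predictor whose importance (impurity/gain share for trees,
normalized |standardized coefficient| for MLR) falls below the floor
(default 0.005), ties broken alphabetically.  The loop stops when nothing is
droppable or test RMSE rises more than 1 % above the best seen; the
finalized set is the fewest-predictor iteration within that 1 % band of the
minimum RMSE ("fewest predictors and lowest RMSE").  Selecting on the test
set follows the pipeline's published design but optimistically biases the
reported RMSE; users wanting an unbiased number should hold out a third
split.

**Comparison statistics.** RMSEs are compared across methods by one-way
ANOVA with growth stages as replicates — an interpretation: the replicate
unit is not stated in the source design, and stage-replicates is the
documented assumption — followed, when significant, by Fisher's protected
LSD with a compact letter display ('a' = highest mean).  The soil/slope
contribution is the one-tailed paired t-test that removing {sand, silt,
clay, OM, slope} raises RMSE across the (ensemble method × stage) pairs;
all-zero differences return p = 0.5 by convention, zero-variance nonzero
differences 0 or 1 by sign.

## The synthetic-field generator

No field campaign data ship with the package, so a seed-reproducible
generator provides fields with the statistical structure the analysis
assumes.  What it emulates, and the defaults:

* **Soil**: two smoothly interlocking soil bodies (a heavy smectitic clay at
  ~55 % clay and a fine-silty carbonatic clay at ~45 %) from a thresholded
  smoothed Gaussian random field (autocorrelation length 18 m), plus
  smoothed per-property noise; sand/silt/clay renormalized to sum exactly
  100 at every pixel.  OM, BD and AWC track the same zones.
* **Terrain**: a gentle ridge along the NW–SE diagonal falling toward the
  NE and SW corners plus smooth noise, rescaled so max − min equals the
  relief target exactly (default 8 m).  Slope is derived with the package's
  own Horn operator.
* **Latent vigor**: standardize(w_soil · z(soil score) + w_slope · z(−slope)
  + smooth noise), where the soil score is the fixed blend 0.5 z(OM) +
  0.3 z(AWC) + 0.2 z(clay).  Defaults w_soil = 1.0, w_slope = 0.7, noise sd
  0.6.  Setting a weight to zero severs that pathway in both vigor and
  yield, which is what makes the null-calibration study meaningful.
* **Reflectance**: canopy pixels mix a healthy and a stressed canopy
  endmember by a logistic function of vigor; bare pixels carry a soil
  endmember (all three spectra live in `data/endmembers.toml`).  Canopy
  grows outward from planting rows (every third pixel row) by
  distance-transform thresholding to hit the per-stage cover fraction
  (defaults 0.15 → 0.85 over V4 → V14/VT).  Additive band noise sd 0.004,
  clipped to [0, 1].  The endmember NDVIre values (soil ≈ 0.11, canopy
  0.42–0.80) make the NDVIre histogram bimodal so that automatic
  thresholding recovers the stored truth mask to ≥ 99 %.
* **Yield**: points on parallel east–west transects (spacing 4.2 m, point
  spacing 4.0 m → ~16.8 m² cells, matching a six-row harvester footprint);
  yield = mean · (1 + CV · standardized response), floored at 1.5 Mg/ha.
  Defaults: mean 10.19 Mg/ha, CV 12.11 %.  The linear response is
  0.8 z(vigor) + 0.35 w_soil z(soil) + 0.35 w_slope z(−slope) + 0.35 ε; the
  threshold-interaction variant adds 0.5 √(w_soil w_slope) · z(clay)z(−slope)
  and a 0.6 · max(z(vigor) − 0.4, 0) hinge, the non-linear structure that
  separates the tree ensembles from the linear baseline.  The per-point
  design columns and effective coefficients (Mg/ha per unit z-score) are
  stored so recovery tests can read them.

What the generator does **not** model — and hence what passing tests do not
show about real data: radiative canopy transfer, weather/thermal time, plant
density, row-direction anisotropy in reflectance, yield-monitor artifacts
(speed/pass delays, moisture), georeferencing error, or spatial
autocorrelation of the yield noise.  Tests on synthetic fields demonstrate
that the pipeline's machinery is correct and that its comparative findings
hold when the assumed structure is present, not that a particular RMSE is
attainable in any real field.

## Numerical choices

* Nodata is NaN in memory, −9999 in files (ESRI ASCII grid, plain text).
* Zero denominators → NaN everywhere, so zonal means stay finite.
* Otsu: 256 bins, first maximum on ties (ties occur across empty gap bins;
  any choice in the gap induces the same partition).
* Voronoi cells are matched to generators by containment (the underlying
  library does not preserve input order); multi-part clipped cells keep the
  part containing the generator.
* Grid convention: row-major, origin top-left, pixel value = full square
  footprint, projected metric coordinates; pixel centers at half-pixel
  offsets, which keeps lattice Voronoi edges off pixel centers.
* Split size rounds half up (`floor(ratio·n + 0.5)`), clamped to leave at
  least one row on each side.

## Problem sizes for the shipped studies

The comparison studies run on a 144 m × 144 m field (1 m pixels, ~1150
points, ~1020 retained polygons, two stages at covers 0.5/0.7), chosen as
the smallest scale at which the polygon funnel, zonal statistics and
ensemble fits all behave as at production scale.  The coefficient-recovery
study uses a 300 m × 300 m field (~5180 points).  The method-ranking and
soil-contribution findings are averaged over seeds 1–10; the null
calibration of the inclusion test uses 20 seeds with both effect weights
zero.  Pixel size, grid extent and stage schedule are all configurable.

## Known limitations

* Inputs are assumed co-projected; there is no reprojection, shadow or
  cloud masking, and no shapefile I/O (GeoJSON and ESRI ASCII grid only).
* Per-flight manual mask thresholds are supported but the automatic Otsu
  default cannot reproduce an analyst's unrecorded choices.
* The 62-predictor count quoted for the original campaign cannot be
  reconstructed exactly from the named index set (5 bands + 6 soil + slope
  + 35 indices = 47 predictors here); the registry is extensible where more
  derivations are needed.
* Selection on the test split biases reported RMSE optimistically (see
  above).
* The soil/slope-inclusion test inherits the random split's blindness to
  spatial structure.  Even with both effect weights at zero, soil rasters
  are spatially smooth and the vigor noise is spatially smooth, so within
  any one field realization they carry a small amount of genuine predictive
  information about each other; under a random (non-spatial) 80:20 split
  that information is exploitable, removing the soil/slope columns slightly
  raises test RMSE, and the one-sided paired test rejects more often than
  its nominal level (roughly 0.2–0.3 of seeds at α = 0.05 in repeated null
  runs, rather than ≈ α).  This is a property of random splits over
  autocorrelated fields — the standard remedy is spatial cross-validation,
  which is outside this package's scope — so the null calibration of the
  inclusion test should be read as seed-set-sensitive, and inclusion
  p-values on real fields as anti-conservative.
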