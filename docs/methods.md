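# Methods

## Model

The pipeline estimates mangrove canopy height H from an X-band InSAR DEM.
Its physical premise: over dense, low-relief mangrove canopies the InSAR
scattering phase centre sits near the canopy top and the ground is near sea
level, so the geoid-referenced DEM elevation is approximately canopy-top
height. Residual penetration, temporal change and noise are absorbed by a
single global calibration against spaceborne-lidar RH98 (the waveform
height below which 98 % of returned energy accumulates):

    RH98_hat = (a * sqrt(x) + b)^2,     x = footprint-maximum DEM value.

The square-root transform linearises the saturating relation between the
phase-centre height and canopy-top height and guarantees nonnegative
predictions; the model is fitted as an ordinary weighted least-squares line
on (sqrt(x), sqrt(RH98)) and predictions are squared back. Fitting the
squared form directly by nonlinear least squares is deliberately not done:
the transform-then-line approach is the definition of the estimator, has a
closed-form solution, and is what the fitted coefficients (a = 1.02,
b = 0.33 for the published global model) refer to.

The footprint **maximum** is the predictor (not the mean): RH98 is a
near-top-of-canopy metric and the tallest DEM pixel under the ~25 m
footprint is its closest analogue; mean/min/sd are carried for filtering
and export.

### Category weights

Short canopies dominate any global lidar sample of mangroves by four
orders of magnitude. To keep the fit from ignoring tall stands, RH98 is
split into six categories ([0,10), [10,20), …, [40,50), ≥50 m) and every
observation in category c receives weight

    w_c = 1 / (6 * n_c),

so each category contributes total mass 1/6 and the masses sum to 1. The
weight table is computed on the training split (after the 70/30 split);
with tens of thousands of shots the split leaves every populated category's
count essentially proportional, so the distinction is immaterial in
practice but keeps training and validation strictly disjoint.

### Candidate forms and selection

Four two-parameter forms are fitted by WLS and compared on training
metrics in the original height units: linear y = ax + b, power y = a·x^b
(line on log-log), quadratic y = a·x² + b, and the square-root line above.
Selection is by lowest RMSE, ties broken by lower MAE, then lower |bias|,
then higher Pearson correlation. Forms whose domain excludes the data
(power with zero heights) drop out silently. Two-parameter
parameterisations were chosen so every candidate serialises to the same
(form, a, b) record.

## Filtering

The quality cascade evaluates, in a fixed order, the shot-level L2A fields
(degrade flag = 0, quality flag = 1, 1 ≤ modes < 5, DEM−EGM2008 < 50 m,
Landsat water persistence < 80, |lowest mode − mean sea surface| < 5 m,
2000 < total energy < 25000) and then the footprint-level rules
(0 < max DEM < 60 m, min DEM < 60 m, 0 < RH98 < 60 m, ≥ 3 DEM pixels, and
an sd cap of 1.5 / 2 / 3 m for 3–4 / 5–6 / >6 pixels). The first failing
criterion is recorded, so reject-reason totals plus the kept count always
equal the input count. All comparisons are strict as written.

The outlier pass bins the surviving pairs twice — by RH98 in 2 m intervals
testing the footprint-max DEM, and by DEM in 2 m intervals testing RH98 —
and removes any pair more than 3 sample standard deviations from its bin
mean in either pass. The two passes are marginal, not a joint 2 m × 2 m
binning: joint bins would contain near-constant values and make a 3σ rule
vacuous. Bins with fewer than 3 members are exempt (their σ is unstable).
Note the arithmetic fact that the largest z-score a sample of size n can
contain is (n−1)/√n: a 3σ rule needs ≥ ~11-member bins before it can flag
anything, and much larger bins before a lone wild outlier is flagged
reliably.

## Raster operations

* Datum conversion is pixelwise subtraction of a geoid-undulation raster
  (nearest-resampled to the tile grid when needed); no geoid model is
  evaluated.
* Artifact replacement is **per pixel** on the absolute difference
  |DEM − reference| > 30 m. A whole-tile swap would discard good data;
  the sign is not used because both positive (voids filled with fill
  values) and negative (phase errors) excursions occur.
* Height clipping sets out-of-range pixels (< 0.1 m or > 60 m) to nodata
  rather than clamping: sub-0.1 m pixels are bare ground and > 60 m pixels
  are above the tallest known mangroves — both are invalid as canopy, not
  saturated.
* Water classification is strict: persistence must exceed 0.70. The
  persistence denominator is the number of stack layers in which the pixel
  is valid.
* Rasterisation assigns a pixel to the polygon covering its centre; a
  centre on a shared boundary takes the lowest label (deterministic
  tie-break).
* Nearest-neighbour resampling takes the source pixel containing the
  target pixel centre.
* Percentiles everywhere use linear interpolation between order
  statistics; standard deviations are sample (n−1) with the single-value
  sd defined as 0 (such footprints are rejected by pixel count anyway).

## Post-processing

Extent-mask misclassification (hills, upland forest) creates tiles whose
height tails are artifacts. All tiles with any pixel above 50 m are
flagged; their 99th percentiles are sorted, ranks normalised to [0,1] for
numerical conditioning, a degree-5 polynomial fitted, and the smallest
in-range root of its second derivative at which curvature actually changes
sign is taken as the inflection; the threshold is the polynomial value
there. Tiles with p99 below the threshold have **all** pixels above their
p99 capped at p99 (capping only the single maximum would leave the
second-largest outlier untouched); tiles above it are genuinely tall and
left unchanged. The threshold is always recomputed from the tile
population being processed — 31.02 m is the value the published global
tile population produced, recorded here as a reference point, never a
default.

## Synthetic scenes

The generator emulates the statistical structure the pipeline assumes, not
the sensors' physics. Defaults are the study conditions:

| parameter | default | rationale |
|---|---|---|
| tile size | 100 px (1.2 km at 12 m) | large enough for ~8.5 k mangrove pixels and 500 shots |
| truth field | Gaussian noise smoothed with σ = 10 px, min-max rescaled to 0.5–40 m | smooth positive canopy field within the mangrove range |
| water | random-walk channels, 15 % of pixels | narrow connected waterways, as in deltaic mangrove systems |
| DEM noise | 1 m (Gaussian) | random error of a 12 m X-band InSAR DEM |
| artifacts | 3 disjoint 3×3 patches, +90 m | gross interferometric errors, far above the 30 m rule |
| undulation | 20 m constant | typical geoid-offset magnitude |
| shots | 500; RH98 noise 2 m; jitter 10 m | spaceborne-lidar vertical error and geolocation error magnitudes |
| contamination | 10 % of shots fail exactly one shot-level criterion | makes per-reason accounting exact |
| backscatter | 10 layers; water ≤ −19.5 dB in 90 % of layers, canopy ≥ −18.5 dB | guarantees unambiguous persistence classification |
| ALS CHM | 1 m grid, 12×12 per cell, 0.5 m noise | airborne-lidar validation raster |

Shots are placed on interior pixels whose 5×5 neighbourhood is land (so
the footprint and its coarse extent pixels are guaranteed on-extent) and
locally homogeneous (3×3 sample sd < 1.2 m), emulating the
homogeneous-canopy shots the cascade retains. Contaminated shots fail one
criterion drawn uniformly over the seven shot-level fields; the
footprint-derived criteria (pixel count, sd, DEM ranges) cannot be forced
from the shot record alone and are exercised by the noisy scenes instead.

What the generator does **not** emulate — waveform shape, orbital sampling
geometry, SAR speckle correlation, tides, real geoid spatial structure,
canopy gaps below footprint scale — bounds what passing tests show: they
validate the algorithms' correctness and statistical behaviour under the
stated noise model, not product accuracy on real acquisitions.

### Calibration-recovery sample

The parameter-recovery check draws 10⁵ (DEM, RH98) pairs from the known
square-root model with 0.3 sd Gaussian noise on the √ scale and stratum
sizes following the global-corpus proportions with a 50-point floor per
stratum ([63480, 29684, 5985, 821, 50, 50]). Two deliberate choices:

* **Stratum floor.** At exact global proportions, 10⁵ points leave ~2 in
  the ≥50 m stratum. That stratum still carries weight mass 1/6, so its
  mean error alone (0.3/√2 on the √ scale) contributes ≈ 0.03 sd to the
  slope — no estimator could recover the slope to ±0.02 from such a draw.
  The floor preserves the four-orders-of-magnitude imbalance while keeping
  every stratum estimable.
* **Design-stratum weights.** Weights come from the generating strata, not
  from re-categorising the noisy observations: with noise comparable to
  the √-scale width of the top categories, noise-promoted points dominate
  tiny heavily-weighted strata and bias the slope upward by ≈ +0.06
  (selection on noise at category borders). In the real pipeline
  categories necessarily come from observed heights, where the noise is
  shared between both variables of the pairing rather than injected on the
  regressand alone.

## Numerical choices and degenerate inputs

* All grids are north-up, pixel-is-area, WGS84 geographic; metric pixel
  sizes are expressed in degrees at the scene latitude, and footprint
  distances use a local equirectangular approximation (exact to well below
  1 mm at 25 m scale).
* Footprint membership is centre distance ≤ 12.5 m (inclusive).
* The 70/30 split assigns floor(0.7·n) per category to training; a
  one-member category therefore validates, never trains.
* Empty height categories are excluded from the weight table; asking for
  the weight of an observation in an excluded category is an error, not a
  silent zero.
* `find_inflection_threshold` requires at least poly_order + 2 points and
  raises with diagnostics (the out-of-range roots) when no in-range
  curvature sign change exists, rather than extrapolating.
* Rasters serialise as ESRI ASCII grids with a JSON sidecar for the
  CRS/vertical-datum tags; nodata is an explicit sentinel (−9999).

## Known limitations

* The calibration is global and static; regionally varying penetration
  depth or acquisition-date mismatch appears as residual bias, not as a
  model term.
* Tall-stand behaviour rests on very few calibration shots (the ≥50 m
  category), so the fitted curve above ~45 m is close to an extrapolation.
* The tall-tile mitigation needs a population of flagged tiles
  (≥ 7 for the quintic); a single-scene run skips it.
* The water mask assumes persistently low backscatter; inundated canopy
  with double-bounce enhancement is not modelled.
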