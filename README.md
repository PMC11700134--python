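# mangroveheight

Mangrove canopy height from InSAR elevation, calibrated with spaceborne
lidar.

Over low-relief mangrove forests an X-band InSAR digital elevation model
(DEM) tracks the elevation near the top of the canopy, so — once water and
non-mangrove pixels are removed and the vertical datum is harmonised — the
DEM value itself is a canopy-height proxy. This package implements that
workflow as a tested, reusable pipeline for researchers in forest remote
sensing:

1. **DEM preparation** — ellipsoid → geoid conversion by subtracting an
   undulation grid; replacement of gross interferometric artifacts wherever
   the 12 m DEM departs from a 30 m reference DEM by more than 30 m;
   removal of pixels outside the plausible mangrove range (0.1–60 m).
2. **Masking** — a water mask from a SAR backscatter time stack (pixels at
   or below −19 dB in more than 70 % of layers are water), a mangrove
   extent mask rasterised/resampled to the 12 m grid, and country labels
   from EEZ polygons.
3. **Footprint pairing and filtering** — each ~25 m lidar footprint (GEDI
   RH98, the height below which 98 % of waveform energy accumulates) is
   paired with the zonal statistics (mean, min, max, sd, count) of the DEM
   pixels under it; a fixed-order quality cascade applies the L2A product
   flags plus footprint-level thresholds, and a 2 m-bin 3σ pass removes
   discordant pairs.
4. **Calibration** — the footprint-maximum DEM value x is regressed on
   RH98 with observations weighted so each of six height categories
   ([0,10), …, ≥50 m) carries equal total mass, w_c = 1/(6 n_c). Four
   candidate forms are fitted by weighted least squares and ranked by
   RMSE/MAE/|bias|/correlation; the square-root-linear form

   &nbsp;&nbsp;&nbsp;&nbsp; RH98 = (a·√x + b)²

   is the published global model with a = 1.02, b = 0.33.
5. **Post-processing** — tiles containing pixels above 50 m are screened
   via the inflection point of a 5th-order polynomial fitted to their
   ordered 99th percentiles; artifact-tailed tiles are capped at their p99.
6. **Reporting** — hold-out validation metrics, residuals binned by
   reference height, airborne-lidar CHM aggregation to the map grid, and
   per-country order statistics (p99, median of the 100 tallest pixels).

A synthetic-scene generator (`mangroveheight.synthetic`) produces complete
co-registered inputs — truth field with river channels, noisy DEM with
planted artifacts, reference DEM, backscatter stack, extent/EEZ rasters,
lidar shots with controlled contamination, and a 1 m airborne CHM — so the
entire chain is testable without any satellite download.

## Worked example

```python
import numpy as np
from mangroveheight import SceneConfig, generate_scene, run_pipeline

scene = generate_scene(SceneConfig(seed=1))
result = run_pipeline(scene, seed=3)

print(f"shots kept by the filter cascade: "
      f"{len(result.kept_pairs)}/{len(result.pairs)}")
print(f"selected form: {result.model.form}")
print(f"coefficients:  a={result.model.a_:.3f}  b={result.model.b_:.3f}")
m = result.metrics
print(f"hold-out (n={result.valid_idx.size}): RMSE={m.rmse:.2f} m  "
      f"MAE={m.mae:.2f} m  bias={m.bias:.2f} m  r={m.corr:.3f}")
h = result.height_map.valid_values()
print(f"calibrated map: {h.size} mangrove pixels, "
      f"median {np.median(h):.1f} m, p99 {np.percentile(h, 99):.1f} m")
```

prints

```
shots kept by the filter cascade: 346/500
selected form: linear
coefficients:  a=1.101  b=-3.531
hold-out (n=106): RMSE=2.26 m  MAE=1.84 m  bias=-0.32 m  r=0.940
calibrated map: 8092 mangrove pixels, median 25.8 m, p99 39.0 m
```

Under the default study conditions (2 m vertical shot noise, 10 m
geolocation jitter, 10 % contaminated shots, 1 m DEM noise) the cascade
removes the contaminated and heterogeneous shots, the fitted calibration is
close to the 1:1 line — on a scene where the DEM *is* noisy truth, the
best-ranked form may be the plain linear one — and the hold-out RMSE (~2.3 m)
sits at the level expected from the injected noise. On a noiseless scene
the pipeline returns the truth field with RMSE exactly 0.

The same stages are scriptable from a shell via the `mangroveheight`
console command (`simulate`, `prepare-dem`, `mask`, `pair`, `calibrate`,
`apply`, `postprocess`, `validate`); rasters travel as ESRI ASCII grids and
shot/pair tables as CSV.

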