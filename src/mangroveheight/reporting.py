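"""Validation statistics and per-country height summaries.

Covers the three assessment routes: hold-out lidar-shot metrics with
residuals binned by reference height, comparison against airborne-lidar
canopy height models aggregated from 1 m to the map grid, and per-country
order statistics (99th percentile and median of the 100 tallest pixels).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibration import FitMetrics, evaluate_metrics
from .raster import GridTransform, RasterTile, require_coregistered


def residual_bins(predicted, observed, bin_width_m: float = 1.0) -> pd.DataFrame:
    """Residuals (map − reference) binned by reference height.

    Returns per populated bin: lower edge, n, mean and sample-sd of the
    residual.  Bin counts sum to the number of pairs.
    """
    predicted = np.asarray(predicted, dtype=float).ravel()
    observed = np.asarray(observed, dtype=float).ravel()
    resid = predicted - observed
    idx = np.floor(observed / bin_width_m).astype(int)
    rows = []
    for b in np.unique(idx):
        r = resid[idx == b]
        rows.append({"bin_lower_m": b * bin_width_m, "n": r.size,
                     "mean_residual_m": float(r.mean()),
                     "sd_residual_m": float(r.std(ddof=1)) if r.size > 1 else 0.0})
    return pd.DataFrame(rows)


def validation_report(x_valid, y_valid, model,
                      bin_width_m: float = 1.0) -> tuple[FitMetrics, pd.DataFrame]:
    """Hold-out metrics and residual bins for a fitted calibration model.

    ``x_valid`` are footprint-max DEM values, ``y_valid`` the reference
    RH98 heights of the validation split (disjoint from training).
    """
    x_valid = np.asarray(x_valid, dtype=float).ravel()
    if x_valid.size == 0:
        raise ValueError("empty validation set")
    pred = model.predict(x_valid)
    return evaluate_metrics(pred, y_valid), residual_bins(pred, y_valid, bin_width_m)


def aggregate_chm(als_1m: RasterTile, target_transform: GridTransform,
                  target_shape: tuple[int, int],
                  min_coverage: float = 0.5) -> RasterTile:
    """Block-mean aggregation of a fine CHM onto the map grid.

    The fine grid must nest exactly in the target grid (shared origin,
    integer pixel-size ratio).  Cells with less than ``min_coverage`` of
    their fine pixels valid are nodata.
    """
    t, s = target_transform, als_1m.transform
    fx, fy = t.dx / s.dx, t.dy / s.dy
    if (abs(fx - round(fx)) > 1e-6 or abs(fy - round(fy)) > 1e-6
            or abs(s.x0 - t.x0) > 1e-9 or abs(s.y0 - t.y0) > 1e-9):
        raise ValueError("fine grid does not nest in the target grid")
    fx, fy = int(round(fx)), int(round(fy))
    nrow, ncol = target_shape
    need_r, need_c = nrow * fy, ncol * fx
    if als_1m.shape[0] < need_r or als_1m.shape[1] < need_c:
        raise ValueError("fine raster does not cover the target grid")
    vals = als_1m.values[:need_r, :need_c]
    valid = als_1m.valid_mask()[:need_r, :need_c]
    vals = np.where(valid, vals, 0.0).reshape(nrow, fy, ncol, fx)
    cnt = valid.reshape(nrow, fy, ncol, fx).sum(axis=(1, 3))
    total = vals.sum(axis=(1, 3))
    out = np.full(target_shape, als_1m.nodata, dtype=float)
    ok = cnt >= min_coverage * fx * fy
    with np.errstate(invalid="ignore", divide="ignore"):
        out[ok] = total[ok] / cnt[ok]
    return RasterTile(out, target_transform, crs=als_1m.crs,
                      vdatum=als_1m.vdatum, nodata=als_1m.nodata)


@dataclass
class CountryStats:
    country_code: int
    n_pixels: int
    p99_m: float
    median_top100_m: float
    histogram: np.ndarray  # counts per 1 m bin, 0–60 m


def country_stats(height_map: RasterTile, country: RasterTile,
                  hist_max_m: float = 60.0) -> list[CountryStats]:
    """Per-country order statistics of mangrove height.

    For each positive country code with at least one valid height pixel:
    the 99th percentile (linear interpolation) over all its pixels, the
    median of its 100 tallest pixel values (median of all values when fewer
    than 100 exist), and a histogram in 1 m bins.
    """
    require_coregistered(height_map, country)
    valid = height_map.valid_mask()
    codes = country.values
    out = []
    for code in np.unique(codes[valid & (codes > 0)]):
        vals = height_map.values[valid & (codes == code)]
        top = np.sort(vals)[-100:]
        hist, _ = np.histogram(vals, bins=np.arange(0.0, hist_max_m + 1.0, 1.0))
        out.append(CountryStats(country_code=int(code), n_pixels=int(vals.size),
                                p99_m=float(np.percentile(vals, 99.0)),
                                median_top100_m=float(np.median(top)),
                                histogram=hist))
    return out


def country_stats_frame(stats: list[CountryStats]) -> pd.DataFrame:
    return pd.DataFrame([{"country_code": s.country_code, "n_pixels": s.n_pixels,
                          "p99_m": s.p99_m, "median_top100_m": s.median_top100_m}
                         for s in stats])
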