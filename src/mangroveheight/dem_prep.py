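"""Vertical-datum harmonisation, artifact replacement and height clipping.

An InSAR DEM over low-relief mangroves tracks the elevation near the top of
the canopy, so once water and upland pixels are masked out the DEM value is
itself a canopy-height proxy.  Before calibration the 12 m DEM must be
(1) moved from ellipsoidal to geoid (orthometric) heights by subtracting a
geoid-undulation grid, (2) cleansed of gross interferometric artifacts by
comparison with an independent 30 m reference DEM, and (3) restricted to
the physically plausible mangrove height range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .raster import RasterTile, grids_aligned, require_coregistered, resample_nearest


@dataclass(frozen=True)
class DemPrepConfig:
    """Thresholds for DEM cleansing.

    artifact_threshold_m
        Absolute DEM-vs-reference difference above which the reference
        value replaces the DEM value (default 30 m).
    max_height_m, min_height_m
        Plausible mangrove height range; pixels outside become nodata.
        The 0.1 m floor removes bare-ground pixels; 60 m is above the
        tallest known mangrove stands.
    """

    artifact_threshold_m: float = 30.0
    max_height_m: float = 60.0
    min_height_m: float = 0.1

    def __post_init__(self) -> None:
        if not (0 < self.min_height_m < self.max_height_m):
            raise ValueError("require 0 < min_height_m < max_height_m")
        if self.artifact_threshold_m <= 0:
            raise ValueError("artifact_threshold_m must be positive")


def convert_to_geoid(tile: RasterTile, undulation: RasterTile,
                     resample: bool = True) -> RasterTile:
    """Ellipsoidal → orthometric heights: subtract the geoid undulation.

    ``undulation`` is resampled (nearest-neighbour) onto the tile grid when
    grids differ and ``resample`` is true; otherwise a grid mismatch is an
    error.  Nodata pixels are preserved.
    """
    if tile.vdatum != "ellipsoid":
        raise ValueError("input tile must carry ellipsoidal heights")
    if (undulation.shape != tile.shape
            or not grids_aligned(undulation.transform, tile.transform)):
        if not resample:
            raise ValueError("undulation grid mismatch and resampling disabled")
        undulation = resample_nearest(undulation, tile.transform, tile.shape)
    valid = tile.valid_mask() & undulation.valid_mask()
    out = np.where(valid, tile.values - undulation.values, tile.nodata)
    return tile.with_values(out, vdatum="geoid")


def replace_artifacts(tdx: RasterTile, ref: RasterTile,
                      cfg: DemPrepConfig = DemPrepConfig()) -> RasterTile:
    """Swap in the reference DEM wherever |DEM − reference| exceeds the threshold.

    Applied per pixel on co-registered geoid-referenced grids.  Nodata in
    the DEM stays nodata; where the reference is nodata the DEM value is
    kept (no basis for replacement).
    """
    if tdx.vdatum != ref.vdatum:
        raise ValueError(f"vdatum mismatch: {tdx.vdatum!r} vs {ref.vdatum!r}")
    require_coregistered(tdx, ref)
    both = tdx.valid_mask() & ref.valid_mask()
    swap = both & (np.abs(tdx.values - ref.values) > cfg.artifact_threshold_m)
    out = np.where(swap, ref.values, tdx.values)
    out[~tdx.valid_mask()] = tdx.nodata
    return tdx.with_values(out)


def clip_heights(tile: RasterTile,
                 cfg: DemPrepConfig = DemPrepConfig()) -> RasterTile:
    """Set pixels outside [min_height_m, max_height_m] to nodata."""
    valid = tile.valid_mask()
    bad = valid & ((tile.values > cfg.max_height_m)
                   | (tile.values < cfg.min_height_m))
    out = np.where(bad, tile.nodata, tile.values)
    return tile.with_values(out)
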