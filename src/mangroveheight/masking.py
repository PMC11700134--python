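"""Water-persistence masking, vector rasterization and mangrove subsetting.

Open water is a smooth, specular surface with persistently low SAR
backscatter.  Thresholding each layer of a backscatter time stack at
−19 dB and counting the fraction of layers voting "water" yields a
normalized persistence image; pixels persistently low (> 70 % of layers)
are classified as water and removed from the DEM together with everything
outside the mangrove-extent mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely

from .raster import GridTransform, RasterTile, require_coregistered


@dataclass(frozen=True)
class WaterMaskConfig:
    backscatter_threshold_db: float = -19.0
    persistence_threshold: float = 0.70

    def __post_init__(self) -> None:
        if not (0 < self.persistence_threshold < 1):
            raise ValueError("persistence_threshold must be in (0, 1)")


@dataclass
class MaskSet:
    """Water, mangrove-extent and country-label rasters on the 12 m grid."""

    water: RasterTile
    mangrove_extent: RasterTile
    country: RasterTile | None = None


def water_persistence(stack: list[RasterTile],
                      cfg: WaterMaskConfig = WaterMaskConfig()) -> RasterTile:
    """Per-pixel fraction of stack layers at or below the backscatter threshold.

    The denominator is the number of layers in which the pixel is valid, so
    partial-coverage stacks normalise correctly.  Pixels valid in no layer
    are nodata.
    """
    if not stack:
        raise ValueError("backscatter stack is empty")
    require_coregistered(*stack)
    votes = np.zeros(stack[0].shape, dtype=float)
    n_valid = np.zeros(stack[0].shape, dtype=float)
    for layer in stack:
        valid = layer.valid_mask()
        votes += valid & (layer.values <= cfg.backscatter_threshold_db)
        n_valid += valid
    first = stack[0]
    with np.errstate(invalid="ignore"):
        frac = np.where(n_valid > 0, votes / np.maximum(n_valid, 1), first.nodata)
    return RasterTile(frac, first.transform, crs=first.crs, nodata=first.nodata)


def classify_water(persistence: RasterTile,
                   cfg: WaterMaskConfig = WaterMaskConfig()) -> RasterTile:
    """Binary water mask: water iff persistence strictly above the threshold."""
    valid = persistence.valid_mask()
    water = (valid & (persistence.values > cfg.persistence_threshold)).astype(float)
    water[~valid] = persistence.nodata
    return persistence.with_values(water)


def rasterize_polygons(polygons: list[tuple[int, shapely.Geometry]],
                       target_transform: GridTransform,
                       target_shape: tuple[int, int]) -> RasterTile:
    """Burn labelled polygons onto a grid by pixel-centre membership.

    ``polygons`` is a list of ``(label, geometry)`` with positive integer
    labels.  A pixel whose centre lies in no polygon gets 0; a centre on a
    shared boundary gets the lowest label (polygons are visited in
    ascending label order, first assignment wins).
    """
    for label, geom in polygons:
        if label <= 0:
            raise ValueError(f"polygon labels must be positive, got {label}")
        if not geom.is_valid:
            raise ValueError(f"invalid geometry for label {label}")
    xs, ys = target_transform.center_grids(target_shape)
    out = np.zeros(target_shape, dtype=float)
    for label, geom in sorted(polygons, key=lambda p: p[0]):
        hit = shapely.intersects_xy(geom, xs, ys) & (out == 0)
        out[hit] = label
    return RasterTile(out, target_transform, nodata=-1.0)


def read_labeled_geojson(path, label_property: str = "label"
                         ) -> list[tuple[int, shapely.Geometry]]:
    """Read (label, geometry) pairs from a GeoJSON FeatureCollection."""
    import json
    from pathlib import Path

    data = json.loads(Path(path).read_text())
    out = []
    for feat in data.get("features", []):
        label = int(feat["properties"][label_property])
        out.append((label, shapely.geometry.shape(feat["geometry"])))
    return out


def apply_masks(dem: RasterTile, masks: MaskSet) -> RasterTile:
    """Retain DEM pixels inside the mangrove extent and not water."""
    require_coregistered(dem, masks.water, masks.mangrove_extent)
    keep = (dem.valid_mask()
            & (masks.mangrove_extent.values == 1)
            & ~(masks.water.values == 1))
    out = np.where(keep, dem.values, dem.nodata)
    return dem.with_values(out)
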