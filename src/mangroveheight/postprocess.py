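"""Tall-tile outlier mitigation via the 99th-percentile / inflection rule.

Extent-mask misclassification (upland forest or hills labelled mangrove)
produces implausibly tall pixels in some tiles.  Mitigation works on the
population of tiles containing any pixel above a flag height (50 m):
their 99th percentiles are ordered, a 5th-order polynomial is fitted to
the ordered values, and the curve's inflection point separates tiles whose
tail is artifact-driven (low p99: cap the tail at p99) from genuinely tall
smooth canopy (high p99: leave untouched).  On the published global tile
population this inflection falls at 31.02 m; the threshold is always
recomputed from the tile population at hand, never assumed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .raster import RasterTile


@dataclass(frozen=True)
class PostprocessConfig:
    flag_height_m: float = 50.0
    percentile: float = 99.0
    poly_order: int = 5

    def __post_init__(self) -> None:
        if not (0 < self.percentile < 100):
            raise ValueError("percentile must be in (0, 100)")
        if self.poly_order < 3:
            raise ValueError("poly_order must be at least 3")


@dataclass
class TileTallStats:
    tile_id: str
    max_m: float
    p99_m: float


def tile_tall_stats(tile: RasterTile, cfg: PostprocessConfig = PostprocessConfig(),
                    tile_id: str = "") -> TileTallStats | None:
    """Max and 99th percentile of a flagged tile; None when no pixel exceeds
    the flag height.  Percentile by linear interpolation of order statistics."""
    vals = tile.valid_values()
    if vals.size == 0 or vals.max() <= cfg.flag_height_m:
        return None
    return TileTallStats(tile_id, float(vals.max()),
                         float(np.percentile(vals, cfg.percentile)))


def find_inflection_threshold(p99_values,
                              cfg: PostprocessConfig = PostprocessConfig()) -> float:
    """Inflection of a degree-5 polynomial fitted to the ordered percentiles.

    Values are sorted ascending and ranks normalised to [0, 1] for
    conditioning; the fitted polynomial's second derivative is solved for
    real roots inside the rank range at which the curvature changes sign,
    and the polynomial value at the smallest such root is returned.
    """
    vals = np.sort(np.asarray(p99_values, dtype=float))
    if vals.size < cfg.poly_order + 2:
        raise ValueError(f"need at least {cfg.poly_order + 2} values, got {vals.size}")
    ranks = np.linspace(0.0, 1.0, vals.size)
    poly = np.polynomial.Polynomial.fit(ranks, vals, cfg.poly_order)
    d2 = poly.deriv(2)
    roots = d2.roots()
    real = np.sort(roots[np.abs(roots.imag) < 1e-9].real)
    eps = 1e-6
    candidates = []
    for r in real:
        if not (0.0 - eps <= r <= 1.0 + eps):
            continue
        lo, hi = max(0.0, r - 1e-4), min(1.0, r + 1e-4)
        if d2(lo) * d2(hi) < 0:  # curvature sign change, a true inflection
            candidates.append(r)
    if not candidates:
        raise ValueError(
            "no inflection of the fitted polynomial lies within the rank range; "
            f"second-derivative roots at ranks {np.round(real, 4).tolist()}")
    return float(poly(candidates[0]))


def mitigate_tile(tile: RasterTile, stats: TileTallStats,
                  threshold_m: float) -> RasterTile:
    """Cap artifact tails: if the tile's p99 is below the inflection
    threshold, every pixel above p99 is set to p99; otherwise (a genuinely
    tall tile) the tile is unchanged.  Never increases any pixel."""
    if stats.p99_m >= threshold_m:
        return tile.copy()
    valid = tile.valid_mask()
    out = np.where(valid & (tile.values > stats.p99_m), stats.p99_m, tile.values)
    return tile.with_values(out)
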