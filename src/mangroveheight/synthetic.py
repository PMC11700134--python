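"""Synthetic mangrove scenes with the statistical structure the pipeline assumes.

A scene bundles every input the pipeline consumes, generated from one seed:

* a smooth true canopy-height field on the 12 m grid, with embedded water
  channels (nodata in the truth) drawn as random walks to mimic the narrow
  river channels of real mangrove systems;
* a 12 m DEM = truth + geoid undulation + Gaussian noise + sparse large
  artifacts (patches offset by > 30 m, emulating interferometric errors);
* a smooth co-located 30 m reference DEM (geoid heights, water at 0 m);
* a SAR backscatter time stack in dB whose water pixels return ≤ −19 dB in
  a configurable fraction of layers while canopy stays well above;
* a binary mangrove-extent raster on a 25 m grid;
* integer country labels (two countries split mid-scene) on the 12 m grid;
* lidar shots sampling the truth at footprint scale with optional vertical
  noise, geolocation jitter and a contaminated fraction built to fail
  exactly one quality criterion each;
* a 1 m airborne-lidar canopy height model of the same truth.

Everything is deterministic in (config, seed): rebuilding a scene from the
same config yields bit-identical rasters and shot tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage

from .gedi import SHOT_LEVEL_CRITERIA, GediShot, shots_to_frame
from .raster import (M_PER_DEG_LAT, GridTransform, RasterTile, m_per_deg_lon)


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of a synthetic scene; the defaults are the study conditions.

    Heights stay within the plausible mangrove range (0–60 m); footprint
    vertical noise (2 m) and geolocation jitter (10 m) match the error
    magnitudes typical of spaceborne-lidar RH metrics, DEM noise (1 m) the
    random error of a 12 m InSAR DEM, and the 90 m artifact magnitude is
    comfortably above the 30 m replacement threshold.
    """

    tile_size_px: int = 100
    origin_lon_lat: tuple[float, float] = (-80.0, 8.0)
    truth_smoothness: float = 10.0
    height_range: tuple[float, float] = (0.5, 40.0)
    water_fraction: float = 0.15
    artifact_count: int = 3
    artifact_magnitude_m: float = 90.0
    n_shots: int = 500
    rh_noise_sd_m: float = 2.0
    geolocation_jitter_sd_m: float = 10.0
    contamination_fraction: float = 0.1
    undulation_m: float = 20.0
    dem_noise_sd_m: float = 1.0
    als_noise_sd_m: float = 0.5
    n_backscatter_layers: int = 10
    water_low_fraction: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tile_size_px < 8:
            raise ValueError("tile_size_px: must be at least 8")
        lo, hi = self.height_range
        if not (0 <= lo < hi <= 60):
            raise ValueError("height_range: must satisfy 0 <= min < max <= 60")
        for name in ("water_fraction", "contamination_fraction", "water_low_fraction"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name}: must be in [0, 1]")
        if self.artifact_count < 0:
            raise ValueError("artifact_count: must be nonnegative")
        if self.artifact_count and self.artifact_magnitude_m <= 30:
            raise ValueError("artifact_magnitude_m: must exceed 30 m")
        if self.n_shots <= 0:
            raise ValueError("n_shots: must be positive")
        for name in ("rh_noise_sd_m", "geolocation_jitter_sd_m",
                     "dem_noise_sd_m", "als_noise_sd_m"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name}: must be nonnegative")
        if self.n_backscatter_layers < 1:
            raise ValueError("n_backscatter_layers: must be at least 1")


@dataclass
class SyntheticScene:
    truth_chm_12m: RasterTile
    tdx_dem: RasterTile
    ref_dem_30m: RasterTile
    backscatter_stack: list[RasterTile]
    mangrove_extent: RasterTile
    eez_labels: RasterTile
    als_chm_1m: RasterTile
    shots: list[GediShot]
    undulation: RasterTile
    water_truth: RasterTile
    config: SceneConfig


# --------------------------------------------------------------- grid set-up

def scene_grids(cfg: SceneConfig):
    """12 m, 30 m, 25 m and 1 m grids sharing the scene's top-left origin.

    Metric pixel sizes are expressed in degrees at the scene latitude.
    """
    lon0, lat0 = cfg.origin_lon_lat
    mx, my = m_per_deg_lon(lat0), M_PER_DEG_LAT
    n12 = cfg.tile_size_px
    extent_m = n12 * 12.0

    def grid(pix_m):
        n = int(math.ceil(extent_m / pix_m))
        return GridTransform(lon0, lat0, pix_m / mx, -pix_m / my), (n, n)

    return {"12": grid(12.0), "30": grid(30.0), "25": grid(25.0),
            "1": (GridTransform(lon0, lat0, 12.0 / mx / 12, -12.0 / my / 12),
                  (n12 * 12, n12 * 12))}


# ------------------------------------------------------------------- pieces

def _truth_field(cfg: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    n = cfg.tile_size_px
    raw = ndimage.gaussian_filter(rng.standard_normal((n, n)),
                                  cfg.truth_smoothness, mode="reflect")
    lo, hi = raw.min(), raw.max()
    span = hi - lo if hi > lo else 1.0
    rmin, rmax = cfg.height_range
    return rmin + (raw - lo) / span * (rmax - rmin)


def _water_channels(cfg: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    """Connected channels drawn as biased random walks from scene edges."""
    n = cfg.tile_size_px
    water = np.zeros((n, n), dtype=bool)
    target = cfg.water_fraction * n * n
    guard = 0
    while water.sum() < target and guard < 200:
        guard += 1
        # enter from a random edge, walk with momentum across the scene
        edge = rng.integers(4)
        if edge == 0:
            r, c, dr, dc = 0, int(rng.integers(n)), 1, 0
        elif edge == 1:
            r, c, dr, dc = n - 1, int(rng.integers(n)), -1, 0
        elif edge == 2:
            r, c, dr, dc = int(rng.integers(n)), 0, 0, 1
        else:
            r, c, dr, dc = int(rng.integers(n)), n - 1, 0, -1
        width = int(rng.integers(1, 3))
        for _ in range(4 * n):
            water[max(0, r - width + 1):r + width, max(0, c - width + 1):c + width] = True
            if rng.random() < 0.3:  # meander
                if dr:
                    dr, dc = 0, int(rng.choice([-1, 1]))
                else:
                    dr, dc = int(rng.choice([-1, 1])), 0
            r, c = r + dr, c + dc
            if not (0 <= r < n and 0 <= c < n):
                break
            if water.sum() >= target:
                break
    return water


def _artifact_mask(cfg: SceneConfig, rng: np.random.Generator,
                   patch_px: int = 3) -> np.ndarray:
    """``artifact_count`` disjoint square patches, separated by ≥ 2 pixels."""
    n = cfg.tile_size_px
    mask = np.zeros((n, n), dtype=bool)
    centers: list[tuple[int, int]] = []
    tries = 0
    while len(centers) < cfg.artifact_count:
        tries += 1
        if tries > 10_000:
            raise ValueError("artifact_count: cannot place disjoint patches")
        r = int(rng.integers(patch_px, n - patch_px))
        c = int(rng.integers(patch_px, n - patch_px))
        if all(max(abs(r - r0), abs(c - c0)) >= 2 * patch_px + 2
               for r0, c0 in centers):
            centers.append((r, c))
            h = patch_px // 2
            mask[r - h:r + h + 1, c - h:c + h + 1] = True
    return mask


# ---------------------------------------------------------------- generator

def generate_scene(cfg: SceneConfig) -> SyntheticScene:
    """Build a full scene; bit-identical for identical configs."""
    rng = np.random.default_rng(cfg.seed)
    grids = scene_grids(cfg)
    t12, shape12 = grids["12"]
    t30, shape30 = grids["30"]
    t25, shape25 = grids["25"]
    t1, shape1 = grids["1"]

    truth_land = _truth_field(cfg, rng)
    water = _water_channels(cfg, rng)
    truth_vals = np.where(water, -9999.0, truth_land)
    truth = RasterTile(truth_vals, t12, vdatum="geoid")

    undulation = RasterTile(np.full(shape12, float(cfg.undulation_m)), t12)

    # 12 m DEM: ellipsoidal = truth (water surface at 0) + undulation + noise
    surface = np.where(water, 0.0, truth_land)
    noise = (rng.standard_normal(shape12) * cfg.dem_noise_sd_m
             if cfg.dem_noise_sd_m else np.zeros(shape12))
    artifacts = _artifact_mask(cfg, rng) if cfg.artifact_count else np.zeros(shape12, bool)
    tdx_vals = surface + cfg.undulation_m + noise
    tdx_vals[artifacts] += cfg.artifact_magnitude_m
    tdx = RasterTile(tdx_vals, t12, vdatum="ellipsoid")

    # 30 m reference: geoid heights of the same surface, sampled at centres
    xs30, ys30 = t30.center_grids(shape30)
    r12, c12 = t12.index_of(xs30, ys30)
    r12 = np.clip(r12, 0, shape12[0] - 1)
    c12 = np.clip(c12, 0, shape12[1] - 1)
    ref = RasterTile(surface[r12, c12], t30, vdatum="geoid")

    # backscatter stack: canopy well above the −19 dB water threshold,
    # water below it in `water_low_fraction` of layers per pixel
    nlay = cfg.n_backscatter_layers
    k_low = int(round(cfg.water_low_fraction * nlay))
    low_layer = np.zeros((nlay,) + shape12, dtype=bool)
    wr, wc = np.nonzero(water)
    for i in range(wr.size):
        lows = rng.choice(nlay, size=k_low, replace=False)
        low_layer[lows, wr[i], wc[i]] = True
    stack = []
    for ell in range(nlay):
        land_db = np.clip(rng.normal(-8.0, 2.0, shape12), -18.5, None)
        wet_db = -19.5 - np.abs(rng.normal(2.0, 1.0, shape12))
        dry_db = np.clip(rng.normal(-12.0, 2.0, shape12), -18.5, None)
        vals = np.where(water, np.where(low_layer[ell], wet_db, dry_db), land_db)
        stack.append(RasterTile(vals, t12))

    # 25 m mangrove extent: 1 where the containing 12 m pixel is land
    xs25, ys25 = t25.center_grids(shape25)
    r25, c25 = t12.index_of(xs25, ys25)
    inside = ((r25 >= 0) & (r25 < shape12[0]) & (c25 >= 0) & (c25 < shape12[1]))
    ext = np.zeros(shape25)
    ext[inside] = (~water[np.clip(r25, 0, shape12[0] - 1),
                          np.clip(c25, 0, shape12[1] - 1)])[inside]
    extent = RasterTile(ext, t25)

    labels = np.ones(shape12)
    labels[:, shape12[1] // 2:] = 2
    eez = RasterTile(labels, t12)

    water_tile = RasterTile(water.astype(float), t12)
    scene = SyntheticScene(truth, tdx, ref, stack, extent, eez,
                           als_chm_1m=None, shots=[], undulation=undulation,
                           water_truth=water_tile, config=cfg)
    scene.als_chm_1m = generate_als_chm(scene, cfg.als_noise_sd_m,
                                        rng=np.random.default_rng(cfg.seed + 1))
    scene.shots = generate_shots(scene, cfg, rng=np.random.default_rng(cfg.seed + 2))
    return scene


def generate_shots(scene: SyntheticScene, cfg: SceneConfig,
                   rng: np.random.Generator | None = None) -> list[GediShot]:
    """Footprint-scale samples of the truth with configurable corruption.

    Shots are centred on interior land pixels whose 3×3 neighbourhood is
    land and locally homogeneous (sample sd < 1.2 m), emulating the
    homogeneous-canopy shots the quality cascade retains; each shot's RH98
    is the footprint mean of the truth at the *true* location plus vertical
    noise, while the reported location adds isotropic geolocation jitter.
    Exactly round(contamination_fraction × n_shots) shots are given values
    failing one quality criterion each, drawn uniformly over the
    shot-level criteria; the chosen criterion is recorded on the shot.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 2)
    if cfg.n_shots <= 0:
        raise ValueError("n_shots: must be positive")
    truth = scene.truth_chm_12m
    land = truth.valid_mask()
    n = cfg.tile_size_px

    # candidates: 5x5 all-land neighbourhood, so the footprint and the
    # containing coarse extent pixels are guaranteed on land
    ok = np.zeros_like(land)
    ok[2:-2, 2:-2] = True
    for dr in range(-2, 3):
        for dc in range(-2, 3):
            ok[2:-2, 2:-2] &= land[2 + dr:n - 2 + dr, 2 + dc:n - 2 + dc]
    # local homogeneity: sample sd of the 3x3 truth block
    filled = np.where(land, truth.values, 0.0)
    s1 = ndimage.uniform_filter(filled, 3) * 9
    s2 = ndimage.uniform_filter(filled**2, 3) * 9
    var = np.maximum(s2 - s1**2 / 9.0, 0.0) / 8.0
    ok[1:-1, 1:-1] &= np.sqrt(var[1:-1, 1:-1]) < 1.2
    rows, cols = np.nonzero(ok)
    if rows.size == 0:
        raise ValueError("no homogeneous land pixels available for shots")

    pick = rng.choice(rows.size, size=cfg.n_shots,
                      replace=rows.size < cfg.n_shots)
    # sub-pixel offset small enough that a zero-jitter footprint always
    # covers the centre pixel and its four cross neighbours (count 5)
    offsets = rng.uniform(-0.03, 0.03, size=(cfg.n_shots, 2))
    t = truth.transform
    lat0 = cfg.origin_lon_lat[1]
    mx, my = m_per_deg_lon(lat0), M_PER_DEG_LAT

    n_bad = int(round(cfg.contamination_fraction * cfg.n_shots))
    bad_idx = set(rng.choice(cfg.n_shots, size=n_bad, replace=False).tolist())
    criteria = [SHOT_LEVEL_CRITERIA[i]
                for i in rng.integers(len(SHOT_LEVEL_CRITERIA), size=cfg.n_shots)]

    from .gedi import FilterConfig, footprint_pixels

    fcfg = FilterConfig()
    shots: list[GediShot] = []
    for i in range(cfg.n_shots):
        r, c = int(rows[pick[i]]), int(cols[pick[i]])
        lon, lat = t.pixel_center(r + offsets[i, 0], c + offsets[i, 1])
        probe = GediShot(shot_id=f"S{i:06d}", lon=float(lon), lat=float(lat), rh98=0.0)
        fp = footprint_pixels(probe, truth, fcfg)
        fp_vals = [truth.values[rr, cc] for rr, cc in fp if land[rr, cc]]
        rh = float(np.mean(fp_vals)) + (rng.normal(0.0, cfg.rh_noise_sd_m)
                                        if cfg.rh_noise_sd_m else 0.0)
        jitter = (rng.normal(0.0, cfg.geolocation_jitter_sd_m, 2)
                  if cfg.geolocation_jitter_sd_m else np.zeros(2))
        shot = GediShot(
            shot_id=f"S{i:06d}",
            lon=float(lon + jitter[0] / mx),
            lat=float(lat + jitter[1] / my),
            rh98=rh,
            quality_flag=1, degrade_flag=0,
            num_modes=int(rng.integers(1, 5)),
            dem_minus_egm=float(rng.uniform(0.0, 40.0)),
            water_persistence_landsat=float(rng.uniform(0.0, 60.0)),
            elev_lowest_mode_minus_mss=float(rng.uniform(-4.0, 4.0)),
            total_energy=float(rng.uniform(3000.0, 20000.0)),
        )
        if i in bad_idx:
            _contaminate(shot, criteria[i], rng)
        shots.append(shot)
    return shots


def _contaminate(shot: GediShot, criterion: str, rng: np.random.Generator) -> None:
    """Overwrite one field so the shot fails exactly ``criterion``."""
    if criterion == "degrade_flag":
        shot.degrade_flag = 1
    elif criterion == "quality_flag":
        shot.quality_flag = 0
    elif criterion == "num_modes":
        shot.num_modes = int(rng.choice([0, 5]))
    elif criterion == "dem_minus_egm":
        shot.dem_minus_egm = float(rng.uniform(55.0, 90.0))
    elif criterion == "water_persistence":
        shot.water_persistence_landsat = float(rng.uniform(85.0, 100.0))
    elif criterion == "lowest_mode_mss":
        shot.elev_lowest_mode_minus_mss = float(rng.choice([-1, 1])
                                                * rng.uniform(6.0, 12.0))
    elif criterion == "total_energy":
        shot.total_energy = float(rng.choice([rng.uniform(100.0, 1500.0),
                                              rng.uniform(26000.0, 40000.0)]))
    else:  # pragma: no cover
        raise ValueError(f"unknown contamination criterion {criterion!r}")
    shot.true_fail_criterion = criterion


def generate_als_chm(scene: SyntheticScene, noise_sd_m: float = 0.0,
                     rng: np.random.Generator | None = None) -> RasterTile:
    """1 m CHM of the truth: 12×12 fine pixels per 12 m cell, optional
    Gaussian noise; fine pixels over truth-nodata (water) are nodata."""
    if rng is None:
        rng = np.random.default_rng(scene.config.seed + 1)
    truth = scene.truth_chm_12m
    t1, shape1 = scene_grids(scene.config)["1"]
    fine = np.repeat(np.repeat(truth.values, 12, axis=0), 12, axis=1)
    land = np.repeat(np.repeat(truth.valid_mask(), 12, axis=0), 12, axis=1)
    if noise_sd_m:
        fine = fine + rng.standard_normal(fine.shape) * noise_sd_m
    fine[~land] = truth.nodata
    return RasterTile(fine, t1, vdatum="geoid", nodata=truth.nodata)


def synthetic_calibration_pairs(n: int = 100_000, seed: int = 0,
                                a: float = 1.02, b: float = 0.33,
                                noise_sd_sqrt: float = 0.3,
                                min_stratum: int = 50):
    """Height-imbalanced (DEM, RH98) pairs from a known sqrt-linear model.

    Stratum sizes follow the global-corpus category proportions (which span
    four orders of magnitude) scaled to ``n`` with a floor of
    ``min_stratum`` points per category so every stratum weight is
    estimable.  True heights are uniform within their 10 m category,
    observed heights carry Gaussian noise (sd ``noise_sd_sqrt``) on the
    square-root scale, and the DEM predictor inverts the generating model
    exactly.  Returns ``(x, y_obs, weights)`` where the weights are the
    equal-category-mass design weights 1/(n_c × 6).
    """
    from .calibration import GLOBAL_CATEGORY_COUNTS, N_CATEGORIES

    rng = np.random.default_rng(seed)
    props = np.asarray(GLOBAL_CATEGORY_COUNTS, float)
    props /= props.sum()
    counts = np.maximum(np.round(props * n).astype(int), min_stratum)
    cat = np.repeat(np.arange(N_CATEGORIES), counts)
    lo = 10.0 * cat
    hi = 10.0 * (cat + 1)
    y_true = rng.uniform(lo, hi)
    x = ((np.sqrt(y_true) - b) / a) ** 2
    y_obs = (np.sqrt(y_true) + rng.normal(0.0, noise_sd_sqrt, y_true.size)) ** 2
    weights = 1.0 / (counts[cat] * N_CATEGORIES)
    return x, y_obs, weights


# ----------------------------------------------------------------- scene I/O

def write_scene(scene: SyntheticScene, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scene.truth_chm_12m.write_ascii(out / "truth_chm_12m.asc")
    scene.tdx_dem.write_ascii(out / "tdx_dem_12m.asc")
    scene.ref_dem_30m.write_ascii(out / "ref_dem_30m.asc")
    scene.mangrove_extent.write_ascii(out / "mangrove_extent_25m.asc")
    scene.eez_labels.write_ascii(out / "eez_labels_12m.asc")
    scene.undulation.write_ascii(out / "undulation_12m.asc")
    scene.water_truth.write_ascii(out / "water_truth_12m.asc")
    scene.als_chm_1m.write_ascii(out / "als_chm_1m.asc")
    for i, layer in enumerate(scene.backscatter_stack):
        layer.write_ascii(out / f"backscatter_{i:02d}.asc")
    shots_to_frame(scene.shots).to_csv(out / "shots.csv", index=False)
    (out / "scene_config.yaml").write_text(yaml.safe_dump(asdict(scene.config)))


def config_from_yaml(path: str | Path) -> SceneConfig:
    d = yaml.safe_load(Path(path).read_text())
    for key in ("origin_lon_lat", "height_range"):
        if key in d:
            d[key] = tuple(d[key])
    return SceneConfig(**d)
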