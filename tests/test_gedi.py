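"""Footprint geometry, zonal statistics and the quality-filter cascade."""

import math

import numpy as np
import pytest

from mangroveheight import (FilterConfig, FootprintPair, FootprintStats, GediShot,
                            GridTransform, RasterTile, binned_outlier_filter,
                            footprint_pixels, footprint_stats, quality_filter)
from mangroveheight.raster import M_PER_DEG_LAT, m_per_deg_lon

CFG = FilterConfig()
LAT0 = 8.0


def make_grid(n=20, px_m=12.0, fill=10.0):
    dx = px_m / m_per_deg_lon(LAT0)
    dy = -px_m / M_PER_DEG_LAT
    t = GridTransform(-80.0, LAT0, dx, dy)
    return RasterTile(np.full((n, n), fill), t)


def shot_at(grid, row, col, row_off=0.0, col_off=0.0, **kw):
    lon, lat = grid.transform.pixel_center(row + row_off, col + col_off)
    kw.setdefault("rh98", 10.0)
    return GediShot(shot_id="s", lon=float(lon), lat=float(lat), **kw)


def oracle_footprint(shot, grid, radius=12.5):
    """Exhaustive centre-distance scan."""
    out = []
    mx, my = m_per_deg_lon(shot.lat), M_PER_DEG_LAT
    for r in range(grid.shape[0]):
        for c in range(grid.shape[1]):
            x, y = grid.transform.pixel_center(r, c)
            d = math.hypot((float(x) - shot.lon) * mx, (float(y) - shot.lat) * my)
            if d <= radius:
                out.append((r, c))
    return sorted(out)


def test_center_shot_covers_pixel_and_cross_neighbours():
    grid = make_grid()
    px = footprint_pixels(shot_at(grid, 10, 10), grid, CFG)
    assert (10, 10) in px
    assert sorted(px) == [(9, 10), (10, 9), (10, 10), (10, 11), (11, 10)]


def test_corner_shot_covers_four_pixels():
    grid = make_grid()
    # centred on the junction of 4 pixels: each centre ~8.49 m away
    px = footprint_pixels(shot_at(grid, 10, 10, 0.5, 0.5), grid, CFG)
    assert sorted(px) == [(10, 10), (10, 11), (11, 10), (11, 11)]


def test_footprint_matches_distance_oracle():
    grid = make_grid()
    rng = np.random.default_rng(12)
    for _ in range(30):
        shot = shot_at(grid, float(rng.uniform(1, 18)), float(rng.uniform(1, 18)))
        assert sorted(footprint_pixels(shot, grid, CFG)) == oracle_footprint(shot, grid)


def test_shot_outside_grid_gives_empty_set():
    grid = make_grid()
    shot = GediShot(shot_id="s", lon=0.0, lat=0.0, rh98=10.0)
    assert footprint_pixels(shot, grid, CFG) == []


def test_footprint_stats_hand_arithmetic(meter_grid):
    dem = meter_grid([[10.0, 12.0, 14.0]])
    st = footprint_stats([(0, 0), (0, 1), (0, 2)], dem)
    assert (st.mean, st.min, st.max, st.count) == (12.0, 10.0, 14.0, 3)
    assert st.sd == pytest.approx(2.0)  # sample sd


def test_footprint_stats_degenerate_cases(meter_grid):
    dem = meter_grid([[7.0, -9999.0]])
    single = footprint_stats([(0, 0)], dem)
    assert (single.count, single.sd) == (1, 0.0)
    empty = footprint_stats([(0, 1)], dem)
    assert empty.count == 0


def good_pair(**overrides):
    shot_kw = dict(shot_id="s", lon=0.0, lat=0.0, rh98=20.0, quality_flag=1,
                   degrade_flag=0, num_modes=2, dem_minus_egm=10.0,
                   water_persistence_landsat=10.0, elev_lowest_mode_minus_mss=1.0,
                   total_energy=10_000.0)
    stats_kw = dict(mean=20.0, min=18.0, max=22.0, sd=1.2, count=4)
    for k, v in overrides.items():
        (shot_kw if k in shot_kw else stats_kw)[k] = v
    return FootprintPair(GediShot(**shot_kw), FootprintStats(**stats_kw))


def test_fully_passing_shot_is_kept():
    out = quality_filter(good_pair(), CFG)
    assert out.kept and out.reject_reason is None


@pytest.mark.parametrize("override, reason", [
    (dict(degrade_flag=1), "degrade_flag"),
    (dict(quality_flag=0), "quality_flag"),
    (dict(num_modes=5), "num_modes"),
    (dict(num_modes=0), "num_modes"),
    (dict(dem_minus_egm=50.0), "dem_minus_egm"),
    (dict(water_persistence_landsat=80.0), "water_persistence"),
    (dict(elev_lowest_mode_minus_mss=-5.5), "lowest_mode_mss"),
    (dict(total_energy=2000.0), "total_energy"),
    (dict(total_energy=26000.0), "total_energy"),
    (dict(max=60.0), "tdx_max_range"),
    (dict(max=0.0), "tdx_max_range"),
    (dict(min=60.0), "tdx_min"),
    (dict(rh98=-0.5), "rh98_range"),
    (dict(rh98=60.0), "rh98_range"),
    (dict(count=2), "pixel_count"),
    (dict(count=4, sd=1.5), "tdx_sd"),   # 3-4 pixels: sd must be < 1.5 m
    (dict(count=6, sd=2.3), "tdx_sd"),   # 5-6 pixels: < 2 m
    (dict(count=7, sd=3.2), "tdx_sd"),   # >6 pixels: < 3 m
])
def test_single_criterion_failures(override, reason):
    out = quality_filter(good_pair(**override), CFG)
    assert not out.kept
    assert out.reject_reason == reason


@pytest.mark.parametrize("override", [
    dict(count=7, sd=2.9),   # just under the >6-pixel limit
    dict(count=5, sd=1.9),
    dict(num_modes=1), dict(num_modes=4),
])
def test_threshold_boundaries_kept(override):
    assert quality_filter(good_pair(**override), CFG).kept


def test_first_failing_criterion_reported():
    # degrade comes before energy in the fixed evaluation order
    out = quality_filter(good_pair(degrade_flag=1, total_energy=100.0), CFG)
    assert out.reject_reason == "degrade_flag"


def test_filter_is_idempotent_and_monotone():
    pairs = [good_pair(), good_pair(degrade_flag=1), good_pair(count=2)]
    once = [quality_filter(p, CFG) for p in pairs]
    twice = [quality_filter(p, CFG) for p in once]
    assert [p.kept for p in once] == [p.kept for p in twice]
    assert [p.reject_reason for p in once] == [p.reject_reason for p in twice]


# ------------------------------------------------------- binned outlier pass

def make_pairs(rh, dem):
    return [FootprintPair(GediShot(shot_id=str(i), lon=0, lat=0, rh98=float(r)),
                          FootprintStats(float(d), float(d), float(d), 0.5, 5))
            for i, (r, d) in enumerate(zip(rh, dem))]


def brute_force_binned(rh, dem, width=2.0, sigma=3.0):
    """Independent two-pass marginal binning oracle."""
    rh, dem = np.asarray(rh, float), np.asarray(dem, float)
    removed = np.zeros(rh.size, dtype=bool)
    for bin_var, test_var in ((rh, dem), (dem, rh)):
        for b in np.unique(np.floor(bin_var / width)):
            members = np.flatnonzero(np.floor(bin_var / width) == b)
            if members.size < 3:
                continue
            mu = test_var[members].mean()
            sd = test_var[members].std(ddof=1)
            for i in members:
                if abs(test_var[i] - mu) > sigma * sd:
                    removed[i] = True
    return removed


def test_identical_pairs_none_removed():
    pairs = make_pairs([10] * 20, [11] * 20)
    out = binned_outlier_filter(pairs, CFG)
    assert all(p.kept for p in out)


def test_single_discordant_pair_removed():
    # bins need enough members for a 3-sigma flag: the largest z-score a
    # sample of size n can contain is (n-1)/sqrt(n), so ~10-member bins can
    # mask even a wild outlier; 1000 pairs give ~50 per 2 m bin
    rng = np.random.default_rng(0)
    n = 1000
    dem = rng.uniform(0, 40, n)
    rh = dem + rng.normal(0, 0.3, n)      # tight 1:1 line
    rh2 = np.append(rh, 5.0)
    dem2 = np.append(dem, 45.0)           # one wildly discordant pair
    out = binned_outlier_filter(make_pairs(rh2, dem2), CFG)
    assert not out[-1].kept
    assert out[-1].reject_reason == "binned_outlier"
    assert sum(not p.kept for p in out[:-1]) <= 2  # line pairs essentially intact


def test_empty_input():
    assert binned_outlier_filter([], CFG) == []


def test_binned_filter_matches_bruteforce_oracle():
    rng = np.random.default_rng(23)
    for _ in range(20):
        n = int(rng.integers(5, 60))
        dem = rng.uniform(0, 30, n)
        rh = dem + rng.normal(0, 2.0, n)
        out = binned_outlier_filter(make_pairs(rh, dem), CFG)
        expect = brute_force_binned(rh, dem)
        np.testing.assert_array_equal([not p.kept for p in out], expect)


def test_binned_filter_idempotent():
    rng = np.random.default_rng(31)
    dem = rng.uniform(0, 30, 100)
    rh = dem + rng.normal(0, 2.0, 100)
    once = binned_outlier_filter(make_pairs(rh, dem), CFG)
    twice = binned_outlier_filter(once, CFG)
    assert [p.kept for p in once] == [p.kept for p in twice]


def test_accounting_sums_to_input(noisy_scene):
    from mangroveheight.pipeline import pair_and_filter, prepare_dem
    pairs = pair_and_filter(noisy_scene.shots, prepare_dem(noisy_scene))
    kept = sum(p.kept for p in pairs)
    rejected = sum(not p.kept for p in pairs)
    assert kept + rejected == len(noisy_scene.shots)
    assert all((p.reject_reason is None) == p.kept for p in pairs)
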