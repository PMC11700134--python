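import numpy as np
import pytest

from mangroveheight import GridTransform, RasterTile, SceneConfig, generate_scene


@pytest.fixture
def meter_grid():
    """Unit-meter grid helper for geometry-free raster tests."""
    def make(values, px=1.0, nodata=-9999.0, vdatum=None):
        values = np.asarray(values, dtype=float)
        t = GridTransform(0.0, values.shape[0] * px, px, -px)
        return RasterTile(values, t, crs="local", vdatum=vdatum, nodata=nodata)
    return make


@pytest.fixture(scope="session")
def clean_config():
    """Noiseless, artifact-free scene: every corruption channel off."""
    return SceneConfig(seed=7, tile_size_px=80, water_fraction=0.1,
                       artifact_count=0, rh_noise_sd_m=0.0,
                       geolocation_jitter_sd_m=0.0, contamination_fraction=0.0,
                       dem_noise_sd_m=0.0, als_noise_sd_m=0.0,
                       undulation_m=0.0, n_shots=200)


@pytest.fixture(scope="session")
def clean_scene(clean_config):
    return generate_scene(clean_config)


@pytest.fixture(scope="session")
def noisy_scene():
    """Default study conditions: noise, jitter, artifacts, contamination."""
    return generate_scene(SceneConfig(seed=1))


@pytest.fixture(scope="session")
def contaminated_scene():
    """1000 shots, 10 % single-criterion contamination, all else clean."""
    return generate_scene(SceneConfig(seed=11, n_shots=1000,
                                      contamination_fraction=0.1,
                                      rh_noise_sd_m=0.0,
                                      geolocation_jitter_sd_m=0.0,
                                      dem_noise_sd_m=0.0, artifact_count=0))
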