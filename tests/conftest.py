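import numpy as np
import pytest

from canopyrue.config import RunConfig
from canopyrue.solar import WeatherConfig, generate_season


@pytest.fixture(scope="session")
def default_config() -> RunConfig:
    return RunConfig()


@pytest.fixture(scope="session")
def season_weather():
    """Default synthetic clear-sky season (61 days x 12 hours)."""
    return generate_season(WeatherConfig())


@pytest.fixture(scope="session")
def short_weather():
    """Three-day season for fast end-to-end checks."""
    return generate_season(WeatherConfig(doy_start=228, doy_end=230))


def mc_leaf_projection(beta_sun_deg, beta_leaf_deg, n=2_000_000, seed=0):
    """Monte-Carlo azimuth average of |sun . leaf normal|: oracle for the
    two-branch analytic projection."""
    rng = np.random.default_rng(seed)
    az = rng.uniform(0.0, 2.0 * np.pi, n)
    bs, bl = np.radians(beta_sun_deg), np.radians(beta_leaf_deg)
    sun = np.array([np.cos(bs), 0.0, np.sin(bs)])
    normals = np.stack([
        np.sin(bl) * np.cos(az), np.sin(bl) * np.sin(az), np.full(n, np.cos(bl)),
    ])
    return float(np.abs(sun @ normals).mean())
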