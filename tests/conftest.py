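import numpy as np
import pandas as pd
import pytest

from phenotherm.synthdata import SimConfig, gen_snowcover, gen_temperature, simulate
from phenotherm.thermal import DailySeries


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A three-site desk-scale world for fast structural tests."""
    return SimConfig(
        elevations=(2400.0, 2800.0, 3200.0),
        n_plants_per_site=12,
        batches_per_site=4,
        plants_per_arm=3,
        flowers_per_plant=3,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_world(small_config):
    return simulate(small_config)


@pytest.fixture(scope="session")
def default_world():
    """The full-size study emulation (5 sites, 75 batches)."""
    cfg = SimConfig(seed=1)
    temps = gen_temperature(cfg)
    snow, melts = gen_snowcover(cfg)
    return cfg, temps, snow, melts


def constant_series(site: str, tmean: float, start="2016-09-01", days=60, half_range=5.0) -> DailySeries:
    idx = pd.date_range(start, periods=days, freq="D")
    return DailySeries(
        site,
        pd.DataFrame({"tmin": tmean - half_range, "tmax": tmean + half_range}, index=idx),
    )


def random_series(rng: np.random.Generator, site="S", start="2016-09-01", days=30) -> DailySeries:
    idx = pd.date_range(start, periods=days, freq="D")
    tmean = rng.normal(8.0, 4.0, days)
    half = rng.uniform(2.0, 7.0, days)
    return DailySeries(site, pd.DataFrame({"tmin": tmean - half, "tmax": tmean + half}, index=idx))
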