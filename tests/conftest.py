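import numpy as np
import pytest

from climexsa import ClimateScenario, GridSpec, generate_climate


@pytest.fixture(scope="session")
def small_spec():
    return GridSpec(lat_min=10.0, lat_max=25.0, lon_min=0.0, lon_max=15.0, resolution=5.0)


@pytest.fixture(scope="session")
def small_climate(small_spec):
    """A 3x3 grid spanning warm-wet to cool-dry conditions."""
    scenario = ClimateScenario(
        mean_temp_equator=30.0,
        lapse_per_degree=0.8,
        seasonal_amplitude=6.0,
        precip_bands=((0.0, 1200.0), (25.0, 150.0)),
        precip_seasonality=0.6,
        noise_amplitude=1.0,
        precip_noise_fraction=0.15,
        seed=11,
    )
    return generate_climate(small_spec, scenario)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
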