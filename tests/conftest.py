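import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from procal import CalibrationSeries, SampleDesign, SimulationConfig, fit_calibration

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def exact_series():
    """Noise-free epicatechin series, slope 10 through the origin."""
    conc = np.array([1.0, 2.0, 5.0])
    return CalibrationSeries("epicatechin", conc, 10.0 * conc)


@pytest.fixture
def default_config():
    return SimulationConfig(seed=7)


@pytest.fixture
def apple_design():
    """Realistic procyanidin-rich extract profile (mg/g)."""
    contents = {
        "monomers": 12.9,
        "dp2": 40.6,
        "dp3": 45.1,
        "dp4": 82.0,
        "dp5": 77.1,
        "dp6": 93.5,
        "dp7": 78.6,
        "dp8": 71.5,
        "dp9": 61.6,
        "dp10": 54.9,
    }
    return SampleDesign(true_contents=contents)


def noise_free_epi_fit(slope=20.0):
    conc = np.array([5.0, 50.0, 100.0])
    series = CalibrationSeries("epicatechin", conc, slope * conc)
    return fit_calibration(series, force_zero=True)
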