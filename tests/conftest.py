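import pytest

from benthicflux.models import ChamberGeometry, Constants
from benthicflux.synthetic import SimulationConfig


@pytest.fixture
def constants() -> Constants:
    return Constants()


@pytest.fixture
def geometry() -> ChamberGeometry:
    return ChamberGeometry(
        cross_sectional_area_m2=0.25,
        headspace_volume_l=10.0,
        chamber_length_cm=120.0,
        insertion_depth_cm=15.0,
    )


@pytest.fixture
def flat_temperature() -> list[tuple[float, float]]:
    return [(0.0, 28.0), (12.0, 28.0), (18.0, 28.0)]


@pytest.fixture
def quiet_config() -> SimulationConfig:
    """Low-noise simulation config for near-exact recovery checks."""
    return SimulationConfig(seed=42, gas_noise_sd=0.01, do_noise_sd=0.005)


@pytest.fixture
def noiseless_config() -> SimulationConfig:
    return SimulationConfig(
        seed=0, gas_noise_sd=0.0, do_noise_sd=0.0, detection_limit_ch4=0.0
    )
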