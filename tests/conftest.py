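import numpy as np
import pytest

from greenlight import (
    GREEN_TOWERS_LETTUCE,
    LEDSpec,
    PhotoperiodSpec,
    PriceProfile,
)


@pytest.fixture(scope="session")
def params():
    return GREEN_TOWERS_LETTUCE


@pytest.fixture(scope="session")
def photoperiod():
    return PhotoperiodSpec(step_seconds=900, n_steps=64, start_hour=4.5)


@pytest.fixture(scope="session")
def led():
    return LEDSpec(etr_cap=86.21, efficacy=2.9)


@pytest.fixture
def flat_prices(photoperiod):
    return PriceProfile.fixed(13.19, photoperiod.n_steps)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
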