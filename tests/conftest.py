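import numpy as np
import pytest

from canopylight.synthetic import Scenario, generate_field, plant_truth


@pytest.fixture(scope="session")
def wavelengths():
    return np.arange(400.0, 751.0, 1.0)


def _noiseless_field(density):
    return generate_field(Scenario(density_class=density, seed=7).noiseless())


@pytest.fixture(scope="session")
def open_water_field():
    return _noiseless_field("open_water")


@pytest.fixture(scope="session")
def low_field():
    return _noiseless_field("low")


@pytest.fixture(scope="session")
def moderate_field():
    return _noiseless_field("moderate")


@pytest.fixture(scope="session")
def high_field():
    return _noiseless_field("high")


@pytest.fixture(scope="session")
def truth_levels():
    return plant_truth().levels
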