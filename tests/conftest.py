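import numpy as np
import pytest

from qclpas.forward import ForwardModelParams
from qclpas.instrument import default_acoustics, default_power, default_tuning
from qclpas.synthetic import (
    default_forward_params,
    default_grid,
    default_sweep,
    make_component_library,
)


@pytest.fixture(scope="session")
def tuning():
    return default_tuning()


@pytest.fixture(scope="session")
def power():
    return default_power()


@pytest.fixture(scope="session")
def acoustics():
    return default_acoustics()


@pytest.fixture(scope="session")
def fwd_params(power) -> ForwardModelParams:
    return default_forward_params(power)


@pytest.fixture(scope="session")
def sweep() -> np.ndarray:
    return default_sweep()


@pytest.fixture(scope="session")
def grid():
    return default_grid()


@pytest.fixture(scope="session")
def library(grid):
    return make_component_library(grid)
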