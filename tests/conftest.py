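import numpy as np
import pytest

from flapperoo.geometry import WingGeometry
from flapperoo.quasi_steady import AeroModel
from flapperoo.synthetic import SyntheticSpec


@pytest.fixture
def geometry() -> WingGeometry:
    return WingGeometry()


@pytest.fixture
def aero() -> AeroModel:
    return AeroModel()


@pytest.fixture
def fast_spec() -> SyntheticSpec:
    """Study-condition spec with fewer cycles for quick pipeline tests."""
    return SyntheticSpec(seed=11, n_cycles=6)


@pytest.fixture
def time_grid():
    """One wingbeat cycle at 3 Hz, 400 samples, no duplicate endpoint."""
    f = 3.0
    n = 400
    return np.arange(n) / (n * f), f
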