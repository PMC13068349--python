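import numpy as np
import pytest

import neurodim as nd
from neurodim.cogtasks import SimConfig


@pytest.fixture(scope="session")
def plane_cloud() -> np.ndarray:
    """Uniform 2-D patch rotated into 3 ambient dimensions, 4000 points."""
    return nd.uniform_hyperplane(2, 3, 4000, seed=11).points


@pytest.fixture(scope="session")
def swiss_cloud() -> np.ndarray:
    """Area-uniform Swiss roll, 6000 points."""
    return nd.swiss_roll(6000, seed=11).points


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    """Scaled-down RNN configuration for fast trial/training tests."""
    return SimConfig(n_rec=64)
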