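import numpy as np
import pytest

from liftlab.cli_reporting import make_fixtures
from liftlab.lift_simulator import SimParams


@pytest.fixture(scope="session")
def noiseless_params() -> SimParams:
    return SimParams(noise_sd_force=0.0, noise_sd_report=0.0)


@pytest.fixture(scope="session")
def fixture_cohort():
    """2 participants x 1 rep/cell, noiseless."""
    return make_fixtures(seed=0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
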