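import numpy as np
import pytest

from fedrad.cohort import CentreSpec, generate_cohort
from fedrad.model import TrainConfig, build_local_model, small_config


@pytest.fixture(scope="session")
def tiny_cohorts():
    """One small centre's (train, test) cohorts at 32x32, both classes."""
    spec = CentreSpec("T", 12, 12, 8, 8, seed=7)
    return generate_cohort(spec, 32)


@pytest.fixture(scope="session")
def small_model():
    return build_local_model(small_config(), seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
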