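import numpy as np
import pytest

from pvsretina.config import PipelineConfig
from pvsretina.synthetic import generate_pvs_phantom, generate_retinal_phantom


@pytest.fixture(scope="session")
def default_config():
    cfg = PipelineConfig()
    cfg.validate()
    return cfg


@pytest.fixture(scope="session")
def small_phantom():
    """A 12-tube phantom on a small grid, shared across tests."""
    return generate_pvs_phantom(12, shape=(72, 72, 36), seed=11)


@pytest.fixture(scope="session")
def retinal_phantom():
    return generate_retinal_phantom(seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
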