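import numpy as np
import pytest

from vischoice.config import SimConfig
from vischoice.synth import generate_session


@pytest.fixture(scope="session")
def small_cfg():
    return SimConfig(seed=11, n_block_cycles=2, n_units_per_side=5)


@pytest.fixture(scope="session")
def small_session(small_cfg):
    return generate_session(small_cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
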