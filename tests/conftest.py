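import numpy as np
import pytest

import smsegnet as sm


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_config():
    """A two-level toy network small enough for exhaustive checks."""
    return sm.SMSegNetConfig(
        plan=sm.ChannelPlan((2, 4), (1, 2), 4, 2),
        input_size=(8, 8, 1))


@pytest.fixture
def one_level_config():
    return sm.SMSegNetConfig(
        plan=sm.ChannelPlan((1,), (1,), 1, 1),
        input_size=(4, 4, 1))


@pytest.fixture(scope="session")
def small_phantom():
    """A small phantom volume/label pair shared across tests."""
    return sm.make_phantom(sm.PhantomSpec(dims=(56, 56, 26), seed=7))
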