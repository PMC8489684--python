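import numpy as np
import pytest

from ringbind import netmodel as nm
from ringbind import protocol as pr
from ringbind.engine import integrate_trial

TEST_SCALE = 8
TEST_DT = 0.05


@pytest.fixture(scope="session")
def cap2_spec():
    return nm.capacity2_spec()


@pytest.fixture(scope="session")
def cap2_scaled():
    return nm.scale_network(nm.capacity2_spec(), TEST_SCALE)


@pytest.fixture(scope="session")
def cap2_scaled_uncoupled():
    return nm.scale_network(nm.capacity2_spec(coupled=False), TEST_SCALE)


@pytest.fixture(scope="session")
def load1_sim(cap2_scaled_uncoupled):
    """One load-1 trial at test scale, shared across tests (expensive)."""
    proto = pr.make_load_trial(1, delay_ms=2000.0)
    return integrate_trial(cap2_scaled_uncoupled, proto, seed=11, dt=TEST_DT)


@pytest.fixture(scope="session")
def load2_sim(cap2_scaled_uncoupled):
    """One load-2 trial at test scale, shared across tests (expensive)."""
    proto = pr.make_load_trial(2, delay_ms=1500.0)
    return integrate_trial(cap2_scaled_uncoupled, proto, seed=7, dt=TEST_DT)


@pytest.fixture(scope="session")
def binding_sim(cap2_scaled):
    """One full binding trial at test scale, shared across tests."""
    proto = pr.make_binding_trial(delay_ms=1500.0)
    return integrate_trial(cap2_scaled, proto, seed=3, dt=TEST_DT)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
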