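import numpy as np
import pytest

from triplexsim import build_protocol, default_parameters, simulate


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def untreated_traj(params):
    proto = build_protocol("untreated", 6, 57, params.q)
    return simulate(params, proto, end_week=57, stop_at_death=False)


@pytest.fixture(scope="session")
def early_traj(params):
    proto = build_protocol("early", 6, 57, params.q)
    return simulate(params, proto, end_week=57, stop_at_death=True)


@pytest.fixture(scope="session")
def chronic_traj(params):
    proto = build_protocol("chronic", 6, 57, params.q)
    return simulate(params, proto, end_week=57, stop_at_death=True)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
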