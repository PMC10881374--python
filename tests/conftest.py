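import numpy as np
import pytest

import caputoland as cl


@pytest.fixture(scope="session")
def params():
    return cl.default_params()


@pytest.fixture(scope="session")
def ci_solver():
    """Desk-scale solver settings: 1-ms step over a 1-s stretch segment."""
    return cl.SolverConfig(h=1e-3, t0=0.0, t_end=1.0)


@pytest.fixture(scope="session")
def protocol_1pct(params):
    return cl.make_quick_stretch_protocol(0.01, lambda_0=params.lambda_0, rise_time=4e-3)


@pytest.fixture(scope="session")
def protocol_2pct(params):
    return cl.make_quick_stretch_protocol(0.02, lambda_0=params.lambda_0, rise_time=4e-3)


@pytest.fixture(scope="session")
def trace_1pct_ones(params, protocol_1pct, ci_solver):
    """Integer-order simulated 1% protocol trace (shared across tests)."""
    return cl.simulate_protocol(
        params, cl.AlphaVector.ones(), cl.AlphaVector.ones(), protocol_1pct, ci_solver
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
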