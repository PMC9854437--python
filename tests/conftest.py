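import numpy as np
import pytest

import perfusim as ps
from perfusim.solver import SolverSettings


@pytest.fixture(scope="session")
def params():
    """Shipped default (calibrated) parameter set."""
    return ps.default_parameters()


@pytest.fixture(scope="session")
def tuned_params():
    """Shipped calibrated + pump-tuned parameter set."""
    return ps.load_tuned_parameters()


@pytest.fixture(scope="session")
def baseline_record(params):
    """Converged pump-off baseline run, shared across tests."""
    return ps.simulate(params)


@pytest.fixture(scope="session")
def tuned_baseline_record(tuned_params):
    return ps.simulate(tuned_params)


@pytest.fixture()
def fast_settings():
    """Short runs for tests that only need a rough steady state."""
    return SolverSettings(min_beats=6, max_beats=40)
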