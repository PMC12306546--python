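import numpy as np
import pytest

from scvrelate import reference_design, simulate


@pytest.fixture(scope="session")
def design_rho05():
    return reference_design(0.5, seed=7)


@pytest.fixture(scope="session")
def mixture_rho05(design_rho05):
    """One simulated benchmark mixture at rho=0.5, shared across tests."""
    return simulate(design_rho05, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
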