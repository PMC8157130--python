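import numpy as np
import pytest

from anngc.models import VARModel
from anngc.simulate import SimulationSpec, generate_network_sim1, simulate_var


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def bivariate_coupled():
    """VAR(1) with unidirectional coupling 0 -> 1 and self-dynamics."""
    coeffs = np.zeros((1, 2, 2))
    coeffs[0, 0, 0] = 0.5
    coeffs[0, 1, 1] = 0.3
    coeffs[0, 0, 1] = 0.4   # channel 0 drives channel 1
    return VARModel(coeffs, np.eye(2))


@pytest.fixture(scope="session")
def sim1_model():
    spec = SimulationSpec(study="I", K_ratio=20)
    return generate_network_sim1(spec, np.random.default_rng(7))


@pytest.fixture(scope="session")
def sim1_panel(sim1_model):
    return simulate_var(sim1_model, 3200, np.random.default_rng(8))
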