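import numpy as np
import pytest

from hdcm import sim_qmatrix, ecpe_qmatrix, hierarchy_preset


@pytest.fixture(scope="session")
def q20():
    """The 20-item, 5-attribute simulation Q-matrix."""
    return sim_qmatrix()


@pytest.fixture(scope="session")
def q_ecpe():
    """The ECPE 28-item, 3-attribute Q-matrix."""
    return ecpe_qmatrix()


@pytest.fixture(scope="session")
def linear5():
    return hierarchy_preset("linear")


@pytest.fixture(scope="session")
def tiny_q():
    """Six items over two attributes; enough for identified toy fits."""
    return np.array([[1, 0], [0, 1], [1, 1], [1, 0], [0, 1], [1, 1]])
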