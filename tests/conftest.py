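import numpy as np
import pytest
import scipy.sparse as sp

from maxentnet.network import GeneNetwork


@pytest.fixture
def identity_net():
    """Three genes, self-loops only."""
    return GeneNetwork(list("ABC"), sp.eye(3, format="csr"))


@pytest.fixture
def complete_net4():
    """Four genes, complete support including self-loops."""
    return GeneNetwork(list("ABCD"), sp.csr_matrix(np.ones((4, 4))))


@pytest.fixture
def star_weights():
    """Row-stochastic star: three leaves -> center with p=1, center -> leaves 1/3."""
    w = np.array(
        [
            [0, 0, 0, 1.0],
            [0, 0, 0, 1.0],
            [0, 0, 0, 1.0],
            [1 / 3, 1 / 3, 1 / 3, 0],
        ]
    )
    return sp.csr_matrix(w), ["L1", "L2", "L3", "C"]
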