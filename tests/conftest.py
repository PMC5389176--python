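import numpy as np
import pytest

from ebcov import BlockStructure, make_truth, draw


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_scenario():
    """The standard simulation truth: 50 genes, 5 blocks, rho 0.7."""
    return make_truth(seed=7)


@pytest.fixture
def two_block_structure():
    return BlockStructure.from_blocks(6, [[0, 1, 2], [3, 4, 5]])


def random_correlation(rng, p, n=40):
    """Sample correlation matrix of random Gaussian data (generic, full rank)."""
    X = rng.standard_normal((n, p))
    R = np.corrcoef(X, rowvar=False)
    np.fill_diagonal(R, 1.0)
    return (R + R.T) / 2.0


@pytest.fixture
def small_draw(default_scenario):
    return draw(default_scenario, 15, seed=3).X
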