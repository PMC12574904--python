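import numpy as np
import pytest

from dazzle import ExpressionMatrix, make_world


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def small_matrix():
    """4 cells x 3 genes of raw counts, hand-checkable."""
    values = np.array([[1.0, 0.0, 2.0],
                       [0.0, 0.0, 5.0],
                       [3.0, 1.0, 0.0],
                       [2.0, 2.0, 2.0]])
    return ExpressionMatrix(values, ["g1", "g2", "g3"],
                            ["c1", "c2", "c3", "c4"])


@pytest.fixture(scope="session")
def tiny_world():
    """A small synthetic world shared by tests that only need structure."""
    return make_world(n_genes=20, n_cells=100, density=0.1, seed=42)


@pytest.fixture(scope="session")
def reference_world():
    """The reference study condition: 50 genes, 500 cells, 5% density, 20% dropout."""
    return make_world(seed=7)
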