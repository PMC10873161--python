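import numpy as np
import pytest

from cellfactor.data_io import CellLabelMap, GeneExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def tiny_expr():
    """A literal 3-gene x 4-cell matrix used by hand-arithmetic tests."""
    return GeneExpressionMatrix(
        ["g1", "g2", "g3"],
        ["c1", "c2", "c3", "c4"],
        np.array([[1.0, 0.0, 2.0, 3.0], [0.0, 2.0, 1.0, 0.0], [5.0, 4.0, 0.0, 1.0]]),
    )


@pytest.fixture
def tiny_labels():
    return CellLabelMap.from_pairs(
        [("c1", "a"), ("c2", "a"), ("c3", "b"), ("c4", "b")]
    )


@pytest.fixture(scope="session")
def planted_small():
    """One small planted dataset shared by fast module tests."""
    from cellfactor.simulate import make_planted_dataset

    return make_planted_dataset(seed=11, m=40, n=60, k=2, n_comm=1, noise_sd=0.3)


def random_expr(rng, m, n, scale=1.0):
    vals = scale * rng.random((m, n))
    return GeneExpressionMatrix(
        [f"g{i}" for i in range(m)], [f"c{j}" for j in range(n)], vals
    )
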