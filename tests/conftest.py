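import numpy as np
import pytest

from commbench.conditions import CorrCondition, SizeScheme, load_registry
from commbench.types import MatrixType, Partition, SimilarityMatrix


@pytest.fixture(scope="session")
def registry():
    return load_registry()


@pytest.fixture
def rng():
    return np.random.default_rng(20161110)


@pytest.fixture
def two_cliques():
    """Two disconnected unit-weight triangles and their planted partition."""
    w = np.zeros((6, 6))
    for a, b in [(0, 1), (0, 2), (1, 2), (3, 4), (3, 5), (4, 5)]:
        w[a, b] = w[b, a] = 1.0
    return SimilarityMatrix(w, MatrixType.COUNT), Partition(np.array([1, 1, 1, 2, 2, 2]))


def tiny_corr_condition(**overrides) -> CorrCondition:
    """A fast 24-node correlation condition for unit tests."""
    base = dict(
        id=901,
        n_nodes=24,
        loading_range=(0.6, 0.9),
        size_scheme=SizeScheme.EQUAL,
        n_communities=3,
        overlap=0.1,
        level_diff=0.0,
        t_obs=200,
    )
    base.update(overrides)
    return CorrCondition(**base)
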