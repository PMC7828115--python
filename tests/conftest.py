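import numpy as np
import pytest

from kmodule import ExpressionMatrix, SyntheticSpec, generate
from kmodule.clustering import ModulePartition


@pytest.fixture
def two_block_diss():
    """6 genes in two perfect blocks: within-dissimilarity 0.1, between 0.9."""
    labels = np.array([1, 1, 1, 2, 2, 2])
    d = np.where(labels[:, None] == labels[None, :], 0.1, 0.9)
    np.fill_diagonal(d, 0.0)
    return d, labels


@pytest.fixture
def two_block_adjacency():
    """6 genes in two blocks: within-adjacency 0.9, between 0.1, zero diagonal."""
    labels = np.array([1, 1, 1, 2, 2, 2])
    a = np.where(labels[:, None] == labels[None, :], 0.9, 0.1)
    np.fill_diagonal(a, 0.0)
    return a, labels


@pytest.fixture
def default_synthetic():
    expr, truth = generate(SyntheticSpec(seed=0))
    return expr, truth


def random_expr(n, m, seed):
    rng = np.random.default_rng(seed)
    return ExpressionMatrix(
        tuple(f"G{i}" for i in range(n)),
        tuple(f"S{j}" for j in range(m)),
        rng.standard_normal((n, m)),
    )


def partition(labels):
    labels = np.asarray(labels, dtype=int)
    return ModulePartition(tuple(f"G{i}" for i in range(len(labels))), labels)
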