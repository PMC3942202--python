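import numpy as np
import pytest

from srclatlrr import (ExpressionMatrix, SubspaceSimConfig,
                       generate_subspace_data, normalize_columns)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def low_rank_normalized(rng):
    """Noiseless rank-3 200x60 matrix with unit-l2 columns."""
    X = rng.standard_normal((200, 3)) @ rng.standard_normal((3, 60))
    X, _ = normalize_columns(X)
    return X


@pytest.fixture
def corrupted_instance(rng):
    """Rank-3 200x60 matrix with sparse +-0.5 spikes on 5% of entries.

    Returns (X, planted support mask); X has unit-l2 columns.
    """
    A = rng.standard_normal((200, 3)) @ rng.standard_normal((3, 60))
    A, _ = normalize_columns(A)
    idx = rng.choice(200 * 60, size=round(0.05 * 200 * 60), replace=False)
    E0 = np.zeros(200 * 60)
    E0[idx] = rng.choice([-0.5, 0.5], size=idx.size)
    X = A + E0.reshape(200, 60)
    X, _ = normalize_columns(X)
    mask = np.zeros(200 * 60, bool)
    mask[idx] = True
    return X, mask.reshape(200, 60)


@pytest.fixture
def clean_subspace_dataset():
    """Three-class orthogonal-subspace data, noiseless (defaults)."""
    em, labels, truth = generate_subspace_data(SubspaceSimConfig(seed=7))
    return em, labels, truth


@pytest.fixture
def small_expression():
    values = np.array([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]])
    return ExpressionMatrix(values=values, gene_ids=["gA", "gB"],
                            sample_ids=["s1", "s2", "s3"])
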