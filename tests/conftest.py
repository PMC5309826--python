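import numpy as np
import pytest

from dpath import ExpressionMatrix, SimConfig, simulate_expression


@pytest.fixture
def tpm_matrix():
    """Small raw-TPM matrix with named genes/cells."""
    rng = np.random.default_rng(42)
    values = rng.gamma(2.0, 10.0, size=(30, 8))
    return ExpressionMatrix(
        values=values,
        gene_ids=[f"g{i:02d}" for i in range(30)],
        cell_ids=[f"c{j}" for j in range(8)],
    )


@pytest.fixture
def small_counts():
    """20 x 10 count fixture used for likelihood-ascent checks."""
    rng = np.random.default_rng(7)
    U = rng.gamma(2.0, 20.0, size=(20, 3))
    V = rng.dirichlet(np.ones(3), size=10).T
    X = rng.poisson(U @ V).astype(float)
    return X


@pytest.fixture
def block_sim():
    """Three well-separated metagenes with disjoint cell blocks.

    Cells are one-hot in the coefficient space and metagene bases have
    disjoint gene supports, so any reasonable factorization separates the
    blocks cleanly."""
    rng = np.random.default_rng(3)
    K, n, m = 3, 90, 24
    U = np.zeros((n, K))
    for k in range(K):
        U[k * 30:(k + 1) * 30, k] = rng.gamma(2.0, 30.0, size=30)
    V = np.zeros((K, m))
    for j in range(m):
        V[j % K, j] = 1.0
    X = rng.poisson(U @ V).astype(float)
    return X, U, V


@pytest.fixture
def default_sim():
    return simulate_expression(SimConfig(seed=11))
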