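import numpy as np
import pytest

from scimpute import CountMatrix, apply_dropout, simulate_complete


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_counts():
    rng = np.random.default_rng(0)
    values = rng.integers(0, 50, size=(20, 8)).astype(float)
    values[0, 0] = 0.0
    return CountMatrix(
        values,
        [f"g{i}" for i in range(20)],
        [f"c{j}" for j in range(8)],
    )


@pytest.fixture(scope="session")
def small_sim():
    """A reduced simulation with dropout, shared across tests."""
    truth = simulate_complete(n_genes=800, cells_per_type=25, de_per_type=25, seed=11)
    return apply_dropout(truth, seed=11)
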