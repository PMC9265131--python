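import numpy as np
import pytest

import milkpredict as mp


@pytest.fixture(scope="session")
def small_herd():
    """300 single-session records from the default (slow) herd."""
    return mp.simulate_herd(mp.slow_cow_config(n_cows=300, sessions_per_cow=1, seed=42))


@pytest.fixture(scope="session")
def toy_model():
    """Two-point LSSVM with a hand-solvable 3x3 KKT system."""
    return mp.train_lssvm(np.array([[0.0], [1.0]]), np.array([-1, 1]), C=1.0, sigma=1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(7)
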