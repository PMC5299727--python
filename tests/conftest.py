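import numpy as np
import pytest

import dmreg


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_dataset():
    """A small simulated dataset with clear signal, shared read-only."""
    cfg = dmreg.SimulationConfig(
        n=40, P=6, J=5, P_r=2, J_r=2, n_assoc=3, psi=0.01, seed=7
    )
    Y, X, truth = dmreg.simulate_dataset(cfg)
    Xs = dmreg.standardize(X)
    return Y, Xs, truth, cfg
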