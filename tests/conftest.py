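import numpy as np
import pytest

from msmcal.config import scenario_config
from msmcal.dgm import Panel, simulate_panel


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def scenario1_panel():
    return simulate_panel(scenario_config(1, seed=77))


@pytest.fixture(scope="session")
def scenario2_panel():
    return simulate_panel(scenario_config(2, seed=77))


@pytest.fixture(scope="session")
def scenario4_panel():
    return simulate_panel(scenario_config(4, seed=77))


def make_panel(V, A, L, Y, X, config=None):
    """Assemble a Panel from plain arrays (test helper)."""
    V = np.asarray(V, dtype=np.int8)
    A = np.asarray(A, dtype=np.int8)
    L = np.asarray(L, dtype=np.int8)
    Y = np.asarray(Y, dtype=float)
    X = np.asarray(X, dtype=float)
    return Panel(
        V=V, A=A, L=L, Y_latent=Y.copy(), Y_obs=Y, X=X,
        eta=np.zeros(V.shape[0]), config=config,
    )
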