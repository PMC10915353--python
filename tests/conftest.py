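import numpy as np
import pytest

from netard import simulate
from netard.pard import standardize


def random_spd(rng: np.random.Generator, p: int) -> np.ndarray:
    """Random well-conditioned SPD matrix."""
    a = rng.standard_normal((p, p))
    return a @ a.T + p * np.eye(p)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240209)


@pytest.fixture(scope="session")
def tiny_hub_dataset():
    """10-gene, 1-hub simulated dataset for fast end-to-end checks."""
    spec = simulate.HubGNSpec(p=10, n_hubs=1, hub_mean_degree=6.0,
                              nonhub_mean_degree=1.0, seed=7)
    x, edges, hubs, omega = simulate.simulate_dataset(spec, n=80)
    return x, edges, hubs, omega


@pytest.fixture(scope="session")
def null_data():
    """Independent standard-normal columns (no network signal)."""
    return simulate.null_expression(n=200, p=10, seed=11)


@pytest.fixture(scope="session")
def std_null_data(null_data):
    return standardize(null_data)
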