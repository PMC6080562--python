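import numpy as np
import pytest

from clustpred import (
    BayesRandomInterceptLogit,
    RandomInterceptLogit,
    SimulationConfig,
    generate_dataset,
)


@pytest.fixture(scope="session")
def default_config():
    """The default study conditions: 50 clusters of 100, beta1=1.5,
    ICC=0.20, 50% prevalence."""
    return SimulationConfig(seed=20180806)


@pytest.fixture(scope="session")
def dev_data(default_config):
    return generate_dataset(default_config, "development")


@pytest.fixture(scope="session")
def small_config():
    """A smaller recipe for fit-level tests (20 clusters of 30)."""
    return SimulationConfig(n_clusters=20, cluster_size=30, seed=7)


@pytest.fixture(scope="session")
def small_data(small_config):
    return generate_dataset(small_config, "development")


@pytest.fixture(scope="session")
def ml_fit_default(dev_data):
    """ML fit on the default development data, shared across tests."""
    return RandomInterceptLogit.from_dataset(dev_data).fit()


@pytest.fixture(scope="session")
def posterior_default(dev_data):
    """A short-burn-in posterior on the default development data (R-hat
    checked), shared across tests."""
    model = BayesRandomInterceptLogit.from_dataset(dev_data)
    return model.fit(burn_in=1000, seed=99)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
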