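import numpy as np
import pytest

from photoacclim.synthetic_data import GeneratorConfig, simulate_experiment


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def noisy_experiment():
    """One default-noise synthetic experiment, shared across tests."""
    return simulate_experiment(GeneratorConfig(seed=0))


@pytest.fixture(scope="session")
def noiseless_experiment():
    return simulate_experiment(GeneratorConfig(seed=0), noiseless=True)
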