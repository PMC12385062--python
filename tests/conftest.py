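import numpy as np
import pytest

from pepal.synthetic import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def tiny_dataset():
    """40-sample synthetic dataset with profiles, for unit tests."""
    cfg = SyntheticConfig(n_samples=40, seed=101)
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def small_dataset():
    """500-sample synthetic dataset with profiles, for integration tests."""
    cfg = SyntheticConfig(n_samples=500, seed=11)
    return generate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
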