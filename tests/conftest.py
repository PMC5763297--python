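import numpy as np
import pytest

from gruf.graph_regression import GrufRegressor
from gruf.synthetic_data import GeneratorConfig, generate_planted_dataset


@pytest.fixture(scope="session")
def planted():
    """Desk-scale planted benchmark with clean side information."""
    return generate_planted_dataset(GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def planted_noisy():
    """Same conditions with the similarity signal destroyed (noise >> signal)."""
    return generate_planted_dataset(GeneratorConfig(seed=1, noise_sd=10.0))


@pytest.fixture()
def oracle_model():
    """Model at the planted latent dimension (oracle rank for recovery runs)."""
    return GrufRegressor(rank_assoc=5, rank_lncrna=5, rank_disease=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
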