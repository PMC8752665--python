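import numpy as np
import pytest

from temporient import synthetic_data as sd


@pytest.fixture(scope="session")
def small_population():
    """A small deterministic corpus with latent truth, shared across tests."""
    spec = sd.PopulationSpec(n_users=20, tweets_per_user=10, seed=7)
    tweets, truth = sd.simulate_corpus(spec)
    return spec, tweets, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
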