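import numpy as np
import pytest

from noisylex.lexicon import generate_synthetic_lexicon
from noisylex.tasks import train_model_versions


@pytest.fixture(scope="session")
def small_lexicon():
    """20 translation pairs; used for fast structural and oracle tests."""
    return generate_synthetic_lexicon(
        n_pairs=20, disyllabic_counts={"A": 7, "B": 8}, seed=11)


@pytest.fixture(scope="session")
def small_models(small_lexicon):
    """Briefly trained native/non-native versions on the 20-pair lexicon.

    Training is short: these models are for oracle-equivalence and
    plumbing tests, not for ceiling performance.
    """
    return train_model_versions(
        small_lexicon, n_replications=1, pretrain_epochs=10, epochs=200,
        seed=5)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
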