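import numpy as np
import pytest


@pytest.fixture(scope="session")
def small_balanced_dataset():
    """Pooled spectrograms of a small balanced synthetic cohort.

    1200 epochs over 12 subjects, frequency bins pooled 128 -> 32 so the
    reduced-size model configuration applies. Shared across the training
    tests to amortize generation cost.
    """
    from mcafnet.synthetic_psg import generate_dataset
    from mcafnet.tf_representation import StftConfig, epochs_to_dataset

    ds = generate_dataset(1200, 12, seed=42)
    X, y, subjects = epochs_to_dataset(ds.epochs, StftConfig(), pool_factor=4)
    return X, y, subjects


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
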