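import numpy as np
import pytest

import libspect as ls


@pytest.fixture(scope="session")
def small_config():
    """Compact noisy benchmark: 4 classes x 30 spectra, 800 channels."""
    return ls.default_config(
        n_classes=4, spectra_per_class=30, n_channels=800, seed=7
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return ls.simulate_dataset(small_config)


@pytest.fixture(scope="session")
def small_split(small_dataset):
    return ls.split_dataset(small_dataset, seed=7)


@pytest.fixture(scope="session")
def noiseless_small():
    """Noise-free 4-class dataset: spectra within a class are identical."""
    cfg = ls.noiseless_config(
        n_classes=4, spectra_per_class=20, n_channels=800, seed=5
    )
    return ls.simulate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
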