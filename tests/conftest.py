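import numpy as np
import pytest

from har_locator.preprocess import fit_unmix, unmix_lin
from har_locator.synthetic import SynthConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """14 synthetic images (2 per class) at 96 px, for unit tests."""
    return generate_dataset(SynthConfig(n_per_class=2, image_size=96, seed=11))


@pytest.fixture(scope="session")
def sample_pair(small_dataset):
    """One unmixed ChannelPair (an ER image: rich texture in both channels)."""
    s = small_dataset[2]
    model = fit_unmix(s.image)
    return unmix_lin(s.image, model)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
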