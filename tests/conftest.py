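import numpy as np
import pytest

from grapetex.datasets import generate_synthetic_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A 20-image (4 per class) synthetic dataset shared across tests."""
    return generate_synthetic_dataset(n_per_class=4, image_size=64, seed=5)


@pytest.fixture
def rng():
    return np.random.default_rng(123)
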