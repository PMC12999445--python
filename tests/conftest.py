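import numpy as np
import pytest

from dermagents.model import synthesize_dataset
from dermagents.training import build_samples


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def benign_image():
    from dermagents import generate_lesion

    return generate_lesion(0, seed=1)


@pytest.fixture(scope="session")
def malignant_image():
    from dermagents import generate_lesion

    return generate_lesion(1, seed=1)


@pytest.fixture(scope="session")
def small_dataset():
    """20 images (10 per class), shared across tests."""
    return synthesize_dataset(10, seed=3)


@pytest.fixture(scope="session")
def small_samples(small_dataset):
    return build_samples(small_dataset)


@pytest.fixture(scope="session")
def dataset_200():
    """200 images (100 per class) for separability-style checks."""
    return synthesize_dataset(100, seed=5)
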