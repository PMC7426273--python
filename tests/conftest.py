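import numpy as np
import pytest

from bireplay import SyntheticConfig, build_split_protocol, generate_synthetic_set


@pytest.fixture(scope="session")
def synthetic_pair():
    """Small, easily separable synthetic image set shared across tests."""
    cfg = SyntheticConfig(n_classes=6, images_per_class_train=60,
                          images_per_class_test=30, image_size=8, seed=7)
    return generate_synthetic_set(cfg)


@pytest.fixture(scope="session")
def split_protocol(synthetic_pair):
    train, test = synthetic_pair
    return build_split_protocol(train, test, 3, 2, scenario="class_il")


@pytest.fixture
def rng():
    return np.random.default_rng(123)
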