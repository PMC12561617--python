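import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_images():
    """Small synthetic 3-class set shared by protocol tests."""
    from ansa_edge.synthetic import generate_synthetic_dataset

    return generate_synthetic_dataset(n_per_class=12, num_classes=3, size=32, seed=7)
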