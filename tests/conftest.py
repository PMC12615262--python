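import numpy as np
import pytest

from scprofile.backbone import ModelGeometry, make_mini_backbone
from scprofile.decoder import ProfileModel


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_geometry():
    return ModelGeometry(input_length=1024, bin_width=32, output_bins=16,
                         embedding_width=12)


@pytest.fixture
def small_backbone(small_geometry):
    return make_mini_backbone(small_geometry, channels=8, n_layers=1, seed=3)


@pytest.fixture
def small_model(small_backbone):
    return ProfileModel(small_backbone, embedding_dim=14, hypernet_hidden=16,
                        seed=5)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Session-scoped synthetic multiome fixture (shared, read-only)."""
    from scprofile.simulate import make_tiny_dataset

    return make_tiny_dataset(seed=1)
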