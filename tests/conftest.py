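import numpy as np
import pytest

from gastromil import FeatureBag, ModelConfig, SyntheticCohortSpec
from gastromil.model import MILModel


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_spec():
    """Desk-scale cohort spec: low feature dim, small bags, easy separation."""
    return SyntheticCohortSpec(
        dim=32, bag_size_range=(16, 48), separation=3.0, seed=11
    )


@pytest.fixture
def small_model():
    cfg = ModelConfig(
        input_dim=32, embed_dim=24, attn_dim=12, hidden_dim=8, n_classes=4, seed=5
    )
    return MILModel(cfg)


def random_bag(rng, m=20, d=32, slide_id="bag"):
    coords = np.stack([np.arange(m) * 256, np.zeros(m, dtype=int)], axis=1)
    return FeatureBag(
        slide_id=slide_id,
        features=rng.standard_normal((m, d)).astype(np.float32),
        coords=coords,
    )


@pytest.fixture
def make_bag(rng):
    def _make(m=20, d=32, slide_id="bag"):
        return random_bag(rng, m, d, slide_id)

    return _make
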