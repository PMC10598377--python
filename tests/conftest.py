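import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_encoder_config():
    """Two-stage miniature encoder for fast unit tests."""
    from mvfusion import EncoderConfig

    return EncoderConfig(
        stem_channels=4,
        block_channels=(4, 8),
        blocks_per_stage=(1, 1),
        embedding_dim=8,
    )


@pytest.fixture
def tiny_phantom_spec():
    """Small, quick phantom dataset spec (12 cases of 8x16x16, 2 views)."""
    from mvfusion import PhantomSpec

    return PhantomSpec(
        n_views=2,
        shape=(8, 16, 16),
        n_cases=12,
        view_informativeness=(0.5, 0.5),
        seed=7,
    )
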