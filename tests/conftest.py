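import numpy as np
import pytest

from gnet.synthetic_data import PhantomSpec


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_spec():
    """A 64x64 phantom spec small enough to train on in tests."""
    return PhantomSpec(image_size=(64, 64), seed=7)


@pytest.fixture
def tiny_config_kwargs():
    """The smallest architecture that still exercises every block."""
    return dict(encoder_filters=(4, 8, 16), spp_pool_sizes=(2, 4),
                spp_filters_per_level=8, input_size=(32, 32))
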