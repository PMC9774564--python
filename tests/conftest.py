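import numpy as np
import pytest

from maskcolor.networks import NetworkConfig
from maskcolor.phantom import PhantomSpec, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_net_cfg():
    """Smallest network configuration that exercises every layer type."""
    return NetworkConfig(image_size=16, base_channels=2, n_residual_blocks=2, n_downsample=1)


@pytest.fixture
def tiny_spec():
    """16x16 phantoms for fast training smoke tests."""
    return PhantomSpec(height=16, width=16, n_blobs=2, noise_sd=0.0, seed=99)


@pytest.fixture
def tiny_samples(tiny_spec):
    return [generate_phantom(tiny_spec, i) for i in range(4)]
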