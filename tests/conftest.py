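import numpy as np
import pytest

from cbct2ct import ArtifactParams, PhantomConfig, generate_anatomy
from cbct2ct.transformer import NetworkConfig


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def tiny_net_cfg():
    """Smallest sensible network: C0=8, M=4, two blocks per stage."""
    return NetworkConfig(base_channels=8, window_size=4,
                         heads=(1, 2, 4, 8, 8), leff_expansion=2)


@pytest.fixture(scope="session")
def small_phantom():
    """64-px phantom slice with masks, shared across tests."""
    cfg = PhantomConfig(image_size=64, seed=11)
    ct, masks = generate_anatomy(cfg)
    return cfg, ct, masks


@pytest.fixture(scope="session")
def default_artifacts():
    return ArtifactParams(seed=7)
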