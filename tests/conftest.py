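import numpy as np
import pytest

from lesionsynth.model import NetworkConfig
from lesionsynth.phantom import PhantomSpec, generate_dataset


def toy_network(side: int = 16) -> NetworkConfig:
    """Small network preset used throughout the CPU test suite."""
    return NetworkConfig(
        side=side, base_channels=4, n_levels=2, latent_dim=32, embed_hidden=4
    )


def toy_phantom_spec(seed: int = 11, side: int = 16) -> PhantomSpec:
    return PhantomSpec(
        side=side,
        volume_range=(30, 400),
        n_lobes=3,
        texture_contrast=0.35,
        background_smoothness=2.0,
        seed=seed,
    )


@pytest.fixture(scope="session")
def small_dataset():
    """Eight deterministic phantoms at side 16 for fast training tests."""
    return generate_dataset(8, toy_phantom_spec(seed=5))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
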