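import numpy as np
import pytest

from lipidmsi.phantom import PhantomConfig, default_config


@pytest.fixture(scope="session")
def small_config() -> PhantomConfig:
    """A reduced phantom (48x32 grid, 12 decoys) for fast structural tests."""
    return default_config(n_decoys=12, ncol=48, nrow=32)


@pytest.fixture(scope="session")
def clean_config() -> PhantomConfig:
    """Noise-free, jitter-free phantom: expectations hold exactly."""
    return default_config(
        n_decoys=12, ncol=48, nrow=32,
        jitter_ppm=0.0, noise_sd=0.0, section_rel_sd=0.0,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
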