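import numpy as np
import pytest
from hypothesis import settings

from hyperclass import SceneConfig, generate_scene

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def clean_scene():
    """A small zero-noise, flat-illumination scene: FFC recovers the
    signature spectra up to count rounding."""
    cfg = SceneConfig(
        height=128,
        width=128,
        n_neurons=3,
        n_glia=1,
        noise_sd=0.0,
        illumination_amplitude=0.0,
        seed=11,
    )
    return cfg, generate_scene(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
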