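import numpy as np
import pytest

from leaftrack import SceneSpec, generate_sequence


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_scene():
    """A short, low-noise synthetic sequence with its ground truth."""
    spec = SceneSpec(image_size=(200, 160), n_frames=12, noise_sd=0.005,
                     growth_rate_percent_per_hour=2.0, seed=7)
    seq, truth = generate_sequence(spec)
    return spec, seq, truth


@pytest.fixture(scope="session")
def static_scene():
    """Zero growth, zero noise: every frame identical."""
    spec = SceneSpec(image_size=(200, 160), n_frames=10, noise_sd=0.0,
                     growth_rate_percent_per_hour=0.0, seed=1)
    seq, truth = generate_sequence(spec)
    return spec, seq, truth
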