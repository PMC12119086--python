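import logging

import numpy as np
import pytest

from hemoccl import SceneConfig, simulate_scene

logging.disable(logging.WARNING)


@pytest.fixture(scope="session")
def clean_scene():
    """Noise-free 2-minute standard scene with every event type."""
    cfg = SceneConfig(duration_s=120.0, n_mismatch=4, n_opto=3,
                      mean_bout_s=12.0, mean_rest_s=10.0, seed=0)
    return simulate_scene(cfg)


@pytest.fixture(scope="session")
def jitter_scene():
    """Noise-free scene with injected integer-pixel rigid jitter."""
    cfg = SceneConfig(duration_s=20.0, n_mismatch=0, n_opto=0,
                      grating_interval_s=6.0, jitter_amplitude_px=3, seed=1)
    return simulate_scene(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
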