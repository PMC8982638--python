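import numpy as np
import pytest

import mbassay as mb


@pytest.fixture(scope="session")
def short_session():
    """A 60-s synthetic session with known bouts, shared across tests."""
    spec = mb.SessionSpec(duration_s=60.0, fps=25.0, n_bouts=3, seed=42)
    track, truth = mb.make_trajectory(spec)
    return spec, track, truth


@pytest.fixture(scope="session")
def rendered_session():
    """A short noise-free rendered stack with its ground truth."""
    spec = mb.SessionSpec(
        duration_s=16.0, fps=25.0, n_bouts=1, bout_duration_s_mean=2.0,
        bout_duration_s_sd=0.5, seed=5,
    )
    track, truth = mb.make_trajectory(spec)
    stack = mb.render_frames(track, spec, noise_sd=0.0, seed=5)
    return spec, track, truth, stack


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
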