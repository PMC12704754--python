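import numpy as np
import pytest

from spcold import simkit


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def heptamer():
    return simkit.build_heptamer_model(3.5)


@pytest.fixture(scope="session")
def preset_8k():
    return simkit.PRESETS["8K"]


@pytest.fixture(scope="session")
def single_emitter_stack():
    """One bright in-plane emitter at 45 deg rendered with noise."""
    rng = np.random.default_rng(7)
    optics = simkit.OpticsConfig()
    model = simkit.build_nanoruler_model(0.0).subset([0])
    n_frames = 100
    # low duty cycle: the background/noise estimates assume blinking
    on = np.array([[0.0, 15 * optics.frame_time_s]])
    scene = simkit.SceneInstance(
        model, np.eye(3), np.array([1600.0, 1500.0]),
        np.array([45.0]), np.array([1.0]),
        [simkit.StateTrace(on, n_frames * optics.frame_time_s)],
        photon_rate_per_s=20000.0)
    pair = simkit.render_stack([scene], optics, n_frames, (32, 32), rng)
    return pair, scene
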