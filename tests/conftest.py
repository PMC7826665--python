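import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

from lidargait.simulate import make_scene, single_walker_scene, crossing_scene
from lidargait.tracking import track_frames


@pytest.fixture(scope="session")
def noisefree_walk():
    """Zero-noise single walker at 15 Hz: frames, ground truth, tracker."""
    cfg = single_walker_scene(range_noise_sd=0.0, seed=1)
    frames, truth = make_scene(cfg)
    tracker = track_frames(frames, cfg.sensor)
    return cfg, frames, truth, tracker


@pytest.fixture(scope="session")
def noisy_walk():
    """Default single-walker scene (1.2 m/s, cadence 110, 10 mm noise)."""
    cfg = single_walker_scene(range_noise_sd=10.0, seed=1)
    frames, truth = make_scene(cfg)
    tracker = track_frames(frames, cfg.sensor)
    return cfg, frames, truth, tracker


@pytest.fixture(scope="session")
def crossing_run():
    """Three-walker crossing scene with occlusions."""
    cfg = crossing_scene(seed=1)
    frames, truth = make_scene(cfg)
    tracker = track_frames(frames, cfg.sensor)
    return cfg, frames, truth, tracker
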