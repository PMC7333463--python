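import numpy as np
import pytest

from califlow import simulate


@pytest.fixture(scope="session")
def blob_texture():
    """A 400x400 frame of smooth bright blobs on black, for warp tests."""
    rng = np.random.default_rng(0)
    yy, xx = np.mgrid[0:400, 0:400]
    frame = np.zeros((400, 400))
    for _ in range(100):
        y, x = rng.integers(20, 380, 2)
        r = rng.integers(2, 5)
        frame = np.maximum(
            frame, 150 * np.exp(-((yy - y) ** 2 + (xx - x) ** 2) / (2 * r ** 2)))
    return frame


@pytest.fixture(scope="session")
def small_bundle():
    """A small noisy simulated dataset with injected motion (30 neurons,
    250x250, 150 frames) shared across integration-style tests."""
    cfg = simulate.SimConfig(
        n_neurons=30, n_frames=150, grid=(250, 250),
        motion=simulate.MotionConfig(p_rot=25, alpha_rot=6.3153),
        noise=simulate.NoiseConfig.from_label("s03c05"))
    return simulate.simulate_bundle(cfg, 11)


@pytest.fixture(scope="session")
def still_bundle():
    """Motion-free, noise-free small dataset (ground-truth-friendly)."""
    cfg = simulate.SimConfig(n_neurons=20, n_frames=120, grid=(200, 200),
                             motion=simulate.MotionConfig(translation_range=0))
    return simulate.simulate_bundle(cfg, 5)
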