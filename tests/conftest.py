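import pytest

from mothtrap.synthetic import SceneConfig, generate_scene


@pytest.fixture(scope="session")
def clean_scene():
    """5 well-separated, mostly stationary insects over 50 frames, no transients."""
    cfg = SceneConfig(n_insects=5, n_frames=50, seed=1)
    frames, truth = generate_scene(cfg)
    background, _ = generate_scene(
        SceneConfig(n_insects=0, n_frames=1, seed=1))
    return frames, background[0], truth


@pytest.fixture(scope="session")
def small_scene():
    """3 insects over 12 smaller frames, for fast unit tests."""
    cfg = SceneConfig(frame_height=540, frame_width=960, n_insects=3, n_frames=12,
                      blob_mean=(180.0, 170.0), blob_sd=30.0, min_blob_side=100,
                      seed=7)
    frames, truth = generate_scene(cfg)
    background, _ = generate_scene(
        SceneConfig(frame_height=540, frame_width=960, n_insects=0, n_frames=1, seed=7))
    return frames, background[0], truth
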