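import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import posemotion as pm

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20210219)


@pytest.fixture
def toy3():
    """A 3-point model for hand-checkable examples."""
    return pm.KeypointModelSpec("toy3", 3, ("a", "b", "c"), "pose_keypoints_2d")


def make_sequence(x, y, c=None, model=pm.BODY25, fps=25.0, source_id="clip"):
    """Build a PoseSequence from (n_frames, n_points) arrays; c defaults to 1."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if c is None:
        c = np.ones_like(x)
    return pm.PoseSequence(model, x, y, c, fps=fps, source_id=source_id)


def random_sequence(rng, n_frames, n_points=25, model=pm.BODY25, fps=25.0):
    """Random positions in a 640x480 frame with full confidence."""
    x = rng.uniform(0, 640, (n_frames, n_points))
    y = rng.uniform(0, 480, (n_frames, n_points))
    return pm.PoseSequence(model, x, y, np.ones_like(x), fps=fps)


@pytest.fixture
def linear_clip(tmp_path):
    """Synthetic 125-frame clip, every point drifting (1, 0) px/frame."""
    spec = pm.TrajectorySpec(
        n_frames=125,
        fps=25.0,
        default_program=pm.MotionProgram("linear", dx=1.0),
        source_id="drift",
    )
    out = tmp_path / "frames"
    seq, truth = pm.generate(spec, out_dir=out)
    return spec, seq, truth, out
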