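import numpy as np
import pytest

from facemark3d import FaceParams, generate_face


@pytest.fixture(scope="session")
def small_face():
    """One deterministic synthetic face at modest sampling density."""
    return generate_face(FaceParams(n_points=2000, seed=42))


@pytest.fixture(scope="session")
def symmetric_face():
    """Perfectly symmetric face: no asymmetry, no pose, no noise."""
    return generate_face(FaceParams(n_points=2000, seed=7, asymmetry=0.0,
                                    pose_x=0.0, pose_y=0.0, pose_z=0.0,
                                    noise_sd=0.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
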