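import numpy as np
import pytest

from gastropano import build_scene, face_sweep_loop, render_sequence
from gastropano.camera import CameraModel


@pytest.fixture(scope="session")
def cam():
    """Small pinhole camera used by most rendering tests."""
    return CameraModel(
        fx=130.0, fy=130.0, cx=79.5, cy=59.5, width=160, height=120,
        distortion="none",
    )


@pytest.fixture(scope="session")
def scene():
    return build_scene(seed=0, tex_pitch=3.0)


@pytest.fixture(scope="session")
def translation_pair(scene, cam):
    """Noiseless fronto-parallel pair: truth homography is a -10 px shift."""
    face = scene.model.face("A-y")
    d = 25.0
    poses = []
    for i, off in enumerate([0.45 * face.su, 0.45 * face.su + 10 * d / cam.fx]):
        surf = face.origin + face.u * off + face.v * 0.5 * face.sv
        from gastropano.phantom import look_at

        R, t = look_at(surf + face.normal * d, -face.normal, -face.v)
        poses.append((R, t, i))
    from gastropano.phantom import CameraTrajectory

    return render_sequence(scene, CameraTrajectory(poses), cam)


@pytest.fixture(scope="session")
def loop_sequence(scene, cam):
    """Noiseless 9-frame out-and-back loop over one face."""
    traj = face_sweep_loop(scene.model, "A-y", n_frames=9, distance_mm=25.0)
    return render_sequence(scene, traj, cam)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
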