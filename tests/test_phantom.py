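import numpy as np
import pytest
from scipy import ndimage

from gastropano import (
    CameraTrajectory,
    PolypSpec,
    augment_gaussian,
    build_scene,
    face_sweep_loop,
    render_sequence,
)
from gastropano.phantom import look_at, truth_panorama_transforms


def _static_pose(scene, face_id="A-y", d=25.0):
    face = scene.model.face(face_id)
    surf = face.uv_to_world([[0.5, 0.5]])[0]
    return look_at(surf + face.normal * d, -face.normal, -face.v)


class TestBuildScene:
    def test_no_polyps_gives_textured_faces_only(self):
        sc = build_scene(seed=0)
        assert len(sc.face_textures) >= 11
        assert sc.polyps == []

    def test_same_seed_bit_identical_textures(self):
        a = build_scene(seed=0)
        b = build_scene(seed=0)
        for fid in a.face_textures:
            assert (a.face_textures[fid] == b.face_textures[fid]).all()

    def test_different_seed_differs(self):
        a = build_scene(seed=0)
        b = build_scene(seed=1)
        assert not (a.face_textures["A-y"] == b.face_textures["A-y"]).all()

    def test_polyp_outside_face_rejected(self):
        with pytest.raises(ValueError, match="polyp 0 on face A-y"):
            build_scene(seed=0, polyps=[PolypSpec("A-y", (0.98, 0.5), 4.0)])

    def test_polyp_radius_exceeding_half_width_rejected(self):
        with pytest.raises(ValueError, match="polyp"):
            build_scene(seed=0, polyps=[PolypSpec("A-y", (0.5, 0.5), 40.0)])

    def test_polyp_brightens_texture_locally(self):
        plain = build_scene(seed=0)
        with_p = build_scene(seed=0, polyps=[PolypSpec("A-y", (0.5, 0.5), 6.0)])
        diff = with_p.face_textures["A-y"] - plain.face_textures["A-y"]
        assert diff.max() > 0.1
        # perturbation confined to the disc neighbourhood
        h, w = diff.shape
        assert np.abs(diff[: h // 4]).max() < 1e-12


class TestRenderSequence:
    def test_static_camera_identity_truth(self, scene, cam):
        R, t = _static_pose(scene)
        seq = render_sequence(scene, CameraTrajectory([(R, t, 0), (R, t, 1)]), cam)
        assert (seq.frames[0].gray == seq.frames[1].gray).all()
        H = seq.pair_homographies[0]["A-y"]
        assert np.allclose(H, np.eye(3), atol=1e-9)

    def test_pure_translation_truth_homography_warp_oracle(self, translation_pair):
        """Warping frame 0 by the truth homography reproduces frame 1.

        The camera step is chosen so the truth translation is exactly
        -10 px, making the warp an integer shift with no resampling.
        """
        H = translation_pair.pair_homographies[0]["A-y"]
        assert np.allclose(H[:2, :2], np.eye(2), atol=1e-9)
        assert abs(H[0, 2] + 10.0) < 1e-6 and abs(H[1, 2]) < 1e-6
        f0 = translation_pair.frames[0].gray
        f1 = translation_pair.frames[1].gray
        warped = np.roll(f0, -10, axis=1)
        diff = np.abs(warped[:, :-10] - f1[:, :-10])
        assert diff.mean() < 1e-6

    def test_truth_homographies_reproject_face_points(self, scene, cam, translation_pair):
        H = translation_pair.pair_homographies[0]["A-y"]
        face = scene.model.face("A-y")
        uv = np.stack(np.meshgrid(np.linspace(0.35, 0.55, 5), np.linspace(0.3, 0.7, 5)), -1).reshape(-1, 2)
        world = face.uv_to_world(uv)
        (R0, t0), (R1, t1) = translation_pair.poses
        p0, _ = cam.project(world @ R0.T + t0)
        p1, _ = cam.project(world @ R1.T + t1)
        proj = (np.hstack([p0, np.ones((len(p0), 1))]) @ H.T)
        proj = proj[:, :2] / proj[:, 2:]
        assert np.linalg.norm(proj - p1, axis=1).max() < 0.5

    def test_loop_truth_transforms_compose_to_identity(self, loop_sequence):
        L = np.eye(3)
        for d in loop_sequence.pair_homographies:
            L = d["A-y"] @ L
        assert np.abs(L / L[2, 2] - np.eye(3)).max() < 1e-6

    def test_determinism_bit_identical(self, scene, cam):
        traj = face_sweep_loop(scene.model, "A-y", n_frames=5)
        a = render_sequence(scene, traj, cam, noise_scalar=0.05, specular_count=1)
        b = render_sequence(scene, traj, cam, noise_scalar=0.05, specular_count=1)
        for fa, fb in zip(a.frames, b.frames):
            assert (fa.gray == fb.gray).all()

    def test_standard_noise_grid_accepted(self, scene, cam):
        R, t = _static_pose(scene)
        for s in (0.01, 0.05, 0.1, 0.2, 0.5):
            seq = render_sequence(
                scene, CameraTrajectory([(R, t, 0), (R, t, 1)]), cam, noise_scalar=s
            )
            assert seq.noise_scalar == s

    def test_noise_applied_after_truth(self, scene, cam):
        R, t = _static_pose(scene)
        seq = render_sequence(
            scene, CameraTrajectory([(R, t, 0), (R, t, 1)]), cam, noise_scalar=0.1
        )
        # truth still identity even though the frames now differ
        assert np.allclose(seq.pair_homographies[0]["A-y"], np.eye(3), atol=1e-9)
        assert not (seq.frames[0].gray == seq.frames[1].gray).all()

    def test_specular_spots_recorded_and_bright(self, scene, cam):
        R, t = _static_pose(scene)
        clean = render_sequence(scene, CameraTrajectory([(R, t, 0)]), cam)
        spotty = render_sequence(
            scene, CameraTrajectory([(R, t, 0)]), cam, specular_count=2
        )
        assert len(spotty.specular_spots) == 2
        assert spotty.frames[0].gray.max() >= clean.frames[0].gray.max()

    def test_pose_outside_cavity_rejected(self, scene, cam):
        R, t = look_at(np.array([-10.0, 30.0, 30.0]), [1, 0, 0], [0, 0, 1])
        with pytest.raises(ValueError, match="outside the cavity"):
            render_sequence(scene, CameraTrajectory([(R, t, 0)]), cam)

    def test_negative_noise_rejected(self, scene, cam):
        R, t = _static_pose(scene)
        with pytest.raises(ValueError):
            render_sequence(scene, CameraTrajectory([(R, t, 0)]), cam, noise_scalar=-0.1)


class TestTrajectories:
    def test_loop_closed_requires_matching_endpoints(self, scene):
        R, t = _static_pose(scene)
        R2, t2 = _static_pose(scene, d=30.0)
        with pytest.raises(ValueError, match="same pose"):
            CameraTrajectory([(R, t, 0), (R2, t2, 1)], loop_closed=True)

    def test_face_sweep_loop_closes(self, scene):
        traj = face_sweep_loop(scene.model, "A-y", n_frames=8)
        R0, t0, _ = traj.poses[0]
        R1, t1, _ = traj.poses[-1]
        assert np.allclose(R0, R1) and np.allclose(t0, t1)

    def test_truth_panorama_transforms_match_homographies(self, loop_sequence):
        Ts = truth_panorama_transforms(loop_sequence, "A-y")
        assert len(Ts) == len(loop_sequence.frames)
        # frame 0 is the reference
        assert np.allclose(Ts[0].params, [1, 0, 0, 0])
        # last frame returns to the reference (loop)
        assert np.abs(Ts[-1].params - [1, 0, 0, 0]).max() < 1e-6


class TestAugmentGaussian:
    def test_vanishing_scale_is_identity(self, scene):
        img = scene.face_textures["A-y"]
        (out,) = augment_gaussian(img, [1e-6])
        assert np.abs(out - img).max() < 1e-3

    def test_constant_image_unchanged(self):
        img = np.full((32, 32), 0.4)
        (out,) = augment_gaussian(img, [3.0])
        assert np.allclose(out, img)

    def test_delta_impulse_matches_explicit_kernel(self):
        img = np.zeros((41, 41))
        img[20, 20] = 1.0
        (out,) = augment_gaussian(img, [2.0])
        yy, xx = np.mgrid[0:41, 0:41]
        expect = ndimage.gaussian_filter(img, 2.0, mode="nearest")
        # central region also matches the analytic sampled Gaussian
        g = np.exp(-((yy - 20) ** 2 + (xx - 20) ** 2) / (2 * 2.0**2))
        g /= g.sum()
        assert np.abs(out - expect).max() < 1e-12
        assert np.abs(out[10:31, 10:31] - g[10:31, 10:31]).max() < 1e-4

    def test_one_output_per_scale(self):
        outs = augment_gaussian(np.zeros((8, 8)), [0.5, 1.0, 2.0])
        assert len(outs) == 3

    def test_nonpositive_scale_rejected(self):
        with pytest.raises(ValueError):
            augment_gaussian(np.zeros((8, 8)), [1.0, 0.0])


def test_sequence_save_round_trip(tmp_path, scene, cam):
    traj = face_sweep_loop(scene.model, "A-y", n_frames=5)
    seq = render_sequence(scene, traj, cam)
    seq.save(tmp_path)
    import json

    truth = json.loads((tmp_path / "truth.json").read_text())
    assert len(truth["poses"]) == 5
    assert len(truth["pair_homographies"]) == 4
    assert sorted(p.name for p in tmp_path.glob("frame_*.png"))[0] == "frame_00000.png"
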