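import numpy as np
import pytest

from gastropano import fusion as fu
from gastropano.phantom import truth_panorama_transforms
from gastropano.transforms import Similarity4


@pytest.fixture(scope="module")
def sweep(loop_sequence):
    imgs = [f.gray for f in loop_sequence.frames]
    truth = truth_panorama_transforms(loop_sequence, "A-y")
    return imgs, truth


class TestSeamResiduals:
    def test_identical_images_identity_zero(self, rng):
        img = rng.uniform(0, 1, (40, 60))
        r = fu.seam_residuals(img, img, Similarity4.identity(), stride=1)
        assert np.abs(r.e).max() < 1e-12
        assert len(r) == 40 * 60

    def test_constant_offset_sign_convention(self, rng):
        prev = rng.uniform(0.2, 0.7, (40, 60))
        img = prev - 0.1  # e = I_i - I_{i-1} = -0.1
        r = fu.seam_residuals(img, prev, Similarity4.identity())
        assert np.allclose(r.e, -0.1, atol=1e-12)

    def test_truth_transform_on_phantom_pair(self, sweep):
        imgs, truth = sweep
        rel = truth[0].inverse().compose(truth[1])
        r = fu.seam_residuals(imgs[1], imgs[0], rel)
        assert np.abs(r.e).mean() < 2 / 255

    def test_empty_overlap_raises(self, rng):
        img = rng.uniform(0, 1, (40, 60))
        far = Similarity4(1, 0, 1000.0, 0)
        with pytest.raises(ValueError, match="empty overlap"):
            fu.seam_residuals(img, img, far)


class TestEnergy:
    def test_hand_computed_residual_energy(self):
        e = np.array([0.1, -0.2, 0.0])
        assert np.isclose(fu.energy_terms(e, 1.0, 0.0, np.zeros(4)), 0.05)

    def test_hand_computed_regularizer_energy(self):
        assert np.isclose(
            fu.energy_terms(np.zeros(3), 1.0, 1.0, np.array([0.0, 0, 3, 4])), 25.0
        )

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            fu.energy_terms(np.array([np.nan]), 1.0, 0.0, np.zeros(4))

    def test_zero_at_perfect_alignment(self, rng):
        img = rng.uniform(0, 1, (40, 60))
        state = fu.fuse(
            [img, img],
            [Similarity4.identity(), Similarity4.identity()],
            fu.FusionConfig(beta=0.0, max_alt_iters=1),
        )
        assert state.energy_history[0] == 0.0
        assert fu.fusion_energy(state) == 0.0


class TestOptimizeColors:
    def _blank_state(self, imgs, transforms, **kw):
        cfg = fu.FusionConfig(**kw)
        from gastropano.fusion import _canvas_geometry

        origin, shape = _canvas_geometry(imgs, transforms, cfg.margin_px)
        return fu.FusionState(
            images=list(imgs),
            masks=[np.ones(i.shape, bool) for i in imgs],
            base_transforms=transforms,
            corrections=[Similarity4.identity() for _ in imgs],
            config=cfg, origin=origin, shape=shape,
        )

    def test_single_image_reproduced(self, rng):
        img = rng.uniform(0, 1, (30, 40))
        st = self._blank_state([img], [Similarity4.identity()])
        fu.optimize_colors(st)
        y0 = int(-st.origin[1])
        x0 = int(-st.origin[0])
        assert np.allclose(st.canvas[y0 : y0 + 30, x0 : x0 + 40], img, atol=1e-12)

    def test_two_equal_weight_contributions_average(self):
        a = np.full((20, 20), 0.2)
        b = np.full((20, 20), 0.4)
        st = self._blank_state([a, b], [Similarity4.identity()] * 2)
        fu.optimize_colors(st)
        v = st.weight_sum > 0
        assert np.allclose(st.canvas[v], 0.3, atol=1e-12)

    def test_weighted_mean(self):
        """Weights (1, 3) on values (0.0, 0.4) average to 0.3."""
        a = np.full((20, 20), 0.0)
        b = np.full((20, 20), 0.4)
        st = self._blank_state([a, b], [Similarity4.identity()] * 2)
        fu.optimize_colors(st)
        # reweight image b's splat by 3
        cb, wb = st.contributions[1]
        st.canvas = (st.contributions[0][0] + 3 * cb) / np.maximum(
            st.contributions[0][1] + 3 * wb, 1e-12
        )
        v = st.weight_sum > 0
        assert np.allclose(st.canvas[v], 0.3, atol=1e-9)

    def test_color_conservation(self, sweep):
        imgs, truth = sweep
        state = fu.fuse(imgs, truth, fu.FusionConfig(max_alt_iters=0))
        v = state.weight_sum > 0
        canvas_mass = float((state.canvas * state.weight_sum)[v].sum())
        contrib_mass = float(sum(c.sum() for c, _ in state.contributions))
        assert np.isclose(canvas_mass, contrib_mass, rtol=1e-9)


class TestOptimizeTransform:
    def test_start_at_truth_stays(self, sweep):
        imgs, truth = sweep
        state = fu.fuse(imgs[:3], truth[:3], fu.FusionConfig(max_alt_iters=0, pairwise_init=False))
        before = state.transforms[1].params.copy()
        fu.optimize_transform(state, 1)
        assert np.abs(state.transforms[1].params - before).max() < 1e-2

    def test_translation_offset_recovered(self, sweep):
        imgs, truth = sweep
        pert = [T for T in truth[:3]]
        pert[1] = Similarity4(
            pert[1].r1, pert[1].r2, pert[1].t1 + 2.0, pert[1].t2
        )
        state = fu.fuse(imgs[:3], pert, fu.FusionConfig(beta=0.0, max_alt_iters=6, pairwise_init=False))
        gp = np.array([[0, 0], [159, 0], [0, 119], [159, 119]], float)
        err = np.linalg.norm(
            state.transforms[1].apply(gp) - truth[1].apply(gp), axis=1
        ).mean()
        assert err < 0.2

    def test_constant_images_flagged_no_update(self):
        a = np.full((40, 60), 0.5)
        state = fu.fuse(
            [a, a],
            [Similarity4.identity(), Similarity4(1, 0, 5.0, 0)],
            fu.FusionConfig(max_alt_iters=0, pairwise_init=False),
        )
        before = state.transforms[1].params.copy()
        fu.optimize_transform(state, 1)
        assert np.allclose(state.transforms[1].params, before)


class TestFuse:
    def test_zero_iterations_returns_initial(self, sweep):
        imgs, truth = sweep
        state = fu.fuse(imgs, truth, fu.FusionConfig(max_alt_iters=0, pairwise_init=False))
        for T, T0 in zip(state.transforms, truth):
            assert np.allclose(T.params, T0.params)
        assert len(state.energy_history) == 1

    def test_perfect_input_converges_immediately(self, sweep):
        imgs, truth = sweep
        state = fu.fuse(imgs, truth, fu.FusionConfig(beta=0.0, max_alt_iters=3, pairwise_init=False))
        # photometric energy at truth is resampling error only
        assert state.energy_history[0] < 0.05
        assert len(state.energy_history) <= 3

    def test_energy_history_non_increasing(self, sweep, rng):
        imgs, truth = sweep
        pert = [
            T if i == 0 else Similarity4(
                T.r1, T.r2, T.t1 + rng.uniform(-2, 2), T.t2 + rng.uniform(-2, 2)
            )
            for i, T in enumerate(truth)
        ]
        state = fu.fuse(imgs, pert, fu.FusionConfig(max_alt_iters=6))
        h = state.energy_history
        assert all(b <= a + 1e-9 for a, b in zip(h, h[1:]))
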