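import numpy as np
import pytest

from gastropano import registration as reg


@pytest.fixture(scope="module")
def matched_pair(translation_pair):
    corrs = reg.detect_and_match(translation_pair.frames[0], translation_pair.frames[1])
    return translation_pair, corrs


class TestDetectAndMatch:
    def test_self_match_is_identity(self, scene, cam, translation_pair):
        corrs = reg.detect_and_match(
            translation_pair.frames[0], translation_pair.frames[0]
        )
        assert all(np.allclose(c.m, c.m_prime) for c in corrs)

    def test_translation_pair_displacements(self, matched_pair):
        _, corrs = matched_pair
        disp = np.stack([c.m_prime - c.m for c in corrs])
        frac = (np.abs(disp - [-10.0, 0.0]).max(axis=1) < 1.0).mean()
        assert frac >= 0.9

    def test_sorted_by_descriptor_distance(self, matched_pair):
        _, corrs = matched_pair
        d = [c.distance for c in corrs]
        assert d == sorted(d)

    def test_uncorrelated_noise_fails(self, rng):
        a = rng.uniform(0, 1, (120, 160))
        b = rng.uniform(0, 1, (120, 160))
        with pytest.raises(reg.DegenerateConfigurationError):
            reg.detect_and_match(a, b)

    def test_respects_max_features(self, matched_pair):
        pair, _ = matched_pair
        corrs = reg.detect_and_match(
            pair.frames[0], pair.frames[1], reg.RegistrationConfig(max_features=5)
        )
        assert len(corrs) <= 5


class TestEstimateHomography:
    def test_identity_correspondences(self, rng):
        pts = rng.uniform(0, 100, (10, 2))
        corrs = [reg.Correspondence(m=p, m_prime=p.copy()) for p in pts]
        hom, inl = reg.estimate_homography(corrs)
        assert np.allclose(hom.H, np.eye(3), atol=1e-9)
        assert hom.rho > 0
        assert len(inl) == 10

    def test_exact_recovery_of_known_homography(self, rng):
        th = np.radians(5.0)
        H = np.array(
            [[np.cos(th), -np.sin(th), 7.0],
             [np.sin(th), np.cos(th), -3.0],
             [0, 0, 1.0]]
        )
        src = rng.uniform(10, 150, (20, 2))
        dst = (np.hstack([src, np.ones((20, 1))]) @ H.T)[:, :2]
        corrs = [reg.Correspondence(m=s, m_prime=d) for s, d in zip(src, dst)]
        hom, _ = reg.estimate_homography(corrs)
        assert np.linalg.norm(hom.H - H) < 1e-6

    def test_ransac_recovers_exact_inlier_set(self, rng):
        th = np.radians(5.0)
        H = np.array(
            [[np.cos(th), -np.sin(th), 7.0],
             [np.sin(th), np.cos(th), -3.0],
             [0, 0, 1.0]]
        )
        src = rng.uniform(10, 150, (14, 2))
        dst = (np.hstack([src, np.ones((14, 1))]) @ H.T)[:, :2]
        corrs = [reg.Correspondence(m=s, m_prime=d) for s, d in zip(src, dst)]
        corrs += [
            reg.Correspondence(m=rng.uniform(0, [159, 119]),
                               m_prime=rng.uniform(0, [159, 119]))
            for _ in range(6)
        ]
        hom, inliers = reg.estimate_homography(corrs, robust=True)
        assert set(inliers.tolist()) == set(range(14))

    def test_collinear_points_degenerate(self):
        src = np.stack([np.linspace(0, 100, 8), np.linspace(0, 50, 8)], axis=1)
        corrs = [reg.Correspondence(m=s, m_prime=s + 5) for s in src]
        with pytest.raises(reg.DegenerateConfigurationError):
            reg.estimate_homography(corrs)

    def test_too_few_correspondences(self):
        corrs = [reg.Correspondence(m=np.zeros(2), m_prime=np.zeros(2))] * 3
        with pytest.raises(reg.DegenerateConfigurationError):
            reg.estimate_homography(corrs)


class TestHpftVerify:
    def test_self_pair_verified_at_root(self, translation_pair):
        f = translation_pair.frames[0]
        corrs = reg.detect_and_match(f, f)
        _, tree = reg.hpft_verify(f, f, corrs)
        assert tree.passed and tree.depth == 0
        assert tree.kl is not None and tree.kl < 1e-6
        assert all(c.verified for c in corrs)

    def test_injected_outliers_rejected(self, matched_pair, rng):
        pair, corrs_in = matched_pair
        corrs = [
            reg.Correspondence(m=c.m.copy(), m_prime=c.m_prime.copy())
            for c in corrs_in
        ]
        n_out = max(1, int(0.25 * len(corrs)))
        outliers = [
            reg.Correspondence(m=rng.uniform(0, [159, 119]),
                               m_prime=rng.uniform(0, [159, 119]))
            for _ in range(n_out)
        ]
        allc = corrs + outliers
        reg.hpft_verify(pair.frames[0], pair.frames[1], allc)
        H = pair.pair_homographies[0]["A-y"]
        src = np.stack([c.m for c in corrs])
        dst = np.stack([c.m_prime for c in corrs])
        true_in = reg.transfer_errors(H, src, dst) < 1.5
        ver_true = sum(c.verified for c, t in zip(corrs, true_in) if t)
        assert ver_true / max(true_in.sum(), 1) >= 0.95
        n_ver = sum(c.verified for c in allc)
        assert sum(c.verified for c in outliers) <= 0.05 * max(n_ver, 1)

    def test_constant_patches_trivially_pass(self):
        """Uniform intensity defeats histogram KL (documented limitation)."""
        a = np.full((64, 64), 0.5)
        pts = np.array([[10.0, 10], [50, 10], [10, 50], [50, 50], [30, 30]])
        # geometrically consistent identity correspondences on flat texture
        corrs = [reg.Correspondence(m=p, m_prime=p.copy()) for p in pts]
        _, tree = reg.hpft_verify(a, a, corrs)
        assert tree.passed
        assert all(c.verified for c in corrs)

    def test_symmetry_between_directions(self, matched_pair):
        pair, _ = matched_pair
        fa, fb = pair.frames[0], pair.frames[1]
        cf = reg.detect_and_match(fa, fb)
        reg.hpft_verify(fa, fb, cf)
        cb = reg.detect_and_match(fb, fa)
        reg.hpft_verify(fb, fa, cb)
        fwd = {tuple(np.round(c.m, 1)) for c in cf if c.verified}
        bwd = {tuple(np.round(c.m_prime, 1)) for c in cb if c.verified}
        inter = len(fwd & bwd)
        assert inter / max(min(len(fwd), len(bwd)), 1) >= 0.95

    def test_mismatched_sizes_rejected(self, translation_pair):
        corrs = [
            reg.Correspondence(m=np.array([5.0, 5]), m_prime=np.array([5.0, 5]))
        ] * 4
        with pytest.raises(ValueError, match="same size"):
            reg.hpft_verify(
                translation_pair.frames[0], np.zeros((60, 80)), corrs
            )


def test_symmetric_kl_properties(rng):
    p = rng.uniform(0, 1, 32)
    q = rng.uniform(0, 1, 32)
    assert reg.symmetric_kl(p, p) < 1e-12
    assert reg.symmetric_kl(p, q) > 0
    assert np.isclose(reg.symmetric_kl(p, q), reg.symmetric_kl(q, p))


def test_serialization_round_trip(tmp_path, matched_pair):
    pair, corrs = matched_pair
    reg.save_correspondences(tmp_path / "c.csv", corrs)
    _, tree = reg.hpft_verify(pair.frames[0], pair.frames[1], corrs)
    reg.save_patch_tree(tmp_path / "t.json", tree)
    import csv, json

    rows = list(csv.DictReader(open(tmp_path / "c.csv")))
    assert len(rows) == len(corrs)
    data = json.loads((tmp_path / "t.json").read_text())
    assert data["rect"] == [0, 0, 160, 120]
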