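import numpy as np
import pytest

from gastropano import CameraTrajectory, chain as ch, render_sequence
from gastropano.phantom import look_at
from gastropano.registration import RegistrationConfig


@pytest.fixture(scope="module")
def clean_graph(loop_sequence):
    return ch.build_chain(
        loop_sequence, ch.default_registrar(RegistrationConfig(seed=0))
    )


def _static_loop(scene, cam, n=5):
    face = scene.model.face("A-y")
    surf = face.uv_to_world([[0.5, 0.5]])[0]
    R, t = look_at(surf + face.normal * 25.0, -face.normal, -face.v)
    traj = CameraTrajectory([(R, t, i) for i in range(n)], loop_closed=True)
    return render_sequence(scene, traj, cam)


class TestBuildChain:
    def test_static_camera_identity_edges(self, scene, cam):
        seq = _static_loop(scene, cam)
        g = ch.build_chain(seq)
        for e in g.edges:
            assert np.abs(e.transform.params - [1, 0, 0, 0]).max() < 1e-6
        res = g.loop_residual()
        assert res["corner_px"] < 1e-6

    def test_noiseless_loop_residual_small(self, clean_graph):
        res = clean_graph.loop_residual()
        assert res["translation_px"] < 1.0
        assert abs(res["rotation_deg"]) < 0.2

    def test_edge_count_and_indices(self, clean_graph, loop_sequence):
        assert len(clean_graph.edges) == len(loop_sequence.frames) - 1
        assert clean_graph.edges[0].source == 0
        assert clean_graph.edges[-1].target == len(loop_sequence.frames) - 1

    def test_non_closed_sequence_rejected(self, translation_pair):
        with pytest.raises(ValueError, match="not loop-closed"):
            ch.build_chain(translation_pair)

    def test_two_frame_loop_rejected(self, scene, cam):
        seq = _static_loop(scene, cam, n=3)
        seq.frames = seq.frames[:3]
        seq.loop_closed = True
        with pytest.raises(ValueError, match="at least 3 distinct"):
            ch.build_chain(ch.FrameSequence(
                frames=seq.frames[:2] + [seq.frames[0]],
                poses=[], pair_homographies=[], polyp_boxes=[],
                noise_scalar=0.0, specular_spots=[], loop_closed=True,
            ))

    def test_unregistrable_pair_named(self, scene, cam, rng):
        seq = _static_loop(scene, cam)
        seq.frames[2].gray = rng.uniform(0, 1, seq.frames[2].gray.shape)
        with pytest.raises(RuntimeError, match=r"pair \(1, 2\)"):
            ch.build_chain(seq)

    def test_panorama_transforms_chain_consistency(self, clean_graph):
        Ts = clean_graph.panorama_transforms()
        assert len(Ts) == len(clean_graph.edges) + 1
        # T_k composed with edge k gives T_{k+1}: x_{k+1} -> pano
        for k, e in enumerate(clean_graph.edges):
            lhs = Ts[k].compose(e.transform.inverse())
            assert np.allclose(lhs.params, Ts[k + 1].params, atol=1e-9)


class TestClosedChainFilter:
    def test_consistent_graph_is_fixed_point(self, scene, cam):
        seq = _static_loop(scene, cam)
        g = ch.build_chain(seq)
        params_before = [e.transform.params.copy() for e in g.edges]
        g2, rejected = ch.closed_chain_filter(g)
        assert rejected == []
        for p, e in zip(params_before, g2.edges):
            assert np.allclose(p, e.transform.params)

    def test_injected_outliers_filtered(self, loop_sequence, rng):
        g = ch.build_chain(
            loop_sequence, ch.default_registrar(RegistrationConfig(seed=0))
        )
        marks = []
        for e in g.edges:
            n_out = max(2, int(0.15 / 0.85 * len(e.src_pts)))
            e.src_pts = np.vstack([e.src_pts, rng.uniform(0, [159, 119], (n_out, 2))])
            e.dst_pts = np.vstack([e.dst_pts, rng.uniform(0, [159, 119], (n_out, 2))])
            marks.append(np.r_[np.zeros(len(e.active), bool), np.ones(n_out, bool)])
            e.active = np.ones(len(e.src_pts), bool)
            e.refit()
        initial = g.loop_residual()["corner_px"]
        g2, rejected = ch.closed_chain_filter(g)
        final = g2.loop_residual()["corner_px"]
        assert final <= initial
        # monotone residual across rounds
        log = [r["corner_px"] for r in g2.residual_log[1:]]
        assert all(b <= a + 1e-9 for a, b in zip(log, log[1:]))
        # >= 90% of injected outliers rejected
        n_out = sum(m.sum() for m in marks)
        out_rej = sum((~e.active & m).sum() for e, m in zip(g2.edges, marks))
        assert out_rej / n_out >= 0.9
        # conservation: rejected + surviving = input, per edge
        for k, e in enumerate(g2.edges):
            n_rej = sum(1 for kk, _, _ in rejected if kk == k)
            assert e.n_active + n_rej == len(e.src_pts)
        # recovered edges match truth transforms
        for e, d in zip(g2.edges, loop_sequence.pair_homographies):
            H = d["A-y"]
            gpts = np.stack(
                np.meshgrid(np.linspace(20, 140, 6), np.linspace(20, 100, 6)), -1
            ).reshape(-1, 2)
            tru = np.hstack([gpts, np.ones((36, 1))]) @ H.T
            tru = tru[:, :2] / tru[:, 2:]
            assert np.linalg.norm(e.transform.apply(gpts) - tru, axis=1).mean() < 0.5

    def test_edge_with_fewer_than_four_correspondences_raises(self, rng):
        from gastropano.transforms import Similarity4

        pts = rng.uniform(0, 100, (5, 2))
        edges = [
            ch.ChainTransform(
                source=k, target=k + 1,
                transform=Similarity4.identity(),
                src_pts=pts.copy(), dst_pts=pts.copy(),
                active=np.ones(5, bool),
            )
            for k in range(3)
        ]
        edges[0].active[:2] = False  # 3 left, below the similarity minimum
        g = ch.ChainGraph(edges=edges, frame_shape=(120, 160))
        with pytest.raises(RuntimeError, match=r"edge \(0, 1\)"):
            ch.closed_chain_filter(g)


def test_graph_json_round_trip(tmp_path, clean_graph):
    clean_graph.to_json(tmp_path / "g.json")
    import json

    data = json.loads((tmp_path / "g.json").read_text())
    assert len(data["edges"]) == len(clean_graph.edges)
    assert "loop_residual" in data
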