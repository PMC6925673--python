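import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gastropano.detection import (
    DetectorConfig,
    SelectiveSSD,
    TrainBatchAssignment,
    multibox_loss,
    select_negatives,
)
from gastropano.detection.anchors import (
    anchor_grid,
    decode_boxes,
    encode_boxes,
    match_anchors,
    nms,
    _to_center,
)
from gastropano.detection.ssd import _softmax


class TestSelectNegatives:
    def test_hardest_negatives_kept(self):
        a = select_negatives([0.2, 0.9, 0.1, 0.5], [1, 0, 0, 0], ratio=2.0)
        assert list(a.selected) == [1, 3]
        assert a.labels[0] == "positive"
        assert a.labels[2] == "negative_discarded"

    def test_ties_break_to_lower_index(self):
        a = select_negatives([0.0, 0.5, 0.5, 0.5], [1, 0, 0, 0], ratio=1.0)
        assert list(a.selected) == [1]

    def test_cap_at_all_negatives(self):
        a = select_negatives([0.1, 0.2, 0.3], [1, 0, 0], ratio=10.0)
        assert list(a.selected) == [1, 2]

    def test_no_positives_keeps_at_least_one(self):
        a = select_negatives([0.1, 0.9], [0, 0], ratio=3.0)
        assert len(a.selected) == 2  # floor(3) capped at #neg
        a = select_negatives([0.1, 0.9], [0, 0], ratio=0.5)
        assert len(a.selected) == 1

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            select_negatives([0.1, 0.2], [1], 1.0)

    def test_nonpositive_ratio_rejected(self):
        with pytest.raises(ValueError):
            select_negatives([0.1], [0], 0.0)

    @settings(derandomize=True, max_examples=200)
    @given(
        losses=st.lists(st.floats(0, 10, allow_nan=False), min_size=1, max_size=8),
        labels_seed=st.integers(0, 2**16),
        ratio=st.sampled_from([0.5, 1.0, 2.0, 3.0]),
    )
    def test_matches_brute_force_sort_oracle(self, losses, labels_seed, ratio):
        rng = np.random.default_rng(labels_seed)
        labels = rng.integers(0, 2, len(losses))
        a = select_negatives(losses, labels, ratio)
        neg = [i for i in range(len(losses)) if not labels[i]]
        n_pos = int(labels.sum())
        k = (
            min(int(np.floor(ratio * n_pos)), len(neg))
            if n_pos
            else min(max(int(np.floor(ratio)), 1), len(neg))
        )
        expect = sorted(sorted(neg, key=lambda i: (-losses[i], i))[:k])
        assert list(a.selected) == expect
        # partition property: selected + discarded = all negatives
        n_disc = (a.labels == "negative_discarded").sum()
        assert len(a.selected) + n_disc == len(neg)


def _assignment(labels_str):
    labels = np.array(labels_str, dtype=object)
    sel = np.flatnonzero(labels == "negative_selected")
    return TrainBatchAssignment(
        labels=labels, conf_losses=np.zeros(len(labels)), ratio=3.0, selected=sel
    )


class TestMultiboxLoss:
    def test_perfect_predictions_zero_loss(self):
        preds = np.zeros((3, 6))
        preds[0, 4:6] = [-50, 50]  # positive, confident foreground
        preds[1, 4:6] = [50, -50]  # selected negative, confident background
        preds[2, 4:6] = [0, 0]
        offsets = np.zeros((3, 4))
        a = _assignment(["positive", "negative_selected", "negative_discarded"])
        loss, grad = multibox_loss(preds, offsets, a)
        assert loss < 1e-12
        assert np.abs(grad).max() < 1e-12

    def test_zero_positives_conf_only(self):
        preds = np.zeros((2, 6))
        preds[:, :4] = 5.0  # localization must be ignored
        a = _assignment(["negative_selected", "negative_discarded"])
        loss, grad = multibox_loss(preds, np.zeros((2, 4)), a)
        assert np.isclose(loss, -np.log(0.5))
        assert np.abs(grad[:, :4]).max() == 0

    def test_smooth_l1_offset_half(self):
        """One positive with encoded offset error (0.5,0,0,0): 0.5*0.5^2."""
        preds = np.zeros((1, 6))
        preds[0, :4] = [0.5, 0, 0, 0]
        preds[0, 4:6] = [-50, 50]
        a = _assignment(["positive"])
        loss, _ = multibox_loss(preds, np.zeros((1, 4)), a, alpha=1.0)
        assert np.isclose(loss, 0.125)

    def test_nan_prediction_rejected(self):
        preds = np.full((1, 6), np.nan)
        a = _assignment(["positive"])
        with pytest.raises(ValueError):
            multibox_loss(preds, np.zeros((1, 4)), a)


class TestAnchors:
    def test_grid_counts_and_order(self):
        anchors = anchor_grid((32, 48), (4, 8), (8.0, 16.0), (1.0, 2.0))
        n1 = (32 // 4) * (48 // 4) * 2
        n2 = (32 // 8) * (48 // 8) * 2
        assert anchors.shape == (n1 + n2, 4)
        # first cell's anchors sit at the first stride-4 cell centre
        assert np.allclose(anchors[0, :2], [2.0, 2.0])
        assert np.allclose(anchors[1, :2], [2.0, 2.0])

    def test_encode_decode_round_trip(self, rng):
        anchors = anchor_grid((64, 64), (8,), (12.0,), (1.0, 1.5))
        boxes = np.stack(
            [
                rng.uniform(5, 30, 20), rng.uniform(5, 30, 20),
                rng.uniform(35, 60, 20), rng.uniform(35, 60, 20),
            ],
            axis=1,
        )
        idx = rng.integers(0, len(anchors), 20)
        enc = encode_boxes(_to_center(boxes), anchors[idx])
        dec = decode_boxes(enc, anchors[idx])
        assert np.abs(dec - boxes).max() < 1e-9

    def test_every_truth_gets_a_positive_anchor(self):
        anchors = anchor_grid((64, 64), (8,), (12.0,), (1.0,))
        truth = np.array([[1.0, 1.0, 4.0, 4.0]])  # tiny box, IOU < 0.5 anywhere
        labels, matched = match_anchors(anchors, truth)
        assert (labels == 1).sum() >= 1
        assert matched[labels == 1][0] == 0

    def test_nms_suppresses_duplicates(self):
        boxes = np.array([[0, 0, 10, 10], [0.5, 0.5, 10.5, 10.5], [30, 30, 40, 40.0]])
        keep = nms(boxes, np.array([0.9, 0.8, 0.7]), 0.5)
        assert list(keep) == [0, 2]


@pytest.fixture(scope="module")
def tiny_detector():
    cfg = DetectorConfig(channels=4, scales=(8.0, 14.0), seed=0, epochs=2, lr=1e-3)
    return SelectiveSSD((32, 48), config=cfg)


class TestSelectiveSSD:
    def test_backprop_matches_numeric_gradient(self, tiny_detector, rng):
        m = tiny_detector
        pano = rng.uniform(0, 1, (32, 48))
        boxes = np.array([[10.0, 10, 20, 20]])
        labels, matched = match_anchors(m.anchors, boxes)
        offsets = np.zeros((len(m.anchors), 4))
        pos = np.flatnonzero(labels == 1)
        offsets[pos] = encode_boxes(_to_center(boxes)[matched[pos]], m.anchors[pos])
        preds = m.forward(pano)
        p = _softmax(preds[:, 4:6])
        neg = labels == 0
        cl = np.zeros(len(preds))
        cl[neg] = -np.log(np.maximum(p[neg, 0], 1e-12))
        a = select_negatives(cl, labels == 1, 3.0)
        _, grad = multibox_loss(preds, offsets, a)
        m.backward(grad)
        g = m.grads[0].copy()
        w = m.params[0]
        for idx in [(0, 0), (2, 5)]:
            eps = 1e-6
            w[idx] += eps
            l1, _ = multibox_loss(m.forward(pano), offsets, a)
            w[idx] -= 2 * eps
            l2, _ = multibox_loss(m.forward(pano), offsets, a)
            w[idx] += eps
            num = (l1 - l2) / (2 * eps)
            assert abs(num - g[idx]) < 1e-6 * max(abs(num), 1.0)

    def test_zero_epochs_checkpoint_is_initialization(self, rng, tmp_path):
        cfg = DetectorConfig(channels=4, scales=(8.0, 14.0), seed=3)
        a = SelectiveSSD((32, 48), config=cfg)
        init = [p.copy() for p in a.params]
        pano = rng.uniform(0, 1, (32, 48))
        curve = a.train([pano], [np.array([[10.0, 10, 20, 20]])], epochs=0)
        assert curve == []
        for p, q in zip(a.params, init):
            assert (p == q).all()
        a.save(tmp_path / "ckpt.npz")
        b = SelectiveSSD.load(tmp_path / "ckpt.npz", config=cfg)
        for p, q in zip(b.params, init):
            assert (p == q).all()

    def test_training_is_deterministic(self, rng):
        pano = rng.uniform(0, 1, (32, 48))
        boxes = [np.array([[10.0, 10, 20, 20]])]
        curves = []
        for _ in range(2):
            cfg = DetectorConfig(channels=4, scales=(8.0, 14.0), seed=5, lr=1e-3)
            det = SelectiveSSD((32, 48), config=cfg)
            curves.append(det.train([pano], boxes, epochs=3))
        assert curves[0] == curves[1]

    def test_blank_invalid_panorama_gives_no_detections(self):
        cfg = DetectorConfig(channels=4, scales=(8.0, 14.0), seed=0)
        det = SelectiveSSD((32, 48), valid_mask=np.zeros((32, 48), bool), config=cfg)
        assert det.infer(np.zeros((32, 48))) == []

    def test_size_mismatch_rejected(self, tiny_detector):
        with pytest.raises(ValueError, match="shape"):
            tiny_detector.infer(np.zeros((64, 64)))
        with pytest.raises(ValueError, match="shape"):
            tiny_detector.train([np.zeros((64, 64))], [np.zeros((0, 4))], epochs=1)

    def test_detections_sorted_and_confident(self, rng):
        # overfit a tiny detector on one panorama with one bright box
        cfg = DetectorConfig(channels=6, scales=(10.0, 16.0), seed=1, lr=3e-3)
        det = SelectiveSSD((32, 48), config=cfg)
        pano = rng.uniform(0.3, 0.5, (32, 48))
        pano[12:22, 18:28] += 0.4
        boxes = [np.array([[18.0, 12, 28, 22]])]
        det.train([pano], boxes, epochs=40)
        dets = det.infer(pano, conf_threshold=0.3)
        assert len(dets) >= 1
        confs = [d.confidence for d in dets]
        assert confs == sorted(confs, reverse=True)
        from gastropano.evaluation import iou

        assert iou(dets[0].box, boxes[0][0]) > 0.5
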