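"""Anchor grids, box encoding and IOU matching for the panorama detector."""

from __future__ import annotations

import numpy as np

__all__ = [
    "anchor_grid",
    "iou_matrix",
    "encode_boxes",
    "decode_boxes",
    "match_anchors",
    "nms",
]

# SSD-style offset variances
_VXY = 0.1
_VWH = 0.2


def anchor_grid(
    shape: tuple[int, int],
    strides: tuple[int, ...],
    scales: tuple[float, ...],
    aspects: tuple[float, ...],
) -> np.ndarray:
    """Anchors as (N, 4) center-size boxes (cx, cy, w, h), panorama px.

    One scale per level (paired with ``strides``), ``aspects`` anchors
    per cell; enumeration order is fixed: level, row, column, aspect.
    """
    H, W = shape
    if len(strides) != len(scales):
        raise ValueError("one scale per stride level")
    out = []
    for stride, scale in zip(strides, scales):
        h, w = H // stride, W // stride
        ys, xs = np.mgrid[0:h, 0:w]
        cx = (xs + 0.5) * stride
        cy = (ys + 0.5) * stride
        for a in aspects:
            aw = scale * np.sqrt(a)
            ah = scale / np.sqrt(a)
            out.append(
                np.stack(
                    [cx.ravel(), cy.ravel(), np.full(cx.size, aw), np.full(cx.size, ah)],
                    axis=1,
                )
            )
    # interleave aspects per cell to match the head channel layout:
    # (level, row, col, aspect)
    per_level = []
    i = 0
    for stride in strides:
        h, w = H // stride, W // stride
        n = h * w
        level = np.stack([out[i + a] for a in range(len(aspects))], axis=1)
        per_level.append(level.reshape(n * len(aspects), 4))
        i += len(aspects)
    return np.concatenate(per_level, axis=0)


def _to_corners(cs: np.ndarray) -> np.ndarray:
    return np.stack(
        [
            cs[:, 0] - cs[:, 2] / 2,
            cs[:, 1] - cs[:, 3] / 2,
            cs[:, 0] + cs[:, 2] / 2,
            cs[:, 1] + cs[:, 3] / 2,
        ],
        axis=1,
    )


def _to_center(corners: np.ndarray) -> np.ndarray:
    return np.stack(
        [
            (corners[:, 0] + corners[:, 2]) / 2,
            (corners[:, 1] + corners[:, 3]) / 2,
            corners[:, 2] - corners[:, 0],
            corners[:, 3] - corners[:, 1],
        ],
        axis=1,
    )


def iou_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise IOU between corner-format box sets (N,4) x (M,4)."""
    a = np.atleast_2d(a)
    b = np.atleast_2d(b)
    x1 = np.maximum(a[:, None, 0], b[None, :, 0])
    y1 = np.maximum(a[:, None, 1], b[None, :, 1])
    x2 = np.minimum(a[:, None, 2], b[None, :, 2])
    y2 = np.minimum(a[:, None, 3], b[None, :, 3])
    inter = np.clip(x2 - x1, 0, None) * np.clip(y2 - y1, 0, None)
    area_a = (a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
    area_b = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    union = area_a[:, None] + area_b[None, :] - inter
    return inter / np.maximum(union, 1e-12)


def encode_boxes(truth_cs: np.ndarray, anchors_cs: np.ndarray) -> np.ndarray:
    """Center-size truth boxes -> SSD offsets relative to anchors."""
    return np.stack(
        [
            (truth_cs[:, 0] - anchors_cs[:, 0]) / anchors_cs[:, 2] / _VXY,
            (truth_cs[:, 1] - anchors_cs[:, 1]) / anchors_cs[:, 3] / _VXY,
            np.log(truth_cs[:, 2] / anchors_cs[:, 2]) / _VWH,
            np.log(truth_cs[:, 3] / anchors_cs[:, 3]) / _VWH,
        ],
        axis=1,
    )


def decode_boxes(offsets: np.ndarray, anchors_cs: np.ndarray) -> np.ndarray:
    """Predicted offsets -> corner-format boxes."""
    cx = offsets[:, 0] * _VXY * anchors_cs[:, 2] + anchors_cs[:, 0]
    cy = offsets[:, 1] * _VXY * anchors_cs[:, 3] + anchors_cs[:, 1]
    w = np.exp(np.clip(offsets[:, 2] * _VWH, -10, 10)) * anchors_cs[:, 2]
    h = np.exp(np.clip(offsets[:, 3] * _VWH, -10, 10)) * anchors_cs[:, 3]
    return _to_corners(np.stack([cx, cy, w, h], axis=1))


def match_anchors(
    anchors_cs: np.ndarray,
    truth_corners: np.ndarray,
    pos_iou: float = 0.5,
    neg_iou: float = 0.4,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-anchor label and matched-truth index.

    Labels: 1 positive, 0 negative, -1 ignore (between thresholds).  The
    best anchor of every truth box is forced positive, so no truth goes
    unmatched.
    """
    n = len(anchors_cs)
    labels = np.zeros(n, dtype=np.int8)
    matched = np.full(n, -1, dtype=np.int64)
    if len(truth_corners) == 0:
        return labels, matched
    iou = iou_matrix(_to_corners(anchors_cs), truth_corners)
    best_t = iou.argmax(axis=1)
    best_iou = iou[np.arange(n), best_t]
    labels[(best_iou >= neg_iou) & (best_iou < pos_iou)] = -1
    pos = best_iou >= pos_iou
    labels[pos] = 1
    matched[pos] = best_t[pos]
    forced = iou.argmax(axis=0)  # best anchor per truth
    labels[forced] = 1
    matched[forced] = np.arange(len(truth_corners))
    return labels, matched


def nms(boxes: np.ndarray, scores: np.ndarray, iou_thresh: float) -> np.ndarray:
    """Greedy non-maximum suppression; returns kept indices, score-desc."""
    order = np.argsort(-scores, kind="stable")
    keep = []
    while len(order):
        i = order[0]
        keep.append(i)
        if len(order) == 1:
            break
        rest = order[1:]
        ious = iou_matrix(boxes[i : i + 1], boxes[rest])[0]
        order = rest[ious <= iou_thresh]
    return np.asarray(keep, dtype=int)
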