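"""Selective single-shot polyp detector for unfolded panoramas.

Polyps occupy a tiny fraction of a panorama, so nearly every predicted
box is background and the confidence loss is swamped by easy negatives.
Selective mining sorts the negative anchors by their confidence loss
(most confidently wrong first) and trains only on the top
``ratio x #positives``, discarding the rest outright.

The network is a small convolutional trunk with two feature-map levels
(strides 4 and 8) and per-level 1x1 prediction heads emitting, for each
anchor, 4 box offsets and 2 class logits.  Anchors whose centres fall in
the panorama gutters are masked out of both training and inference, and
predicted boxes are clipped to the face slot under their centre so no
detection spans a gutter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._nn import Adam, Conv2d, MaxPool2, ReLU, Sequential
from .anchors import (
    anchor_grid,
    decode_boxes,
    encode_boxes,
    match_anchors,
    nms,
    _to_center,
)

__all__ = [
    "DetectorConfig",
    "Detection",
    "TrainBatchAssignment",
    "select_negatives",
    "multibox_loss",
    "SelectiveSSD",
]


@dataclass
class DetectorConfig:
    channels: int = 12
    strides: tuple[int, ...] = (4, 8)
    scales: tuple[float, ...] = (10.0, 18.0)
    aspects: tuple[float, ...] = (1.0, 1.5, 2 / 3)
    ratio: float = 3.0  # negatives : positives
    mining: str = "selective"  # "selective" or "all"
    seed: int = 7
    epochs: int = 30
    lr: float = 2e-3
    alpha: float = 1.0  # localization weight
    pos_iou: float = 0.5
    neg_iou: float = 0.4
    conf_threshold: float = 0.5
    nms_iou: float = 0.5


@dataclass
class Detection:
    box: np.ndarray  # [x_min, y_min, x_max, y_max] panorama px
    confidence: float
    class_name: str = "polyp"


@dataclass
class TrainBatchAssignment:
    labels: np.ndarray  # per-anchor: "positive" / "negative_selected" / "negative_discarded"
    conf_losses: np.ndarray  # per-anchor confidence loss (0 where not a negative)
    ratio: float
    selected: np.ndarray  # indices of selected negatives

    @property
    def n_selected(self) -> int:
        return len(self.selected)


def select_negatives(conf_losses, labels, ratio: float) -> TrainBatchAssignment:
    """Keep the ``ratio x #positives`` hardest negatives, discard the rest.

    ``labels`` flags each anchor positive (1/True) or negative
    (0/False); ties in loss break toward the smaller anchor index.  With
    no positives, ``max(floor(ratio), 1)`` negatives are kept (when any
    exist).
    """
    losses = np.asarray(conf_losses, dtype=float)
    lab = np.asarray(labels)
    if losses.shape != lab.shape:
        raise ValueError(
            f"losses and labels length mismatch: {losses.shape} vs {lab.shape}"
        )
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    pos = lab.astype(bool)
    neg_idx = np.flatnonzero(~pos)
    n_pos = int(pos.sum())
    if n_pos:
        k = min(int(np.floor(ratio * n_pos)), len(neg_idx))
    else:
        k = min(max(int(np.floor(ratio)), 1), len(neg_idx))
    order = neg_idx[np.lexsort((neg_idx, -losses[neg_idx]))]
    selected = np.sort(order[:k])
    out = np.full(losses.shape, "negative_discarded", dtype=object)
    out[pos] = "positive"
    out[selected] = "negative_selected"
    return TrainBatchAssignment(
        labels=out, conf_losses=losses, ratio=ratio, selected=selected
    )


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=1, keepdims=True)


def _smooth_l1(x: np.ndarray) -> np.ndarray:
    ax = np.abs(x)
    return np.where(ax < 1, 0.5 * x * x, ax - 0.5)


def _smooth_l1_grad(x: np.ndarray) -> np.ndarray:
    return np.clip(x, -1, 1)


def multibox_loss(
    predictions: np.ndarray,
    truth_offsets: np.ndarray,
    assignment: TrainBatchAssignment,
    alpha: float = 1.0,
) -> tuple[float, np.ndarray]:
    """Confidence + alpha * localization loss, and its gradient.

    ``predictions`` is (N, 6): 4 offsets then 2 class logits (bg, fg).
    Confidence = cross-entropy over positives and selected negatives
    only; localization = smooth-L1 over positives only against the
    encoded ``truth_offsets``; both normalized by #positives (1 when
    none).
    """
    if np.any(~np.isfinite(predictions)):
        raise ValueError("NaN/inf prediction")
    n = len(predictions)
    pos = assignment.labels == "positive"
    sel = assignment.labels == "negative_selected"
    n_pos = max(int(pos.sum()), 1)
    logits = predictions[:, 4:6]
    p = _softmax(logits)
    grad = np.zeros_like(predictions)

    conf = 0.0
    for mask, cls in ((pos, 1), (sel, 0)):
        if np.any(mask):
            conf += float(-np.log(np.maximum(p[mask, cls], 1e-12)).sum())
            onehot = np.zeros((int(mask.sum()), 2))
            onehot[:, cls] = 1.0
            grad[mask, 4:6] = (p[mask] - onehot) / n_pos
    loc = 0.0
    if np.any(pos):
        diff = predictions[pos, :4] - truth_offsets[pos]
        loc = float(_smooth_l1(diff).sum())
        grad[pos, :4] = alpha * _smooth_l1_grad(diff) / n_pos
    loss = conf / n_pos + alpha * loc / n_pos
    return loss, grad


class SelectiveSSD:
    """Two-level single-shot detector over a fixed panorama geometry."""

    def __init__(
        self,
        input_shape: tuple[int, int],
        valid_mask: np.ndarray | None = None,
        config: DetectorConfig | None = None,
    ):
        self.cfg = config or DetectorConfig()
        self.input_shape = tuple(input_shape)
        rng = np.random.default_rng(self.cfg.seed)
        C = self.cfg.channels
        A = len(self.cfg.aspects)
        self.trunk1 = Sequential(
            Conv2d(1, C, 3, rng), ReLU(), MaxPool2(),
            Conv2d(C, 2 * C, 3, rng), ReLU(), MaxPool2(),
        )
        self.trunk2 = Sequential(Conv2d(2 * C, 2 * C, 3, rng), ReLU(), MaxPool2())
        self.head1 = Conv2d(2 * C, A * 6, 1, rng)
        self.head2 = Conv2d(2 * C, A * 6, 1, rng)
        for head in (self.head1, self.head2):
            # small head weights and a low foreground prior (~1%) in the
            # class biases keep the first epochs stable regardless of
            # the trunk initialization
            head.w *= 0.1
            for a in range(A):
                head.b[a * 6 + 4] = 0.0
                head.b[a * 6 + 5] = -np.log(99.0)
        self.anchors = anchor_grid(
            self.input_shape, self.cfg.strides, self.cfg.scales, self.cfg.aspects
        )
        self.valid_mask = (
            np.ones(self.input_shape, dtype=bool) if valid_mask is None else valid_mask
        )
        cx = np.clip(self.anchors[:, 0].astype(int), 0, self.input_shape[1] - 1)
        cy = np.clip(self.anchors[:, 1].astype(int), 0, self.input_shape[0] - 1)
        self.anchor_valid = self.valid_mask[cy, cx]
        self.loss_curve: list[float] = []

    # -- plumbing ------------------------------------------------------
    @property
    def _modules(self):
        return [self.trunk1, self.trunk2, self.head1, self.head2]

    @property
    def params(self):
        return [p for m in self._modules for p in m.params]

    @property
    def grads(self):
        return [g for m in self._modules for g in m.grads]

    def _normalize(self, pano: np.ndarray) -> np.ndarray:
        v = pano[self.valid_mask]
        mu = v.mean() if v.size else 0.0
        sd = v.std() if v.size else 1.0
        out = (pano - mu) / max(sd, 1e-6)
        return np.where(self.valid_mask, out, 0.0)

    def _flatten_head(self, out: np.ndarray) -> np.ndarray:
        A = len(self.cfg.aspects)
        c, h, w = out.shape
        return out.reshape(A, 6, h, w).transpose(2, 3, 0, 1).reshape(h * w * A, 6)

    def _unflatten_head(self, grad: np.ndarray, shape) -> np.ndarray:
        A = len(self.cfg.aspects)
        c, h, w = shape
        return grad.reshape(h, w, A, 6).transpose(2, 3, 0, 1).reshape(c, h, w)

    def forward(self, pano: np.ndarray) -> np.ndarray:
        x = self._normalize(pano)[None, :, :]
        f1 = self.trunk1.forward(x)
        f2 = self.trunk2.forward(f1)
        o1 = self.head1.forward(f1)
        o2 = self.head2.forward(f2)
        self._shapes = (o1.shape, o2.shape)
        return np.concatenate([self._flatten_head(o1), self._flatten_head(o2)])

    def backward(self, grad_preds: np.ndarray) -> None:
        s1, s2 = self._shapes
        n1 = s1[1] * s1[2] * len(self.cfg.aspects)
        g1 = self._unflatten_head(grad_preds[:n1], s1)
        g2 = self._unflatten_head(grad_preds[n1:], s2)
        gf2 = self.head2.backward(g2)
        gf1 = self.head1.backward(g1) + self.trunk2.backward(gf2)
        self.trunk1.backward(gf1)

    # -- training ------------------------------------------------------
    def train(
        self,
        panoramas: list[np.ndarray],
        truth_boxes: list[np.ndarray],
        epochs: int | None = None,
    ) -> list[float]:
        """Seeded SGD (Adam) over the labeled panoramas; returns loss curve."""
        if not panoramas:
            raise ValueError("need at least one labeled panorama")
        cfg = self.cfg
        epochs = cfg.epochs if epochs is None else epochs
        per_image = []
        for pano, boxes in zip(panoramas, truth_boxes):
            if pano.shape != self.input_shape:
                raise ValueError(
                    f"panorama shape {pano.shape} != detector shape {self.input_shape}"
                )
            boxes = np.asarray(boxes, dtype=float).reshape(-1, 4)
            labels, matched = match_anchors(
                self.anchors, boxes, cfg.pos_iou, cfg.neg_iou
            )
            labels[~self.anchor_valid] = -1
            if len(boxes) and not np.any(labels == 1):
                raise ValueError(
                    "no positive anchor matches any truth box; "
                    "review anchor scales/aspects for this panorama geometry"
                )
            offsets = np.zeros((len(self.anchors), 4))
            pos_idx = np.flatnonzero(labels == 1)
            if len(pos_idx):
                offsets[pos_idx] = encode_boxes(
                    _to_center(boxes)[matched[pos_idx]], self.anchors[pos_idx]
                )
            per_image.append((pano, labels, offsets))
        rng = np.random.default_rng(cfg.seed + 1)
        opt = Adam(self.params, lr=cfg.lr)
        self.loss_curve = []
        for _ep in range(epochs):
            order = rng.permutation(len(per_image))
            ep_loss = 0.0
            for i in order:
                pano, labels, offsets = per_image[i]
                preds = self.forward(pano)
                p = _softmax(preds[:, 4:6])
                neg = labels == 0
                conf_losses = np.zeros(len(preds))
                conf_losses[neg] = -np.log(np.maximum(p[neg, 0], 1e-12))
                if cfg.mining == "selective":
                    assignment = select_negatives(conf_losses, labels == 1, cfg.ratio)
                    # anchors outside the pos/neg sets stay discarded
                    assignment.labels[~neg & ~(labels == 1)] = np.where(
                        labels[~neg & ~(labels == 1)] == 1,
                        "positive",
                        "negative_discarded",
                    )
                else:
                    out = np.full(len(preds), "negative_discarded", dtype=object)
                    out[labels == 1] = "positive"
                    out[neg] = "negative_selected"
                    assignment = TrainBatchAssignment(
                        labels=out,
                        conf_losses=conf_losses,
                        ratio=np.inf,
                        selected=np.flatnonzero(neg),
                    )
                loss, grad = multibox_loss(preds, offsets, assignment, cfg.alpha)
                self.backward(grad)
                opt.step(self.grads)
                ep_loss += loss
            self.loss_curve.append(ep_loss / len(per_image))
        return self.loss_curve

    # -- inference -----------------------------------------------------
    def infer(
        self,
        pano: np.ndarray,
        conf_threshold: float | None = None,
        nms_iou: float | None = None,
        slot_clip: dict[str, tuple[int, int, int, int]] | None = None,
    ) -> list[Detection]:
        """Detections above threshold, NMS-pruned, confidence-descending."""
        if pano.shape != self.input_shape:
            raise ValueError(
                f"panorama shape {pano.shape} != detector shape {self.input_shape}"
            )
        ct = self.cfg.conf_threshold if conf_threshold is None else conf_threshold
        ni = self.cfg.nms_iou if nms_iou is None else nms_iou
        if not np.any(self.valid_mask):
            return []
        preds = self.forward(pano)
        conf = _softmax(preds[:, 4:6])[:, 1]
        keep = (conf >= ct) & self.anchor_valid
        if not np.any(keep):
            return []
        boxes = decode_boxes(preds[keep, :4], self.anchors[keep])
        conf = conf[keep]
        H, W = self.input_shape
        boxes[:, 0::2] = np.clip(boxes[:, 0::2], 0, W - 1)
        boxes[:, 1::2] = np.clip(boxes[:, 1::2], 0, H - 1)
        if slot_clip:
            boxes = np.stack([self._clip_to_slot(b, slot_clip) for b in boxes])
        ok = (boxes[:, 2] > boxes[:, 0]) & (boxes[:, 3] > boxes[:, 1])
        boxes, conf = boxes[ok], conf[ok]
        if len(boxes) == 0:
            return []
        kept = nms(boxes, conf, ni)
        return [Detection(box=boxes[i], confidence=float(conf[i])) for i in kept]

    @staticmethod
    def _clip_to_slot(box: np.ndarray, slots: dict) -> np.ndarray:
        cx = (box[0] + box[2]) / 2
        cy = (box[1] + box[3]) / 2
        for x0, y0, w, h in slots.values():
            if x0 <= cx < x0 + w and y0 <= cy < y0 + h:
                return np.array(
                    [
                        max(box[0], x0 - 0.5),
                        max(box[1], y0 - 0.5),
                        min(box[2], x0 + w - 0.5),
                        min(box[3], y0 + h - 0.5),
                    ]
                )
        return box

    # -- checkpointing -------------------------------------------------
    def save(self, path) -> None:
        import dataclasses
        import json

        arrays = {f"p{i}": p for i, p in enumerate(self.params)}
        np.savez(
            path,
            input_shape=np.asarray(self.input_shape),
            valid_mask=self.valid_mask,
            loss_curve=np.asarray(self.loss_curve),
            config_json=np.frombuffer(
                json.dumps(dataclasses.asdict(self.cfg)).encode(), dtype=np.uint8
            ),
            **arrays,
        )

    @classmethod
    def load(cls, path, config: DetectorConfig | None = None) -> "SelectiveSSD":
        import json

        data = np.load(path, allow_pickle=False)
        if config is None and "config_json" in data:
            d = json.loads(bytes(data["config_json"]).decode())
            for key in ("strides", "scales", "aspects"):
                d[key] = tuple(d[key])
            config = DetectorConfig(**d)
        model = cls(
            tuple(int(v) for v in data["input_shape"]),
            valid_mask=data["valid_mask"],
            config=config,
        )
        for i, p in enumerate(model.params):
            p[...] = data[f"p{i}"]
        model.loss_curve = list(data["loss_curve"])
        return model
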