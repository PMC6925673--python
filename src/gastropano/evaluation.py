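"""Quantitative evaluation: detection tallies, seam texture error, FB curves.

Three evaluations mirror the pipeline's claims:

* detection vs. reference boxes at IOU > 0.5 (recall and accuracy
  percentages, greedy one-to-one matching in confidence order);
* seam texture error of a fused panorama: for every canvas pixel that
  received two or more image contributions, the mean pairwise absolute
  intensity difference of those contributions (0 iff all overlapping
  contributions agree exactly) — reported per region and
  coverage-weighted overall as the "gastropano texture error";
* forward-backward (FB) robustness curves: the number of initial
  features whose start point returns to within a threshold after
  mapping into the other frame and back, per Gaussian noise scalar.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np

from . import registration as reg
from .fusion import FusionState, SeamResiduals, seam_residuals
from .phantom import Frame
from .transforms import Similarity4

__all__ = [
    "DetectionTally",
    "TextureErrorReport",
    "iou",
    "tally_detections",
    "texture_metric_error",
    "fb_error_curve",
    "seam_rmse",
]


# ---------------------------------------------------------------------
# IOU + detection tallies
# ---------------------------------------------------------------------

def iou(box_a, box_b) -> float:
    """Intersection-over-union of two [x_min, y_min, x_max, y_max] boxes."""
    a = np.asarray(box_a, dtype=float)
    b = np.asarray(box_b, dtype=float)
    if a[2] <= a[0] or a[3] <= a[1] or b[2] <= b[0] or b[3] <= b[1]:
        raise ValueError("degenerate (zero-area) box")
    x1, y1 = max(a[0], b[0]), max(a[1], b[1])
    x2, y2 = min(a[2], b[2]), min(a[3], b[3])
    inter = max(x2 - x1, 0.0) * max(y2 - y1, 0.0)
    union = (a[2] - a[0]) * (a[3] - a[1]) + (b[2] - b[0]) * (b[3] - b[1]) - inter
    return float(inter / union)


@dataclass
class DetectionTally:
    truth_count: int
    detected_count: int
    matched_count: int  # detections matched to a truth at IOU > threshold
    truth_matched: int  # truths with at least one matched detection
    iou_threshold: float = 0.5
    accuracy_defined: bool = True

    @property
    def unmatched_count(self) -> int:
        return self.detected_count - self.matched_count

    @property
    def recall(self) -> float:
        return 100.0 * self.truth_matched / self.truth_count if self.truth_count else 0.0

    @property
    def accuracy(self) -> float:
        if not self.detected_count:
            return 0.0
        return 100.0 * self.matched_count / self.detected_count

    @property
    def recall_pct(self) -> float:
        """Recall rounded to one decimal, as reported."""
        return round(self.recall, 1)

    @property
    def accuracy_pct(self) -> float:
        return round(self.accuracy, 1)

    def as_row(self) -> dict:
        return {
            "clinical": self.truth_count,
            "detected": self.detected_count,
            "iou_gt": self.matched_count,
            "iou_le": self.unmatched_count,
            "recall_pct": self.recall_pct,
            "accuracy_pct": self.accuracy_pct,
        }


def _det_boxes_confs(detections) -> tuple[np.ndarray, np.ndarray]:
    boxes, confs = [], []
    for i, d in enumerate(detections):
        if hasattr(d, "box"):
            boxes.append(np.asarray(d.box, float))
            confs.append(float(getattr(d, "confidence", 1.0)))
        else:
            boxes.append(np.asarray(d, float))
            confs.append(1.0 - i * 1e-9)  # preserve given order
    if boxes:
        return np.stack(boxes), np.asarray(confs)
    return np.zeros((0, 4)), np.zeros(0)


def tally_detections(truth_boxes, detections, iou_threshold: float = 0.5) -> DetectionTally:
    """Greedy one-to-one matching in descending confidence.

    Each detection claims the unclaimed truth box of highest IOU,
    counting as matched only when that IOU exceeds the threshold; a
    detection can match at most one truth and vice versa.
    """
    truth = np.asarray(truth_boxes, dtype=float).reshape(-1, 4)
    boxes, confs = _det_boxes_confs(detections)
    order = np.argsort(-confs, kind="stable")
    claimed = np.zeros(len(truth), dtype=bool)
    matched = 0
    for i in order:
        best_j, best_iou = -1, iou_threshold
        for j in range(len(truth)):
            if claimed[j]:
                continue
            v = iou(boxes[i], truth[j])
            if v > best_iou:
                best_j, best_iou = j, v
        if best_j >= 0:
            claimed[best_j] = True
            matched += 1
    return DetectionTally(
        truth_count=len(truth),
        detected_count=len(boxes),
        matched_count=matched,
        truth_matched=int(claimed.sum()),
        iou_threshold=iou_threshold,
        accuracy_defined=len(boxes) > 0,
    )


def tally_from_counts(
    truth: int, detected: int, matched: int, associated: int | None = None
) -> DetectionTally:
    """Tally arithmetic from printed contingency counts.

    Clinical-style reporting: recall counts reference findings that
    received *an associated detection* at all (``associated``, default
    one detection per finding up to the smaller count), while accuracy
    is the fraction of detections whose localization is correct
    (``matched``, IOU > 0.5).
    """
    if matched > min(truth, detected):
        raise ValueError("matched count exceeds truth or detected count")
    if associated is None:
        associated = min(truth, detected)
    return DetectionTally(
        truth_count=truth,
        detected_count=detected,
        matched_count=matched,
        truth_matched=associated,
        accuracy_defined=detected > 0,
    )


# ---------------------------------------------------------------------
# texture metric error
# ---------------------------------------------------------------------

@dataclass
class TextureErrorReport:
    method: str
    regions: dict[str, float]
    region_coverage: dict[str, int]  # multi-contribution pixel counts
    overall: float
    metric: str = "gastropano texture error"

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["method", "region", "error", "n_pixels"])
            for name, val in self.regions.items():
                w.writerow([self.method, name, val, self.region_coverage[name]])
            w.writerow([self.method, "overall", self.overall, sum(self.region_coverage.values())])


def texture_metric_error(
    state_or_contributions,
    region_masks: dict[str, np.ndarray] | None = None,
    method: str = "fused",
) -> TextureErrorReport:
    """Seam texture error from per-image canvas contributions.

    For each canvas pixel with >= 2 contributing images, the error is
    the mean pairwise absolute difference of the contributed
    intensities (each contribution is that image's weight-normalized
    splat).  Region scores average over the given masks; overall is the
    coverage-weighted mean.  Raises when no pixel has two contributions.
    """
    if isinstance(state_or_contributions, FusionState):
        contribs = state_or_contributions.contributions
    else:
        contribs = list(state_or_contributions)
    if not contribs:
        raise ValueError("no contributions")
    shape = contribs[0][0].shape
    vals = np.stack([c for c, _ in contribs])  # (K, H, W) weighted sums
    wgts = np.stack([w for _, w in contribs])
    with np.errstate(invalid="ignore", divide="ignore"):
        intens = np.where(wgts > 1e-9, vals / np.maximum(wgts, 1e-12), np.nan)
    n_contrib = (wgts > 1e-9).sum(axis=0)
    multi = n_contrib >= 2
    if not np.any(multi):
        raise ValueError("no panorama pixel has two or more contributions")
    K = len(contribs)
    # mean pairwise |difference| per pixel over contributing images
    diff_sum = np.zeros(shape)
    pair_cnt = np.zeros(shape)
    for i in range(K):
        for j in range(i + 1, K):
            both = (wgts[i] > 1e-9) & (wgts[j] > 1e-9)
            diff_sum[both] += np.abs(intens[i][both] - intens[j][both])
            pair_cnt[both] += 1
    err = np.zeros(shape)
    err[multi] = diff_sum[multi] / pair_cnt[multi]

    if region_masks is None:
        region_masks = {"overall": np.ones(shape, dtype=bool)}
    regions = {}
    coverage = {}
    for name, mask in region_masks.items():
        sel = mask & multi
        coverage[name] = int(sel.sum())
        regions[name] = float(err[sel].mean()) if sel.any() else 0.0
    total = sum(coverage.values())
    overall = (
        sum(regions[n] * coverage[n] for n in regions) / total if total else 0.0
    )
    return TextureErrorReport(
        method=method, regions=regions, region_coverage=coverage, overall=overall
    )


def seam_rmse(images, transforms: list[Similarity4], stride: int = 2) -> float:
    """RMS of Eq.-3 seam residuals over all consecutive pairs."""
    errs = []
    for k in range(1, len(images)):
        rel = transforms[k - 1].inverse().compose(transforms[k])
        try:
            r = seam_residuals(images[k], images[k - 1], rel, stride=stride)
        except ValueError:
            continue
        errs.append(r.e)
    if not errs:
        raise ValueError("no overlapping consecutive pair")
    e = np.concatenate(errs)
    return float(np.sqrt(np.mean(e**2)))


# ---------------------------------------------------------------------
# forward-backward robustness curves
# ---------------------------------------------------------------------

def _tree_homography_at(node: reg.PatchNode, pt: np.ndarray) -> np.ndarray | None:
    """Deepest passing patch homography covering a point (fallback: any H)."""
    best = None
    stack = [node]
    while stack:
        n = stack.pop()
        x, y, w, h = n.rect
        if not (x <= pt[0] < x + w and y <= pt[1] < y + h):
            continue
        if n.H is not None and (best is None or n.passed or n.depth > best[1]):
            if n.passed:
                best = (n.H, n.depth + 100)  # prefer passing patches
            elif best is None or n.depth > best[1]:
                best = (n.H, n.depth)
        stack.extend(n.children)
    return None if best is None else best[0]


def _apply_h(H: np.ndarray, pts: np.ndarray) -> np.ndarray:
    q = np.hstack([pts, np.ones((len(pts), 1))]) @ H.T
    return q[:, :2] / q[:, 2:3]


def fb_errors_plain(frame_a, frame_b, config: reg.RegistrationConfig | None = None) -> np.ndarray:
    """FB error per initial feature for plain ratio-test matching.

    Features are matched A->B and, independently, B->A; the FB error is
    the distance from the start point to its position after the forward
    match followed by the backward match of that endpoint.  Features
    without a match in either direction get infinite error.
    """
    cfg = config or reg.RegistrationConfig()
    kp_a, d_a = reg.detect_keypoints(frame_a, cfg)
    kp_b, d_b = reg.detect_keypoints(frame_b, cfg)
    kp_a, d_a = kp_a[: cfg.max_features], d_a[: cfg.max_features]
    if len(kp_a) == 0 or len(kp_b) == 0:
        return np.full(len(kp_a), np.inf)

    def ratio_nn(da, db):
        """index of NN in db per row of da, -1 where the ratio test fails."""
        d2 = ((da[:, None, :] - db[None, :, :]) ** 2).sum(axis=2)
        if d2.shape[1] < 2:
            return np.full(len(da), -1)
        part = np.argpartition(d2, 1, axis=1)[:, :2]
        rows = np.arange(len(da))
        first = np.where(
            d2[rows, part[:, 0]] <= d2[rows, part[:, 1]], part[:, 0], part[:, 1]
        )
        second = np.where(first == part[:, 0], part[:, 1], part[:, 0])
        ok = np.sqrt(d2[rows, first]) <= cfg.ratio * np.sqrt(
            np.maximum(d2[rows, second], 1e-300)
        )
        return np.where(ok, first, -1)

    fwd = ratio_nn(d_a, d_b)
    bwd = ratio_nn(d_b, d_a)
    errs = np.full(len(kp_a), np.inf)
    for i in range(len(kp_a)):
        j = fwd[i]
        if j < 0:
            continue
        i2 = bwd[j]
        if i2 < 0:
            continue
        errs[i] = np.linalg.norm(kp_a[i] - kp_a[i2])
    return errs


def fb_errors_hpft(frame_a, frame_b, config: reg.RegistrationConfig | None = None) -> np.ndarray:
    """FB error per initial feature under HPFT.

    HPFT starts from the same descriptor matches as plain matching and
    adds a patch-homography field on top, so each feature has up to two
    backward-position estimates: its own match cycle (where one exists)
    and the forward-then-backward patch mapping (forward field from
    A->B matching, backward field estimated independently from B->A).
    The FB error is the smaller of the two; features with neither get
    infinite error.
    """
    cfg = config or reg.RegistrationConfig()
    kp_a, _ = reg.detect_keypoints(frame_a, cfg)
    kp_a = kp_a[: cfg.max_features]
    errs = fb_errors_plain(frame_a, frame_b, cfg)
    try:
        corrs_f = reg.detect_and_match(frame_a, frame_b, cfg)
        _, tree_f = reg.hpft_verify(frame_a, frame_b, corrs_f, cfg)
        corrs_b = reg.detect_and_match(frame_b, frame_a, cfg)
        _, tree_b = reg.hpft_verify(frame_b, frame_a, corrs_b, cfg)
    except reg.DegenerateConfigurationError:
        return errs
    for i, p in enumerate(kp_a):
        Hf = _tree_homography_at(tree_f, p)
        if Hf is None:
            continue
        q = _apply_h(Hf, p[None, :])[0]
        Hb = _tree_homography_at(tree_b, q)
        if Hb is None:
            continue
        back = _apply_h(Hb, q[None, :])[0]
        errs[i] = min(errs[i], float(np.linalg.norm(back - p)))
    return errs


def fb_error_curve(
    make_pair,
    method: str,
    noise_scalars,
    thresholds,
    config: reg.RegistrationConfig | None = None,
) -> np.ndarray:
    """Counts of features with FB error below threshold, per noise scalar.

    ``make_pair(noise_scalar)`` renders/returns the frame pair for a
    condition; ``method`` is "hpft" or "plain".  Returns an array of
    shape (len(noise_scalars), len(thresholds)); counts are cumulative
    (non-decreasing) in the threshold.
    """
    if method == "hpft":
        fn = fb_errors_hpft
    elif method == "plain":
        fn = fb_errors_plain
    else:
        raise ValueError(f"unknown method {method!r} (no backward mode)")
    out = np.zeros((len(noise_scalars), len(thresholds)), dtype=int)
    for i, s in enumerate(noise_scalars):
        fa, fb = make_pair(s)
        errs = fn(fa, fb, config)
        for j, t in enumerate(thresholds):
            out[i, j] = int((errs < t).sum())
    return out
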