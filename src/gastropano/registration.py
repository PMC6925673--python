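"""Feature registration with homographic patch verification (HPFT).

Pairwise registration proceeds in three steps:

1. detect SIFT keypoints in both frames and match descriptors with a
   ratio test (``detect_and_match``);
2. estimate the frame-to-frame homography ``m' ~ rho H m``, optionally
   with seeded RANSAC (``estimate_homography``);
3. verify matches by homographic patch subdivision (``hpft_verify``): a
   quadtree over frame A is refined until each patch, warped by its
   local homography into frame B, has an intensity histogram close to
   its counterpart under symmetric KL divergence.  Correspondences in a
   passing patch are accepted only if they also agree with the patch
   homography to within a reprojection threshold; correspondences whose
   patch never passes are rejected.

Mucosal scenes are dominated by regional peristalsis, so locally
homographic patches are a good model even when a single global
homography is not.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.feature import SIFT, match_descriptors

from .phantom import Frame

__all__ = [
    "Correspondence",
    "Homography",
    "PatchNode",
    "RegistrationConfig",
    "detect_and_match",
    "estimate_homography",
    "hpft_verify",
    "symmetric_kl",
    "DegenerateConfigurationError",
]


class DegenerateConfigurationError(ValueError):
    pass


@dataclass
class Correspondence:
    m: np.ndarray  # (2,) point in frame A, px
    m_prime: np.ndarray  # (2,) point in frame B, px
    distance: float = 0.0  # descriptor distance
    verified: bool = False


@dataclass
class Homography:
    H: np.ndarray  # 3x3, normalized H[2,2] = 1
    rho: float = 1.0  # pre-normalization scale of Eq. m' = rho H m

    def apply(self, pts: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(pts, dtype=float))
        q = np.hstack([p, np.ones((len(p), 1))]) @ self.H.T
        return q[:, :2] / q[:, 2:3]

    def inverse(self) -> "Homography":
        Hi = np.linalg.inv(self.H)
        return Homography(H=Hi / Hi[2, 2], rho=1.0 / max(self.rho, 1e-12))


@dataclass
class PatchNode:
    rect: tuple[int, int, int, int]  # x, y, w, h in frame A
    depth: int
    H: np.ndarray | None = None
    kl: float | None = None
    passed: bool = False
    corr_indices: list[int] = field(default_factory=list)
    children: list["PatchNode"] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "rect": list(self.rect),
            "depth": self.depth,
            "kl": self.kl,
            "passed": self.passed,
            "n_corrs": len(self.corr_indices),
            "children": [c.to_dict() for c in self.children],
        }


@dataclass
class RegistrationConfig:
    max_features: int = 200
    ratio: float = 0.8
    ransac_iters: int = 500
    ransac_px: float = 2.0
    seed: int = 0
    kl_threshold: float = 0.15
    min_patch_px: int = 16
    max_depth: int = 4
    reproj_px: float = 2.0
    hist_bins: int = 32
    c_dog: float = 0.004  # SIFT DoG contrast threshold
    detect_sigma: float = 0.0  # Gaussian noise suppression before detection


# ---------------------------------------------------------------------
# detection + matching
# ---------------------------------------------------------------------

def _as_frame(x) -> Frame:
    if isinstance(x, Frame):
        return x
    return Frame(index=-1, gray=np.asarray(x, dtype=float))


def detect_keypoints(frame: Frame | np.ndarray, config: "RegistrationConfig | None" = None):
    """SIFT keypoints + descriptors, response-ranked, mask-restricted."""
    cfg = config or RegistrationConfig()
    fr = _as_frame(frame)
    gray = fr.gray
    if cfg.detect_sigma > 0:
        gray = ndimage.gaussian_filter(gray, cfg.detect_sigma, mode="nearest")
    det = SIFT(c_dog=cfg.c_dog, n_scales=3)
    try:
        det.detect_and_extract(gray)
    except RuntimeError:  # no keypoints found
        return np.zeros((0, 2)), np.zeros((0, 128))
    kp = det.keypoints[:, ::-1].astype(float)  # (x, y)
    desc = det.descriptors.astype(float)
    mask = fr.valid_mask()
    keep = mask[
        np.clip(det.keypoints[:, 0], 0, mask.shape[0] - 1),
        np.clip(det.keypoints[:, 1], 0, mask.shape[1] - 1),
    ]
    kp, desc = kp[keep], desc[keep]
    # rank by blob response so truncation keeps the strongest features
    resp = np.abs(ndimage.gaussian_laplace(gray, sigma=1.5))
    r = resp[
        np.clip(kp[:, 1].astype(int), 0, resp.shape[0] - 1),
        np.clip(kp[:, 0].astype(int), 0, resp.shape[1] - 1),
    ]
    order = np.argsort(-r, kind="stable")
    return kp[order], desc[order]


def detect_and_match(
    frame_a: Frame | np.ndarray,
    frame_b: Frame | np.ndarray,
    config: RegistrationConfig | None = None,
) -> list[Correspondence]:
    """Ratio-test SIFT matching, sorted by descriptor distance.

    Raises ``DegenerateConfigurationError`` when fewer than 4 matches
    survive (no homography is estimable from them).
    """
    cfg = config or RegistrationConfig()
    kp_a, d_a = detect_keypoints(frame_a, cfg)
    kp_b, d_b = detect_keypoints(frame_b, cfg)
    if len(kp_a) < 4 or len(kp_b) < 4:
        raise DegenerateConfigurationError(
            f"too few keypoints ({len(kp_a)} vs {len(kp_b)})"
        )
    pairs = match_descriptors(
        d_a, d_b, cross_check=True, max_ratio=cfg.ratio
    )
    if len(pairs) < 4:
        raise DegenerateConfigurationError(f"only {len(pairs)} matches")
    dist = np.linalg.norm(d_a[pairs[:, 0]] - d_b[pairs[:, 1]], axis=1)
    # stable sort on (distance, keypoint index): deterministic tie-break
    order = np.lexsort((pairs[:, 0], dist))[: cfg.max_features]
    return [
        Correspondence(
            m=kp_a[pairs[i, 0]].copy(),
            m_prime=kp_b[pairs[i, 1]].copy(),
            distance=float(dist[i]),
        )
        for i in order
    ]


# ---------------------------------------------------------------------
# homography estimation
# ---------------------------------------------------------------------

def _dlt(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """Normalized DLT homography from >= 4 correspondences."""

    def normalizer(p):
        c = p.mean(axis=0)
        s = np.sqrt(2) / max(np.linalg.norm(p - c, axis=1).mean(), 1e-12)
        T = np.array([[s, 0, -s * c[0]], [0, s, -s * c[1]], [0, 0, 1]])
        return T

    Ta, Tb = normalizer(src), normalizer(dst)
    sa = (np.hstack([src, np.ones((len(src), 1))]) @ Ta.T)[:, :2]
    sb = (np.hstack([dst, np.ones((len(dst), 1))]) @ Tb.T)[:, :2]
    A = []
    for (x, y), (u, v) in zip(sa, sb):
        A.append([-x, -y, -1, 0, 0, 0, u * x, u * y, u])
        A.append([0, 0, 0, -x, -y, -1, v * x, v * y, v])
    A = np.asarray(A)
    _, s, vt = np.linalg.svd(A)
    if s[-2] < 1e-10 * s[0]:
        raise DegenerateConfigurationError(
            "degenerate correspondence configuration (collinear points?)"
        )
    h = vt[-1].reshape(3, 3)
    return np.linalg.inv(Tb) @ h @ Ta


def transfer_errors(H: np.ndarray, src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """Symmetric transfer error per correspondence, px."""
    try:
        Hi = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return np.full(len(src), np.inf)
    f = np.hstack([src, np.ones((len(src), 1))]) @ H.T
    b = np.hstack([dst, np.ones((len(dst), 1))]) @ Hi.T
    with np.errstate(divide="ignore", invalid="ignore"):
        ef = np.linalg.norm(f[:, :2] / f[:, 2:3] - dst, axis=1)
        eb = np.linalg.norm(b[:, :2] / b[:, 2:3] - src, axis=1)
    e = 0.5 * (ef + eb)
    return np.where(np.isfinite(e), e, np.inf)


def estimate_homography(
    corrs: list[Correspondence],
    robust: bool = False,
    config: RegistrationConfig | None = None,
) -> tuple[Homography, np.ndarray]:
    """Fit ``m' ~ rho H m``; returns (Homography, inlier index array).

    ``robust=True`` runs seeded RANSAC (threshold ``config.ransac_px``)
    followed by a DLT refit on the inliers; otherwise all
    correspondences are used and reported as inliers.
    """
    cfg = config or RegistrationConfig()
    if len(corrs) < 4:
        raise DegenerateConfigurationError("need at least 4 correspondences")
    src = np.stack([c.m for c in corrs]).astype(float)
    dst = np.stack([c.m_prime for c in corrs]).astype(float)
    if robust:
        rng = np.random.default_rng(cfg.seed)
        best_inl = None
        for _ in range(cfg.ransac_iters):
            idx = rng.choice(len(corrs), 4, replace=False)
            try:
                H = _dlt(src[idx], dst[idx])
            except (DegenerateConfigurationError, np.linalg.LinAlgError):
                continue
            err = transfer_errors(H, src, dst)
            inl = err < cfg.ransac_px
            if best_inl is None or inl.sum() > best_inl.sum():
                best_inl = inl
        if best_inl is None or best_inl.sum() < 4:
            raise DegenerateConfigurationError("RANSAC found no valid model")
        Hraw = _dlt(src[best_inl], dst[best_inl])
        err = transfer_errors(Hraw, src, dst)
        inliers = np.flatnonzero(err < cfg.ransac_px)
    else:
        Hraw = _dlt(src, dst)
        inliers = np.arange(len(corrs))
    if abs(Hraw[2, 2]) < 1e-12:
        raise DegenerateConfigurationError("homography with vanishing H[2,2]")
    # DLT returns H up to scale; rho is the scale removed by H[2,2]=1
    rho = float(1.0 / abs(Hraw[2, 2]) * np.sign(Hraw[2, 2]))
    H = Hraw / Hraw[2, 2]
    return Homography(H=H, rho=abs(rho)), inliers


# ---------------------------------------------------------------------
# HPFT verification
# ---------------------------------------------------------------------

def symmetric_kl(p: np.ndarray, q: np.ndarray, eps: float = 1e-6) -> float:
    """Symmetric KL divergence between two normalized histograms."""
    p = np.asarray(p, dtype=float) + eps
    q = np.asarray(q, dtype=float) + eps
    p /= p.sum()
    q /= q.sum()
    return float(np.sum((p - q) * (np.log(p) - np.log(q))))


def _patch_kl(
    gray_a: np.ndarray,
    gray_b: np.ndarray,
    rect: tuple[int, int, int, int],
    H: np.ndarray,
    bins: int,
) -> float | None:
    """KL between a patch of A and its H-warped counterpart in B.

    Returns None when too little of the warped patch lands inside B.
    """
    x, y, w, h = rect
    yy, xx = np.mgrid[y : y + h, x : x + w]
    pts = np.stack([xx.ravel(), yy.ravel(), np.ones(xx.size)])
    q = H @ pts
    with np.errstate(divide="ignore", invalid="ignore"):
        qx = q[0] / q[2]
        qy = q[1] / q[2]
    valid = (
        np.isfinite(qx)
        & np.isfinite(qy)
        & (qx >= 0)
        & (qx <= gray_b.shape[1] - 1)
        & (qy >= 0)
        & (qy <= gray_b.shape[0] - 1)
    )
    if valid.sum() < 0.25 * xx.size or valid.sum() < 16:
        return None
    vals_a = gray_a[yy.ravel()[valid], xx.ravel()[valid]]
    vals_b = ndimage.map_coordinates(
        gray_b, np.stack([qy[valid], qx[valid]]), order=1
    )
    edges = np.linspace(0, 1, bins + 1)
    ha, _ = np.histogram(vals_a, bins=edges)
    hb, _ = np.histogram(vals_b, bins=edges)
    return symmetric_kl(ha, hb)


def hpft_verify(
    frame_a: Frame | np.ndarray,
    frame_b: Frame | np.ndarray,
    corrs: list[Correspondence],
    config: RegistrationConfig | None = None,
) -> tuple[list[Correspondence], PatchNode]:
    """Verify correspondences by homographic patch subdivision.

    Returns the input correspondences (with ``verified`` set in place)
    and the quadtree for inspection.
    """
    cfg = config or RegistrationConfig()
    if len(corrs) < 4:
        raise DegenerateConfigurationError("need at least 4 correspondences")
    fa, fb = _as_frame(frame_a), _as_frame(frame_b)
    if fa.gray.shape != fb.gray.shape:
        raise ValueError("frames must have the same size")
    for c in corrs:
        c.verified = False
    src = np.stack([c.m for c in corrs])
    dst = np.stack([c.m_prime for c in corrs])

    def local_h(indices: np.ndarray, fallback: np.ndarray | None) -> np.ndarray | None:
        if len(indices) >= 4:
            sub = [corrs[i] for i in indices]
            try:
                hom, _ = estimate_homography(sub, robust=True, config=cfg)
                return hom.H
            except DegenerateConfigurationError:
                pass
        return fallback

    def build(rect, depth, parent_h):
        x, y, w, h = rect
        inside = np.flatnonzero(
            (src[:, 0] >= x) & (src[:, 0] < x + w)
            & (src[:, 1] >= y) & (src[:, 1] < y + h)
        )
        node = PatchNode(rect=rect, depth=depth, corr_indices=list(inside))
        H = local_h(inside, parent_h)
        node.H = H
        if H is None:
            return node  # unverifiable patch: corrs stay rejected
        kl = _patch_kl(fa.gray, fb.gray, rect, H, cfg.hist_bins)
        node.kl = kl
        can_split = (
            depth < cfg.max_depth
            and w // 2 >= cfg.min_patch_px
            and h // 2 >= cfg.min_patch_px
        )
        if kl is not None and kl <= cfg.kl_threshold:
            node.passed = True
            if len(inside):
                err = transfer_errors(H, src[inside], dst[inside])
                for i, e in zip(inside, err):
                    if e <= cfg.reproj_px:
                        corrs[i].verified = True
            return node
        if can_split:
            # subdivide from the patch center into 4 quadrants
            w2, h2 = w // 2, h // 2
            for rx, ry, rw, rh in (
                (x, y, w2, h2),
                (x + w2, y, w - w2, h2),
                (x, y + h2, w2, h - h2),
                (x + w2, y + h2, w - w2, h - h2),
            ):
                node.children.append(build((rx, ry, rw, rh), depth + 1, H))
        return node

    Hh, Ww = fa.gray.shape
    root = build((0, 0, Ww, Hh), 0, None)
    return corrs, root


# ---------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------

def save_correspondences(path, corrs: list[Correspondence], frame_a_idx: int = 0, frame_b_idx: int = 1) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["frame_a_idx", "frame_b_idx", "x", "y", "x_prime", "y_prime", "verified"])
        for c in corrs:
            w.writerow(
                [frame_a_idx, frame_b_idx, c.m[0], c.m[1], c.m_prime[0], c.m_prime[1], int(c.verified)]
            )


def save_patch_tree(path, root: PatchNode) -> None:
    Path(path).write_text(json.dumps(root.to_dict(), indent=1))
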