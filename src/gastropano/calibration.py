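"""Fisheye calibration from chessboard views and frame undistortion.

Endoscope optics bend straight lines severely; registration assumes
undistorted frames, so the pipeline starts from a chessboard
calibration of the equidistant fisheye model:

1. inner chessboard corners are detected (Harris + subpixel refinement)
   and ordered into the known grid;
2. intrinsics are initialized by Zhang's homography method (ignoring
   distortion), per-view poses from the homographies;
3. all parameters — (fx, fy, cx, cy), k1..k4 and the per-view poses —
   are refined jointly by Levenberg-Marquardt on the pixel reprojection
   error, whose RMS is always reported.

Undistortion inverse-maps each ideal pinhole pixel through the
distortion model with bilinear interpolation; pixels whose source falls
outside the captured frame are zeroed and flagged in a validity mask
that the registration stage consumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize
from scipy.spatial.transform import Rotation
from skimage.feature import corner_harris, corner_peaks, corner_subpix

from .camera import CameraModel
from .phantom import Frame

__all__ = [
    "CalibrationResult",
    "ChessboardPattern",
    "find_chessboard_corners",
    "calibrate_fisheye",
    "calibrate_fisheye_from_points",
    "undistort",
    "render_chessboard",
]


@dataclass(frozen=True)
class ChessboardPattern:
    cols: int  # squares across
    rows: int  # squares down
    square_mm: float

    @property
    def inner(self) -> tuple[int, int]:
        return self.cols - 1, self.rows - 1

    def object_points(self) -> np.ndarray:
        """Inner-corner coordinates on the board plane (z = 0), mm."""
        ic, ir = self.inner
        xs, ys = np.meshgrid(np.arange(1, ic + 1), np.arange(1, ir + 1))
        return np.stack(
            [xs.ravel() * self.square_mm, ys.ravel() * self.square_mm,
             np.zeros(ic * ir)],
            axis=1,
        )


@dataclass
class CalibrationResult:
    camera: CameraModel
    rms_px: float
    per_view_rms: list[float]
    n_views: int


# ---------------------------------------------------------------------
# corner detection
# ---------------------------------------------------------------------

def find_chessboard_corners(
    image: np.ndarray | Frame, pattern: ChessboardPattern
) -> np.ndarray:
    """Detect and grid-order the inner corners; (N, 2) as (x, y) px.

    Ordering: principal axes of the detected point cloud give grid
    directions; points are split into rows along the minor axis and
    sorted along the major axis.  Raises ``ValueError`` when the
    expected corner count is not found.
    """
    gray = image.gray if isinstance(image, Frame) else np.asarray(image, float)
    ic, ir = pattern.inner
    n_expect = ic * ir
    resp = corner_harris(gray, sigma=2.0)
    peaks = corner_peaks(
        resp, min_distance=4, threshold_rel=0.02, num_peaks=n_expect
    )
    if len(peaks) != n_expect:
        raise ValueError(
            f"found {len(peaks)} corners, expected {n_expect}"
        )
    sub = corner_subpix(gray, peaks, window_size=11)
    bad = np.any(np.isnan(sub), axis=1)
    sub[bad] = peaks[bad]
    pts = sub[:, ::-1]  # (x, y)

    centered = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    e1 = vt[0] if ic >= ir else vt[1]
    e2 = vt[1] if ic >= ir else vt[0]
    # canonical orientation: major axis to +x, minor to +y
    if e1[0] < 0:
        e1 = -e1
    if e2[1] < 0:
        e2 = -e2
    a = centered @ e1
    b = centered @ e2
    order = np.argsort(b, kind="stable")
    # split into rows at the (ir - 1) largest gaps along the minor axis;
    # equal-size chunking misassigns corners when tilt brings adjacent
    # rows close together
    gaps = np.diff(b[order])
    cuts = np.sort(np.argsort(-gaps)[: ir - 1]) + 1 if ir > 1 else []
    rows_idx = np.split(order, cuts)
    out = []
    for row in rows_idx:
        if len(row) != ic:
            raise ValueError("corner grid ordering failed (uneven rows)")
        out.append(row[np.argsort(a[row], kind="stable")])
    return pts[np.concatenate(out)]


# ---------------------------------------------------------------------
# Zhang initialization
# ---------------------------------------------------------------------

def _homography(obj_xy: np.ndarray, img_xy: np.ndarray) -> np.ndarray:
    def norm_t(p):
        c = p.mean(axis=0)
        s = np.sqrt(2) / max(np.linalg.norm(p - c, axis=1).mean(), 1e-12)
        return np.array([[s, 0, -s * c[0]], [0, s, -s * c[1]], [0, 0, 1]])

    Ta, Tb = norm_t(obj_xy), norm_t(img_xy)
    oa = (np.hstack([obj_xy, np.ones((len(obj_xy), 1))]) @ Ta.T)[:, :2]
    ob = (np.hstack([img_xy, np.ones((len(img_xy), 1))]) @ Tb.T)[:, :2]
    A = []
    for (x, y), (u, v) in zip(oa, ob):
        A.append([-x, -y, -1, 0, 0, 0, u * x, u * y, u])
        A.append([0, 0, 0, -x, -y, -1, v * x, v * y, v])
    _, _, vt = np.linalg.svd(np.asarray(A))
    H = np.linalg.inv(Tb) @ vt[-1].reshape(3, 3) @ Ta
    return H / H[2, 2]


def _zhang_intrinsics(homographies: list[np.ndarray], size: tuple[int, int]):
    def v_ij(H, i, j):
        return np.array(
            [
                H[0, i] * H[0, j],
                H[0, i] * H[1, j] + H[1, i] * H[0, j],
                H[1, i] * H[1, j],
                H[2, i] * H[0, j] + H[0, i] * H[2, j],
                H[2, i] * H[1, j] + H[1, i] * H[2, j],
                H[2, i] * H[2, j],
            ]
        )

    V = []
    for H in homographies:
        V.append(v_ij(H, 0, 1))
        V.append(v_ij(H, 0, 0) - v_ij(H, 1, 1))
    _, _, vt = np.linalg.svd(np.asarray(V))
    b11, b12, b22, b13, b23, b33 = vt[-1]
    try:
        cy = (b12 * b13 - b11 * b23) / (b11 * b22 - b12**2)
        lam = b33 - (b13**2 + cy * (b12 * b13 - b11 * b23)) / b11
        fx = np.sqrt(lam / b11)
        fy = np.sqrt(lam * b11 / (b11 * b22 - b12**2))
        cx = -b13 * fx**2 / lam
        if not (np.isfinite([fx, fy, cx, cy]).all() and fx > 0 and fy > 0):
            raise FloatingPointError
    except (FloatingPointError, ZeroDivisionError, ValueError):
        # fall back to a generic wide-angle guess
        w, h = size
        fx = fy = 0.8 * w
        cx, cy = (w - 1) / 2, (h - 1) / 2
    return fx, fy, cx, cy


def _pose_from_h(H: np.ndarray, K: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    M = np.linalg.inv(K) @ H
    s = 1.0 / np.linalg.norm(M[:, 0])
    r1, r2, t = s * M[:, 0], s * M[:, 1], s * M[:, 2]
    r3 = np.cross(r1, r2)
    R = np.stack([r1, r2, r3], axis=1)
    U, _, Vt = np.linalg.svd(R)
    R = U @ Vt
    if np.linalg.det(R) < 0:
        R = -R
        t = -t
    if t[2] < 0:  # board must be in front of the camera
        R[:, :2] *= -1
        t = -t
    return R, t


# ---------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------

def calibrate_fisheye(
    chessboard_images: list[np.ndarray | Frame],
    pattern: ChessboardPattern,
) -> CalibrationResult:
    """Joint fisheye calibration from full-pattern chessboard views.

    Requires at least 3 images with the full pattern detected; raises
    ``ValueError`` listing the images where detection failed if fewer
    remain.
    """
    if len(chessboard_images) < 3:
        raise ValueError(
            f"need at least 3 chessboard images, got {len(chessboard_images)}"
        )
    detections = []
    failures = []
    for i, img in enumerate(chessboard_images):
        try:
            detections.append((i, find_chessboard_corners(img, pattern)))
        except ValueError as exc:
            failures.append((i, str(exc)))
    if len(detections) < 3:
        raise ValueError(
            "pattern not found in enough images; failures: "
            + "; ".join(f"image {i}: {msg}" for i, msg in failures)
        )
    first = chessboard_images[0]
    shape = (first.gray if isinstance(first, Frame) else first).shape
    return calibrate_fisheye_from_points(
        [pts for _, pts in detections], pattern, (shape[1], shape[0])
    )


def calibrate_fisheye_from_points(
    image_points: list[np.ndarray],
    pattern: ChessboardPattern,
    size: tuple[int, int],
) -> CalibrationResult:
    """Calibrate from already-detected, grid-ordered corner observations.

    ``size`` is (width, height) px.  This is the estimation core of
    :func:`calibrate_fisheye`; it is public so corner observations from
    other detectors (or exact synthetic projections) can be used.
    """
    obj = pattern.object_points()
    detections = [(i, np.asarray(p, dtype=float)) for i, p in enumerate(image_points)]
    w_img, h_img = size

    homs = [_homography(obj[:, :2], pts) for _, pts in detections]
    fx, fy, cx, cy = _zhang_intrinsics(homs, (w_img, h_img))
    cx = float(np.clip(cx, 0, w_img - 1))
    cy = float(np.clip(cy, 0, h_img - 1))
    K = np.array([[fx, 0, cx], [0, fy, cy], [0, 0, 1.0]])
    poses = [_pose_from_h(H, K) for H in homs]

    n_views = len(detections)
    x0 = np.concatenate(
        [
            [fx, fy, cx, cy, 0.0, 0.0, 0.0, 0.0],
            np.concatenate(
                [
                    np.concatenate([Rotation.from_matrix(R).as_rotvec(), t])
                    for R, t in poses
                ]
            ),
        ]
    )

    def unpack(x):
        cam = CameraModel(
            fx=max(x[0], 1e-3), fy=max(x[1], 1e-3),
            cx=float(np.clip(x[2], 0, w_img - 1)),
            cy=float(np.clip(x[3], 0, h_img - 1)),
            width=w_img, height=h_img, k=x[4:8], distortion="fisheye",
        )
        views = [
            (Rotation.from_rotvec(x[8 + 6 * i : 11 + 6 * i]).as_matrix(),
             x[11 + 6 * i : 14 + 6 * i])
            for i in range(n_views)
        ]
        return cam, views

    # small ridge on k: coefficients the data cannot constrain (higher
    # orders at modest view angles) go to zero instead of wandering
    k_ridge = np.array([1.0, 1.0, 30.0, 100.0])

    def residuals(x, free_k=True):
        cam, views = unpack(x)
        res = []
        for (R, t), (_, pts) in zip(views, detections):
            proj, _ = cam.project(obj @ R.T + t)
            res.append((proj - pts).ravel())
        res.append(k_ridge * x[4:8])
        out = np.concatenate(res)
        return np.where(np.isfinite(out), out, 1e3)

    # stage 1: distortion pinned at zero (robust to the pinhole-biased
    # Zhang initialization); stage 2: everything free
    def residuals_nok(x_nok):
        x = np.concatenate([x_nok[:4], np.zeros(4), x_nok[4:]])
        return residuals(x)

    x0_nok = np.concatenate([x0[:4], x0[8:]])
    sol1 = optimize.least_squares(residuals_nok, x0_nok, method="lm", max_nfev=300)
    x1 = np.concatenate([sol1.x[:4], np.zeros(4), sol1.x[4:]])
    sol = optimize.least_squares(residuals, x1, method="lm", max_nfev=400)
    cam, views = unpack(sol.x)

    def per_view_errors(cam, views):
        out = []
        for (R, t), (_, pts) in zip(views, detections):
            proj, _ = cam.project(obj @ R.T + t)
            out.append(np.asarray(proj - pts))
        return out

    errs = per_view_errors(cam, views)
    per_view = [float(np.sqrt(np.mean(e**2))) for e in errs]
    # a grossly inconsistent view (mis-ordered corners slipping through,
    # partial occlusion) poisons the joint fit: drop and refit
    good = [rms_i <= max(1.0, 5 * np.median(per_view)) for rms_i in per_view]
    if not all(good) and sum(good) >= 3:
        kept = [pts for (_, pts), g in zip(detections, good) if g]
        result = calibrate_fisheye_from_points(kept, pattern, size)
        result.n_views = len(kept)
        return result
    rms = float(np.sqrt(np.mean(np.concatenate([e.ravel() ** 2 for e in errs]))))
    return CalibrationResult(
        camera=cam, rms_px=rms, per_view_rms=per_view, n_views=n_views
    )


# ---------------------------------------------------------------------
# undistortion
# ---------------------------------------------------------------------

def undistort(frame: Frame | np.ndarray, cam: CameraModel) -> Frame:
    """Resample a fisheye frame to the ideal pinhole camera.

    Output size equals the input; out-of-source pixels are zeroed and
    excluded from the validity mask.
    """
    fr = frame if isinstance(frame, Frame) else Frame(index=-1, gray=np.asarray(frame, float))
    if fr.gray.shape != (cam.height, cam.width):
        raise ValueError(
            f"frame size {fr.gray.shape} does not match camera "
            f"({cam.height}, {cam.width})"
        )
    if cam.is_pinhole:
        return Frame(
            index=fr.index, gray=fr.gray.copy(),
            color=None if fr.color is None else fr.color.copy(),
            mask=fr.valid_mask().copy(), pose=fr.pose,
        )
    yy, xx = np.mgrid[0 : cam.height, 0 : cam.width]
    pix = np.stack([xx.ravel().astype(float), yy.ravel().astype(float)], axis=1)
    src = cam.distort_points(pix)
    sx, sy = src[:, 0], src[:, 1]
    inside = (sx >= 0) & (sx <= cam.width - 1) & (sy >= 0) & (sy <= cam.height - 1)

    def warp(img):
        vals = ndimage.map_coordinates(img, np.stack([sy, sx]), order=1, cval=0.0)
        return np.where(inside, vals, 0.0).reshape(cam.height, cam.width)

    gray = warp(fr.gray)
    color = None
    if fr.color is not None:
        color = np.stack([warp(fr.color[..., c]) for c in range(3)], axis=-1)
    src_mask = ndimage.map_coordinates(
        fr.valid_mask().astype(float), np.stack([sy, sx]), order=1, cval=0.0
    )
    mask = (inside & (src_mask > 0.999)).reshape(cam.height, cam.width)
    return Frame(index=fr.index, gray=gray, color=color, mask=mask, pose=fr.pose)


# ---------------------------------------------------------------------
# synthetic chessboard views (test/calibration fixture generator)
# ---------------------------------------------------------------------

def render_chessboard(
    cam: CameraModel,
    pattern: ChessboardPattern,
    R: np.ndarray,
    t: np.ndarray,
    supersample: int = 2,
) -> np.ndarray:
    """Render a chessboard at pose (R, t) through the camera model.

    The board occupies ``[0, cols] x [0, rows]`` squares on its z = 0
    plane; light/dark squares at 0.9 / 0.1 on a 0.6 background.
    """
    s = supersample
    yy, xx = np.mgrid[0 : cam.height * s, 0 : cam.width * s]
    pix = np.stack(
        [(xx.ravel() + 0.5) / s - 0.5, (yy.ravel() + 0.5) / s - 0.5], axis=1
    )
    dirs = cam.unproject(pix)
    # ray-plane intersection with the board plane in camera coordinates
    n_cam = R[:, 2]
    p0_cam = t
    denom = dirs @ n_cam
    with np.errstate(divide="ignore", invalid="ignore"):
        lam = (p0_cam @ n_cam) / denom
    pts_cam = dirs * lam[:, None]
    board = (pts_cam - t) @ R  # board-frame coordinates
    bx = board[:, 0] / pattern.square_mm
    by = board[:, 1] / pattern.square_mm
    on_board = (
        (lam > 0)
        & (np.abs(denom) > 1e-9)
        & (bx >= 0) & (bx < pattern.cols)
        & (by >= 0) & (by < pattern.rows)
    )
    shade = np.where((np.floor(bx) + np.floor(by)) % 2 == 0, 0.9, 0.1)
    img = np.where(on_board, shade, 0.6)
    img = img.reshape(cam.height * s, cam.width * s)
    if s > 1:
        img = img.reshape(cam.height, s, cam.width, s).mean(axis=(1, 3))
    return img
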