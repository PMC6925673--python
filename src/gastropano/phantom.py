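"""Synthetic gastric-cavity phantom: scenes, trajectories and rendering.

Every downstream stage (registration, chain filtering, fusion,
projection, detection) is exercised against sequences rendered here,
with exact ground truth recorded before any degradation is applied:

* the cavity is the planar double-cube model, so the map between two
  views of the same face is an exact homography, recorded analytically
  from the poses (plane-induced homography);
* mucosa is band-limited value noise with darker vessel-like curves;
  polyps are circular blobs with a brighter rim, drawn into the face
  textures, so their panorama-space boxes are known exactly;
* degradations mimic endoscopic capture: additive specular highlights
  (wet mucosa reflections) and zero-mean Gaussian intensity noise whose
  standard deviation is the "noise scalar" on the [0,1] intensity scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage

from .camera import CameraModel
from .geometry import DoubleCubeModel, build_double_cube

__all__ = [
    "Frame",
    "PolypSpec",
    "PhantomScene",
    "CameraTrajectory",
    "FrameSequence",
    "build_scene",
    "render_sequence",
    "augment_gaussian",
    "look_at",
    "face_sweep_loop",
]

# reddish mucosa tint applied to the gray texture at color export
_TINT = np.array([[0.55, 0.15, 0.12], [0.45, 0.28, 0.25]])  # slope rows: R,G,B


@dataclass
class Frame:
    """One endoscopic image: gray + color + validity mask."""

    index: int
    gray: np.ndarray  # (H, W) float in [0,1]
    color: np.ndarray | None = None  # (H, W, 3) float in [0,1]
    mask: np.ndarray | None = None  # (H, W) bool, True where pixels are real
    pose: tuple[np.ndarray, np.ndarray] | None = None  # (R 3x3, t 3)

    @property
    def shape(self) -> tuple[int, int]:
        return self.gray.shape

    def valid_mask(self) -> np.ndarray:
        if self.mask is None:
            return np.ones(self.gray.shape, dtype=bool)
        return self.mask


@dataclass(frozen=True)
class PolypSpec:
    face_id: str
    center_uv: tuple[float, float]
    radius_mm: float
    amplitude: float = 0.35


@dataclass
class PhantomScene:
    model: DoubleCubeModel
    face_textures: dict[str, np.ndarray]  # face_id -> (tv, tu) float [0,1]
    polyps: list[PolypSpec]
    seed: int
    tex_pitch: float  # texture pixels per mm

    def sample_texture(self, face_id: str, uv: np.ndarray) -> np.ndarray:
        """Bilinear texture lookup at face uv coordinates."""
        tex = self.face_textures[face_id]
        uv = np.atleast_2d(uv)
        rows = uv[:, 1] * (tex.shape[0] - 1)
        cols = uv[:, 0] * (tex.shape[1] - 1)
        return ndimage.map_coordinates(
            tex, np.stack([rows, cols]), order=1, mode="nearest"
        )

    def polyp_panorama_boxes(self) -> list[list[float]]:
        """Ground-truth [x_min, y_min, x_max, y_max] panorama boxes."""
        boxes = []
        for p in self.polyps:
            face = self.model.face(p.face_id)
            c = self.model.surface_to_panorama(p.face_id, [p.center_uv])[0]
            rx = p.radius_mm / face.su * self.model.layout[p.face_id][2]
            ry = p.radius_mm / face.sv * self.model.layout[p.face_id][3]
            boxes.append([c[0] - rx, c[1] - ry, c[0] + rx, c[1] + ry])
        return boxes

    def unfold_truth(self) -> np.ndarray:
        """Paste the face textures into the panorama layout (gutters = 0)."""
        H, W = self.model.pano_shape
        pano = np.zeros((H, W))
        for fid, (x0, y0, w, h) in self.model.layout.items():
            tex = self.face_textures[fid]
            yy, xx = np.mgrid[0:h, 0:w]
            uv = np.stack(
                [(xx.ravel() + 0.0) / max(w - 1, 1), (yy.ravel() + 0.0) / max(h - 1, 1)],
                axis=1,
            )
            pano[y0 : y0 + h, x0 : x0 + w] = self.sample_texture(fid, uv).reshape(h, w)
        return pano


@dataclass
class CameraTrajectory:
    poses: list[tuple[np.ndarray, np.ndarray, int]]  # (R, t, frame index)
    loop_closed: bool = False

    def __post_init__(self) -> None:
        if self.loop_closed and len(self.poses) >= 2:
            R0, t0, _ = self.poses[0]
            R1, t1, _ = self.poses[-1]
            if not (np.allclose(R0, R1) and np.allclose(t0, t1)):
                raise ValueError(
                    "loop_closed trajectory must start and end at the same pose"
                )

    def centers(self) -> np.ndarray:
        return np.stack([-R.T @ t for R, t, _ in self.poses])


@dataclass
class FrameSequence:
    frames: list[Frame]
    poses: list[tuple[np.ndarray, np.ndarray]]
    pair_homographies: list[dict[str, np.ndarray]]  # per consecutive pair
    polyp_boxes: list[list[float]]
    noise_scalar: float
    specular_spots: list[tuple[int, float, float, float, float]]
    loop_closed: bool = False

    def __len__(self) -> int:
        return len(self.frames)

    # -- disk round trip ----------------------------------------------
    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for fr in self.frames:
            img = fr.color if fr.color is not None else fr.gray
            iio.imwrite(
                out / f"frame_{fr.index:05d}.png",
                (np.clip(img, 0, 1) * 255).astype(np.uint8),
            )
        truth = {
            "poses": [
                np.hstack([R, t[:, None]]).ravel().tolist() for R, t in self.poses
            ],
            "pair_homographies": [
                {fid: H.ravel().tolist() for fid, H in d.items()}
                for d in self.pair_homographies
            ],
            "polyp_boxes": self.polyp_boxes,
            "noise_scalar": self.noise_scalar,
            "specular_spots": [list(s) for s in self.specular_spots],
            "loop_closed": self.loop_closed,
        }
        with open(out / "truth.json", "w") as fh:
            json.dump(truth, fh, indent=1)


# ---------------------------------------------------------------------
# scene construction
# ---------------------------------------------------------------------

def _value_noise(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    """Band-limited value noise: smoothed random grids at three octaves."""
    out = np.zeros(shape)
    for cells, amp in ((6, 1.0), (12, 0.55), (24, 0.4), (48, 0.3)):
        grid = rng.standard_normal((cells, cells))
        out += amp * ndimage.zoom(
            grid, (shape[0] / cells, shape[1] / cells), order=3, grid_mode=True,
            mode="nearest",
        )
    out -= out.min()
    out /= max(out.max(), 1e-12)
    return out


def _stamp(tex: np.ndarray, cy: float, cx: float, radius: float, delta: np.ndarray | float, profile) -> None:
    """Add ``delta * profile(dist/radius)`` inside a disc, in place."""
    r = int(np.ceil(radius)) + 1
    y0, y1 = max(0, int(cy) - r), min(tex.shape[0], int(cy) + r + 1)
    x0, x1 = max(0, int(cx) - r), min(tex.shape[1], int(cx) + r + 1)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    d = np.hypot(yy - cy, xx - cx) / radius
    tex[y0:y1, x0:x1] += delta * profile(d)


def _draw_vessels(rng: np.random.Generator, tex: np.ndarray, n: int, width_px: float) -> None:
    h, w = tex.shape
    for _ in range(n):
        p = rng.uniform([0, 0], [h, w], size=(3, 2))
        ts = np.linspace(0, 1, 160)[:, None]
        pts = ((1 - ts) ** 2) * p[0] + 2 * ts * (1 - ts) * p[1] + ts**2 * p[2]
        depth = rng.uniform(0.08, 0.16)
        for cy, cx in pts:
            _stamp(tex, cy, cx, width_px, -depth / 8.0, lambda d: np.exp(-(d**2)))


def _draw_polyp(tex: np.ndarray, cu: float, cv: float, r_px_u: float, r_px_v: float, amp: float) -> None:
    # raised blob: gently brightened dome + bright rim near the boundary
    cy, cx = cv * (tex.shape[0] - 1), cu * (tex.shape[1] - 1)
    r = 0.5 * (r_px_u + r_px_v)
    _stamp(tex, cy, cx, r, amp * 0.5, lambda d: np.clip(1 - d**2, 0, None))
    _stamp(tex, cy, cx, r, amp, lambda d: np.exp(-((d - 0.85) ** 2) / (2 * 0.12**2)) * (d <= 1.1))


def build_scene(
    seed: int,
    polyps: list[PolypSpec] | None = None,
    model: DoubleCubeModel | None = None,
    tex_pitch: float = 2.0,
    n_vessels: int = 6,
) -> PhantomScene:
    """Build a deterministic phantom scene.

    Raises ``ValueError`` naming the offending polyp if a polyp disc is
    not fully inside its face.
    """
    model = model or build_double_cube()
    polyps = list(polyps or [])
    for i, p in enumerate(polyps):
        face = model.face(p.face_id)  # KeyError for unknown ids
        ru, rv = p.radius_mm / face.su, p.radius_mm / face.sv
        cu, cv = p.center_uv
        if p.radius_mm <= 0:
            raise ValueError(f"polyp {i} on face {p.face_id}: radius must be positive")
        if cu - ru < 0 or cu + ru > 1 or cv - rv < 0 or cv + rv > 1:
            raise ValueError(
                f"polyp {i} on face {p.face_id}: disc (center {p.center_uv}, "
                f"radius {p.radius_mm} mm) extends outside the face"
            )
    textures: dict[str, np.ndarray] = {}
    for fi, face in enumerate(model.faces):
        rng = np.random.default_rng([seed, fi])
        shape = (
            max(int(round(face.sv * tex_pitch)), 8),
            max(int(round(face.su * tex_pitch)), 8),
        )
        tex = 0.35 + 0.35 * _value_noise(rng, shape)
        _draw_vessels(rng, tex, n_vessels, width_px=1.2 * tex_pitch)
        for p in polyps:
            if p.face_id == face.face_id:
                _draw_polyp(
                    tex,
                    p.center_uv[0],
                    p.center_uv[1],
                    p.radius_mm / face.su * shape[1],
                    p.radius_mm / face.sv * shape[0],
                    p.amplitude,
                )
        textures[face.face_id] = np.clip(tex, 0.0, 1.0)
    return PhantomScene(model=model, face_textures=textures, polyps=polyps,
                        seed=seed, tex_pitch=tex_pitch)


# ---------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------

def look_at(center: np.ndarray, forward: np.ndarray, up_hint: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pose (R, t) with X_cam = R X_world + t, image x=right, y=down, z=forward."""
    f = np.asarray(forward, dtype=float)
    f = f / np.linalg.norm(f)
    x = np.cross(f, np.asarray(up_hint, dtype=float))
    x = x / np.linalg.norm(x)
    y = np.cross(f, x)
    R = np.stack([x, y, f])
    t = -R @ np.asarray(center, dtype=float)
    return R, t


def face_sweep_loop(
    model: DoubleCubeModel,
    face_id: str = "A-y",
    n_frames: int = 8,
    distance_mm: float = 25.0,
    u_range: tuple[float, float] = (0.35, 0.65),
    v_center: float = 0.5,
) -> CameraTrajectory:
    """Out-and-back fronto-parallel sweep facing one face.

    The camera translates parallel to the face's u axis and returns to
    its start, so consecutive truth homographies are pure image
    translations and the loop composes to the identity exactly.
    """
    if n_frames < 3:
        raise ValueError("need at least 3 frames for a loop")
    face = model.face(face_id)
    n_out = n_frames // 2 + 1
    offs = np.concatenate(
        [
            np.linspace(u_range[0], u_range[1], n_out),
            np.linspace(u_range[1], u_range[0], n_frames - n_out + 1)[1:],
        ]
    )
    poses = []
    for i, off in enumerate(offs):
        surf = face.uv_to_world([[off, v_center]])[0]
        center = surf + face.normal * distance_mm
        R, t = look_at(center, -face.normal, -face.v)
        poses.append((R, t, i))
    return CameraTrajectory(poses=poses, loop_closed=True)


# ---------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------

def _render_frame(scene: PhantomScene, cam: CameraModel, R: np.ndarray, t: np.ndarray) -> np.ndarray:
    C = -R.T @ t
    yy, xx = np.mgrid[0 : cam.height, 0 : cam.width]
    pix = np.stack([xx.ravel().astype(float), yy.ravel().astype(float)], axis=1)
    dirs_cam = cam.unproject(pix)
    dirs_world = dirs_cam @ R  # R.T @ d for each row
    face_idx, uv, _ = scene.model.cast_rays(C, dirs_world)
    gray = np.zeros(face_idx.shape)
    for i, face in enumerate(scene.model.faces):
        sel = face_idx == i
        if np.any(sel):
            gray[sel] = scene.sample_texture(face.face_id, uv[sel])
    return gray.reshape(cam.height, cam.width)


def _colorize(gray: np.ndarray) -> np.ndarray:
    return np.clip(_TINT[0][None, None, :] + gray[..., None] * _TINT[1][None, None, :], 0, 1)


def _pair_truth_homography(cam: CameraModel, pose1, pose2, face) -> np.ndarray:
    """Plane-induced pixel homography frame1 -> frame2 for one face."""
    R1, t1 = pose1
    R2, t2 = pose2
    R_rel = R2 @ R1.T
    t_rel = t2 - R_rel @ t1
    n_w, d_w = face.plane
    n_c1 = R1 @ n_w
    d1 = d_w + n_c1 @ t1  # plane in cam1: n_c1 . X = d1 (negative: n faces camera)
    Hn = R_rel + np.outer(t_rel, n_c1) / d1
    K = cam.K
    H = K @ Hn @ np.linalg.inv(K)
    return H / H[2, 2]


def _visible_faces(scene: PhantomScene, cam: CameraModel, R: np.ndarray, t: np.ndarray,
                   n_grid: int = 7, min_hits: int = 6) -> dict[str, int]:
    """Face -> number of grid samples visible (unoccluded, in frame)."""
    C = -R.T @ t
    out: dict[str, int] = {}
    g = np.linspace(0.05, 0.95, n_grid)
    uv = np.stack(np.meshgrid(g, g), axis=-1).reshape(-1, 2)
    for i, face in enumerate(scene.model.faces):
        pts = face.uv_to_world(uv)
        cam_pts = pts @ R.T + t
        pix, in_front = cam.project(cam_pts)
        inside = (
            in_front
            & (pix[:, 0] >= 0) & (pix[:, 0] <= cam.width - 1)
            & (pix[:, 1] >= 0) & (pix[:, 1] <= cam.height - 1)
        )
        if not np.any(inside):
            continue
        dirs = pts[inside] - C
        hit_face, _, hit_t = scene.model.cast_rays(C, dirs)
        # t is in units of |dirs|, so an unoccluded hit at the point itself has t == 1
        unoccluded = (hit_face == i) & (np.abs(hit_t - 1.0) < 1e-6)
        n_vis = int(np.count_nonzero(unoccluded))
        if n_vis >= min_hits:
            out[face.face_id] = n_vis
    return out


def render_sequence(
    scene: PhantomScene,
    traj: CameraTrajectory,
    cam: CameraModel,
    noise_scalar: float = 0.0,
    specular_count: int = 0,
    rng_seed: int | None = None,
) -> FrameSequence:
    """Render the trajectory and record exact pre-degradation ground truth.

    Truth homographies (per consecutive pair, per face visible in both
    frames) are computed analytically from the poses; Gaussian noise
    (std = ``noise_scalar`` on [0,1]) and specular highlights are applied
    afterwards, so the truth always refers to the clean geometry.
    """
    if not traj.poses:
        raise ValueError("trajectory is empty")
    if noise_scalar < 0:
        raise ValueError("noise_scalar must be non-negative")
    centers = traj.centers()
    inside = scene.model.contains(centers)
    if not np.all(inside):
        bad = int(np.flatnonzero(~inside)[0])
        raise ValueError(f"camera pose {bad} lies outside the cavity")
    rng = np.random.default_rng(scene.seed if rng_seed is None else rng_seed)

    frames: list[Frame] = []
    poses: list[tuple[np.ndarray, np.ndarray]] = []
    vis: list[dict[str, int]] = []
    for R, t, idx in traj.poses:
        gray = _render_frame(scene, cam, R, t)
        frames.append(Frame(index=idx, gray=gray, color=_colorize(gray), pose=(R, t)))
        poses.append((R, t))
        vis.append(_visible_faces(scene, cam, R, t))

    pair_h: list[dict[str, np.ndarray]] = []
    for i in range(1, len(frames)):
        d: dict[str, np.ndarray] = {}
        common = set(vis[i - 1]) & set(vis[i])
        for fid in sorted(common):
            d[fid] = _pair_truth_homography(
                cam, poses[i - 1], poses[i], scene.model.face(fid)
            )
        pair_h.append(d)

    # degradations, applied after truth is recorded
    spots: list[tuple[int, float, float, float, float]] = []
    for i, fr in enumerate(frames):
        for _ in range(specular_count):
            cx = rng.uniform(0.1, 0.9) * cam.width
            cy = rng.uniform(0.1, 0.9) * cam.height
            radius = rng.uniform(0.015, 0.04) * cam.width
            gain = rng.uniform(0.5, 1.0)
            spots.append((i, cx, cy, radius, gain))
            yy, xx = np.mgrid[0 : cam.height, 0 : cam.width]
            blob = gain * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * radius**2))
            fr.gray = np.clip(fr.gray + blob, 0, 1)
            if fr.color is not None:
                fr.color = np.clip(fr.color + blob[..., None], 0, 1)
        if noise_scalar > 0:
            fr.gray = np.clip(
                fr.gray + rng.normal(0, noise_scalar, fr.gray.shape), 0, 1
            )
            if fr.color is not None:
                fr.color = np.clip(
                    fr.color + rng.normal(0, noise_scalar, fr.color.shape), 0, 1
                )

    return FrameSequence(
        frames=frames,
        poses=poses,
        pair_homographies=pair_h,
        polyp_boxes=scene.polyp_panorama_boxes(),
        noise_scalar=noise_scalar,
        specular_spots=spots,
        loop_closed=traj.loop_closed,
    )


def random_polyp_scene(
    seed: int,
    model: DoubleCubeModel | None = None,
    tex_pitch: float = 1.0,
    n_polyps: tuple[int, int] = (2, 5),
    radius_mm: tuple[float, float] = (4.0, 6.5),
    amplitude: tuple[float, float] = (0.25, 0.4),
    n_vessels: int = 6,
) -> PhantomScene:
    """Scene with polyps placed uniformly at random on random faces."""
    model = model or build_double_cube()
    rng = np.random.default_rng(seed)
    polyps = []
    for _ in range(int(rng.integers(*n_polyps))):
        fid = model.face_ids[int(rng.integers(0, len(model.faces)))]
        f = model.face(fid)
        r = float(rng.uniform(*radius_mm))
        ru, rv = r / f.su, r / f.sv
        cu = float(rng.uniform(ru + 0.02, 1 - ru - 0.02))
        cv = float(rng.uniform(rv + 0.02, 1 - rv - 0.02))
        polyps.append(
            PolypSpec(fid, (cu, cv), r, amplitude=float(rng.uniform(*amplitude)))
        )
    return build_scene(
        seed=seed, polyps=polyps, model=model, tex_pitch=tex_pitch,
        n_vessels=n_vessels,
    )


def truth_panorama_transforms(seq: FrameSequence, face_id: str):
    """Exact per-frame panorama transforms for a single-face sweep.

    Valid when every pairwise truth homography for ``face_id`` is a
    similarity (fronto-parallel motion); composes their inverses so
    frame 0 is the reference.
    """
    from .transforms import Similarity4

    out = [Similarity4.identity()]
    for d in seq.pair_homographies:
        H = d[face_id]
        if not (
            np.allclose(H[2, :2], 0, atol=1e-9)
            and np.isclose(H[0, 0], H[1, 1], atol=1e-9)
            and np.isclose(H[0, 1], -H[1, 0], atol=1e-9)
        ):
            raise ValueError(f"truth homography for {face_id} is not a similarity")
        edge = Similarity4(H[0, 0], H[1, 0], H[0, 2], H[1, 2])
        out.append(out[-1].compose(edge.inverse()))
    return out


# ---------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------

def augment_gaussian(image: np.ndarray | Frame, scales: list[float]) -> list[np.ndarray]:
    """Gaussian-smoothed copies of an image, one per scale (std in px)."""
    img = image.gray if isinstance(image, Frame) else np.asarray(image, dtype=float)
    out = []
    for s in scales:
        if s <= 0:
            raise ValueError(f"Gaussian scale must be positive, got {s}")
        out.append(ndimage.gaussian_filter(img, sigma=s, mode="nearest"))
    return out
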