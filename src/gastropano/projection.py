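"""Texture projection onto the double-cube model and panorama unfolding.

The stomach-approximating double cube gives every interior point a
(face, uv) chart coordinate; unfolding pastes each face into its fixed
slot of a two-row layout.  ``project_texture`` works by reverse mapping:
every panorama pixel is lifted to its surface point, that point is
projected into each frame that sees it (with a visibility check against
the cavity geometry), and the samples are combined by a weighted mean —
the same estimator the fusion stage uses for its canvas.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage

from .camera import CameraModel
from .geometry import DoubleCubeModel
from .phantom import Frame

__all__ = [
    "PanoramaImage",
    "surface_to_panorama",
    "panorama_to_surface",
    "project_texture",
]


@dataclass
class PanoramaImage:
    pixels: np.ndarray  # (H, W) gray in [0,1]
    face_ids: np.ndarray  # (H, W) int index into model.faces, -1 invalid
    weight: np.ndarray  # (H, W) accumulated sample weight (0 = uncovered)
    model: DoubleCubeModel

    @property
    def valid(self) -> np.ndarray:
        return (self.face_ids >= 0) & (self.weight > 0)

    @property
    def coverage(self) -> float:
        """Covered fraction of the unfolded surface area."""
        on_surface = self.face_ids >= 0
        return float(self.valid.sum() / max(on_surface.sum(), 1))

    def inverse_map(self, px) -> list[tuple[str, np.ndarray] | None]:
        return self.model.panorama_to_surface(px)

    def save(self, path_png, path_json=None) -> None:
        iio.imwrite(
            path_png, (np.clip(self.pixels, 0, 1) * 255).astype(np.uint8)
        )
        if path_json is not None:
            meta = {
                "layout": self.model.layout_table(),
                "coverage": self.coverage,
            }
            Path(path_json).write_text(json.dumps(meta, indent=1))


def surface_to_panorama(model: DoubleCubeModel, face_id: str, uv) -> np.ndarray:
    """Face uv in [0,1]^2 -> panorama pixel (x, y)."""
    return model.surface_to_panorama(face_id, uv)


def panorama_to_surface(model: DoubleCubeModel, px):
    """Panorama pixel -> (face id, uv), or None in the gutters."""
    return model.panorama_to_surface(px)


def project_texture(
    frames: list[Frame],
    poses: list[tuple[np.ndarray, np.ndarray]],
    cam: CameraModel,
    model: DoubleCubeModel,
    zbuffer: bool = True,
    cosine_weight: bool = False,
) -> PanoramaImage:
    """Project frame textures onto the cavity and unfold the panorama.

    Each panorama pixel's value is the weighted mean of all frame
    samples whose ray reaches the corresponding surface point; with
    ``zbuffer`` enabled a sample only contributes when the surface point
    is the first cavity intersection along the viewing ray (no
    see-through walls).  Raises if no frame covers any surface point.
    """
    if len(frames) != len(poses):
        raise ValueError("need one pose per frame")
    H, W = model.pano_shape
    face_map = model.face_id_map()
    csum = np.zeros((H, W))
    wsum = np.zeros((H, W))

    for i, face in enumerate(model.faces):
        x0, y0, w, h = model.layout[face.face_id]
        yy, xx = np.mgrid[0:h, 0:w]
        uv = np.stack(
            [xx.ravel() / max(w - 1, 1), yy.ravel() / max(h - 1, 1)], axis=1
        )
        world = face.uv_to_world(uv)
        acc_c = np.zeros(len(world))
        acc_w = np.zeros(len(world))
        for fr, (R, t) in zip(frames, poses):
            C = -R.T @ t
            cam_pts = world @ R.T + t
            pix, in_front = cam.project(cam_pts)
            inside = (
                in_front
                & (pix[:, 0] >= 0) & (pix[:, 0] <= cam.width - 1)
                & (pix[:, 1] >= 0) & (pix[:, 1] <= cam.height - 1)
            )
            if not np.any(inside):
                continue
            idx = np.flatnonzero(inside)
            if zbuffer:
                dirs = world[idx] - C
                hit_face, _, hit_t = model.cast_rays(C, dirs)
                visible = (hit_face == i) & (np.abs(hit_t - 1.0) < 1e-6)
                idx = idx[visible]
                if len(idx) == 0:
                    continue
            vals = ndimage.map_coordinates(
                fr.gray, np.stack([pix[idx, 1], pix[idx, 0]]), order=1
            )
            mask = fr.valid_mask()
            mvals = ndimage.map_coordinates(
                mask.astype(float),
                np.stack([pix[idx, 1], pix[idx, 0]]),
                order=1,
            )
            ok = mvals > 0.999
            idx, vals = idx[ok], vals[ok]
            if len(idx) == 0:
                continue
            wgt = np.ones(len(idx))
            if cosine_weight:
                rays = world[idx] - C
                rays = rays / np.linalg.norm(rays, axis=1, keepdims=True)
                wgt = np.abs(rays @ face.normal)
            acc_c[idx] += wgt * vals
            acc_w[idx] += wgt
        csum[y0 : y0 + h, x0 : x0 + w] = (acc_c / np.maximum(acc_w, 1e-12)).reshape(h, w)
        wsum[y0 : y0 + h, x0 : x0 + w] = acc_w.reshape(h, w)

    if not np.any(wsum > 0):
        raise ValueError("no frame covers any surface point")
    pixels = np.where(wsum > 0, csum, 0.0)
    return PanoramaImage(pixels=pixels, face_ids=face_map, weight=wsum, model=model)
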