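"""Pinhole / equidistant-fisheye camera model.

Endoscopes use wide-angle optics that bend straight lines heavily; the
equidistant model (image radius proportional to a polynomial in the view
angle) is the standard parametrization for such lenses.  Distortion:

    theta   = atan(r),  r = |(X/Z, Y/Z)|
    theta_d = theta * (1 + k1 th^2 + k2 th^4 + k3 th^6 + k4 th^8)
    (xd,yd) = (theta_d / r) * (X/Z, Y/Z)
    pixel   = (fx*xd + cx, fy*yd + cy)

All coefficients zero reduces to... not quite a pinhole (theta != tan
theta); ``distortion="none"`` selects the true pinhole projection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = ["CameraModel"]


@dataclass
class CameraModel:
    fx: float
    fy: float
    cx: float
    cy: float
    width: int
    height: int
    k: np.ndarray = field(default_factory=lambda: np.zeros(4))
    distortion: str = "fisheye"  # "fisheye" or "none"

    def __post_init__(self) -> None:
        self.k = np.asarray(self.k, dtype=float).reshape(4)
        if self.fx <= 0 or self.fy <= 0:
            raise ValueError("focal lengths must be positive")
        if not (0 <= self.cx < self.width and 0 <= self.cy < self.height):
            raise ValueError("principal point must lie inside the image")

    # ------------------------------------------------------------------
    @property
    def K(self) -> np.ndarray:
        return np.array(
            [[self.fx, 0, self.cx], [0, self.fy, self.cy], [0, 0, 1.0]]
        )

    @property
    def is_pinhole(self) -> bool:
        return self.distortion == "none" or not np.any(self.k)

    # -- distortion on normalized coordinates --------------------------
    def _theta_d(self, theta: np.ndarray) -> np.ndarray:
        t2 = theta * theta
        k1, k2, k3, k4 = self.k
        return theta * (1 + t2 * (k1 + t2 * (k2 + t2 * (k3 + t2 * k4))))

    def _theta_from_theta_d(self, theta_d: np.ndarray) -> np.ndarray:
        # Newton iterations; theta_d is monotone in theta for sane k
        theta = theta_d.copy()
        k1, k2, k3, k4 = self.k
        for _ in range(12):
            t2 = theta * theta
            f = theta * (1 + t2 * (k1 + t2 * (k2 + t2 * (k3 + t2 * k4)))) - theta_d
            df = 1 + t2 * (3 * k1 + t2 * (5 * k2 + t2 * (7 * k3 + 9 * t2 * k4)))
            theta = theta - f / np.maximum(df, 1e-9)
        return theta

    # -- projection ----------------------------------------------------
    def project(self, pts_cam: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Camera-frame 3D points -> pixel coordinates.

        Returns ``(pix, in_front)``; points with Z <= 0 are flagged.
        """
        p = np.atleast_2d(np.asarray(pts_cam, dtype=float))
        z = p[:, 2]
        in_front = z > 1e-9
        with np.errstate(divide="ignore", invalid="ignore"):
            xn = p[:, 0] / z
            yn = p[:, 1] / z
        if self.distortion == "none":
            xd, yd = xn, yn
        else:
            r = np.hypot(xn, yn)
            theta = np.arctan(r)
            theta_d = self._theta_d(theta)
            scale = np.where(r > 1e-12, theta_d / np.maximum(r, 1e-12), 1.0)
            xd = xn * scale
            yd = yn * scale
        pix = np.stack([self.fx * xd + self.cx, self.fy * yd + self.cy], axis=1)
        pix[~in_front] = np.nan
        return pix, in_front

    def unproject(self, pix: np.ndarray) -> np.ndarray:
        """Pixel coordinates -> unit-Z camera-frame ray directions."""
        p = np.atleast_2d(np.asarray(pix, dtype=float))
        xd = (p[:, 0] - self.cx) / self.fx
        yd = (p[:, 1] - self.cy) / self.fy
        if self.distortion == "none":
            xn, yn = xd, yd
        else:
            theta_d = np.hypot(xd, yd)
            theta = self._theta_from_theta_d(theta_d)
            r = np.tan(theta)
            scale = np.where(theta_d > 1e-12, r / np.maximum(theta_d, 1e-12), 1.0)
            xn = xd * scale
            yn = yd * scale
        return np.stack([xn, yn, np.ones_like(xn)], axis=1)

    def distort_points(self, pix_pinhole: np.ndarray) -> np.ndarray:
        """Map ideal-pinhole pixels to fisheye pixels (same intrinsics)."""
        p = np.atleast_2d(np.asarray(pix_pinhole, dtype=float))
        if self.distortion == "none":
            return p.copy()
        xn = (p[:, 0] - self.cx) / self.fx
        yn = (p[:, 1] - self.cy) / self.fy
        r = np.hypot(xn, yn)
        theta = np.arctan(r)
        theta_d = self._theta_d(theta)
        scale = np.where(r > 1e-12, theta_d / np.maximum(r, 1e-12), 1.0)
        return np.stack(
            [self.fx * xn * scale + self.cx, self.fy * yn * scale + self.cy],
            axis=1,
        )

    def undistort_points(self, pix_fisheye: np.ndarray) -> np.ndarray:
        """Inverse of :meth:`distort_points`."""
        d = self.unproject(np.atleast_2d(pix_fisheye))
        return np.stack(
            [self.fx * d[:, 0] + self.cx, self.fy * d[:, 1] + self.cy], axis=1
        )

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "fx": self.fx,
            "fy": self.fy,
            "cx": self.cx,
            "cy": self.cy,
            "width": self.width,
            "height": self.height,
            "k": [float(v) for v in self.k],
            "distortion": self.distortion,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CameraModel":
        return cls(
            fx=d["fx"], fy=d["fy"], cx=d["cx"], cy=d["cy"],
            width=d["width"], height=d["height"],
            k=np.asarray(d.get("k", [0, 0, 0, 0]), dtype=float),
            distortion=d.get("distortion", "fisheye"),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    @classmethod
    def from_yaml(cls, path) -> "CameraModel":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
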