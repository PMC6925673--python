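"""Planar 4-DOF similarity transforms shared by the chain and fusion stages.

A transform is the vector ``(r1, r2, t1, t2)`` acting on image points as

    [x']   [r1 -r2] [x]   [t1]
    [y'] = [r2  r1] [y] + [t2]

i.e. rotation+scale encoded by the complex number ``a = r1 + i r2`` and a
pixel translation.  Keeping the chain and the seam optimizer in this one
parameter family makes warped coordinates linear in the parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Similarity4"]


@dataclass
class Similarity4:
    r1: float = 1.0
    r2: float = 0.0
    t1: float = 0.0
    t2: float = 0.0

    # ------------------------------------------------------------------
    @classmethod
    def identity(cls) -> "Similarity4":
        return cls()

    @classmethod
    def from_params(cls, p) -> "Similarity4":
        r1, r2, t1, t2 = (float(v) for v in p)
        return cls(r1, r2, t1, t2)

    @classmethod
    def from_components(cls, angle_rad: float, log_scale: float, t) -> "Similarity4":
        s = float(np.exp(log_scale))
        return cls(
            s * float(np.cos(angle_rad)),
            s * float(np.sin(angle_rad)),
            float(t[0]),
            float(t[1]),
        )

    @property
    def params(self) -> np.ndarray:
        return np.array([self.r1, self.r2, self.t1, self.t2])

    @property
    def linear(self) -> np.ndarray:
        return np.array([[self.r1, -self.r2], [self.r2, self.r1]])

    @property
    def translation(self) -> np.ndarray:
        return np.array([self.t1, self.t2])

    @property
    def scale(self) -> float:
        return float(np.hypot(self.r1, self.r2))

    @property
    def angle_rad(self) -> float:
        return float(np.arctan2(self.r2, self.r1))

    @property
    def log_scale(self) -> float:
        return float(np.log(max(self.scale, 1e-300)))

    def as_matrix(self) -> np.ndarray:
        M = np.eye(3)
        M[:2, :2] = self.linear
        M[:2, 2] = self.translation
        return M

    # ------------------------------------------------------------------
    def apply(self, pts: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(pts, dtype=float))
        return p @ self.linear.T + self.translation[None, :]

    def compose(self, other: "Similarity4") -> "Similarity4":
        """``self.compose(other)``: apply ``other`` first, then ``self``."""
        a = complex(self.r1, self.r2) * complex(other.r1, other.r2)
        t = self.apply(other.translation[None, :])[0]
        return Similarity4(a.real, a.imag, t[0], t[1])

    def inverse(self) -> "Similarity4":
        a = complex(self.r1, self.r2)
        if abs(a) < 1e-300:
            raise ValueError("non-invertible similarity (zero linear part)")
        ai = 1.0 / a
        ti = -(np.array([[ai.real, -ai.imag], [ai.imag, ai.real]]) @ self.translation)
        return Similarity4(ai.real, ai.imag, ti[0], ti[1])

    # ------------------------------------------------------------------
    @classmethod
    def fit(cls, src: np.ndarray, dst: np.ndarray, weights=None) -> "Similarity4":
        """Least-squares similarity with ``dst ~ T(src)`` (>= 2 points)."""
        src = np.atleast_2d(np.asarray(src, dtype=float))
        dst = np.atleast_2d(np.asarray(dst, dtype=float))
        if len(src) < 2:
            raise ValueError("need at least 2 point pairs")
        w = np.ones(len(src)) if weights is None else np.asarray(weights, float)
        w = w / w.sum()
        cs = (w[:, None] * src).sum(axis=0)
        cd = (w[:, None] * dst).sum(axis=0)
        zs = (src[:, 0] - cs[0]) + 1j * (src[:, 1] - cs[1])
        zd = (dst[:, 0] - cd[0]) + 1j * (dst[:, 1] - cd[1])
        denom = (w * np.abs(zs) ** 2).sum()
        a = (w * np.conj(zs) * zd).sum() / max(denom, 1e-300)
        lin = np.array([[a.real, -a.imag], [a.imag, a.real]])
        t = cd - lin @ cs
        return cls(a.real, a.imag, t[0], t[1])

    def transfer_errors(self, src: np.ndarray, dst: np.ndarray) -> np.ndarray:
        return np.linalg.norm(self.apply(src) - np.atleast_2d(dst), axis=1)
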