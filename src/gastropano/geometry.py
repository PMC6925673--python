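"""Double-cube cavity geometry and its canonical panorama unfolding.

The gastric cavity is approximated by two axis-aligned cubes of edge
``edge_mm`` joined through a rectangular opening: cube A occupies
``[0,L]^3`` and cube B occupies ``[L,2L] x [L/2,3L/2] x [0,L]``.  The
half-edge offset along y leaves two wall strips on the junction plane
``x = L``, so the interior surface decomposes into 12 exposed planar
rectangles ("faces").  Each face carries a local uv chart in ``[0,1]^2``
and a fixed slot in a two-row unfold layout, which makes the surface ->
panorama mapping injective and exactly invertible up to pixel rounding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Face", "DoubleCubeModel", "build_double_cube"]


@dataclass(frozen=True)
class Face:
    """One planar interior rectangle of the cavity.

    ``origin + su * u * s + sv * v * t`` for ``(s, t)`` in ``[0,1]^2``
    spans the rectangle; ``normal`` points into the cavity volume the
    face bounds.
    """

    face_id: str
    origin: np.ndarray  # (3,) mm
    u: np.ndarray  # (3,) unit vector along the first uv axis
    v: np.ndarray  # (3,) unit vector along the second uv axis
    su: float  # extent along u, mm
    sv: float  # extent along v, mm
    normal: np.ndarray  # (3,) inward unit normal

    def uv_to_world(self, uv: np.ndarray) -> np.ndarray:
        uv = np.atleast_2d(np.asarray(uv, dtype=float))
        return (
            self.origin[None, :]
            + uv[:, :1] * self.su * self.u[None, :]
            + uv[:, 1:2] * self.sv * self.v[None, :]
        )

    def world_to_uv(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float)) - self.origin[None, :]
        return np.stack(
            [pts @ self.u / self.su, pts @ self.v / self.sv], axis=1
        )

    @property
    def plane(self) -> tuple[np.ndarray, float]:
        """Inward-normal plane ``n . X = d`` containing the face."""
        return self.normal, float(self.normal @ self.origin)


def _f(face_id, origin, u, v, su, sv, normal):
    return Face(
        face_id,
        np.asarray(origin, dtype=float),
        np.asarray(u, dtype=float),
        np.asarray(v, dtype=float),
        float(su),
        float(sv),
        np.asarray(normal, dtype=float),
    )


def _cavity_faces(L: float) -> list[Face]:
    h = L / 2.0
    return [
        # cube A, interior [0,L]^3; inward normals point into A
        _f("A-x", (0, 0, 0), (0, 1, 0), (0, 0, 1), L, L, (1, 0, 0)),
        _f("A+y", (0, L, 0), (1, 0, 0), (0, 0, 1), L, L, (0, -1, 0)),
        _f("A-y", (0, 0, 0), (1, 0, 0), (0, 0, 1), L, L, (0, 1, 0)),
        _f("A+z", (0, 0, L), (1, 0, 0), (0, 1, 0), L, L, (0, 0, -1)),
        _f("A-z", (0, 0, 0), (1, 0, 0), (0, 1, 0), L, L, (0, 0, 1)),
        # junction wall strip on the A side (opening is y in [L/2, L])
        _f("A+x", (L, 0, 0), (0, 1, 0), (0, 0, 1), h, L, (-1, 0, 0)),
        # cube B, interior [L,2L] x [L/2,3L/2] x [0,L]
        _f("B+x", (2 * L, h, 0), (0, 1, 0), (0, 0, 1), L, L, (-1, 0, 0)),
        _f("B+y", (L, 3 * h, 0), (1, 0, 0), (0, 0, 1), L, L, (0, -1, 0)),
        _f("B-y", (L, h, 0), (1, 0, 0), (0, 0, 1), L, L, (0, 1, 0)),
        _f("B+z", (L, h, L), (1, 0, 0), (0, 1, 0), L, L, (0, 0, -1)),
        _f("B-z", (L, h, 0), (1, 0, 0), (0, 1, 0), L, L, (0, 0, 1)),
        # junction wall strip on the B side
        _f("B-x", (L, L, 0), (0, 1, 0), (0, 0, 1), h, L, (1, 0, 0)),
    ]


@dataclass
class DoubleCubeModel:
    """Double-cube cavity plus its fixed 2-row unfold layout.

    Parameters
    ----------
    edge_mm : cube edge length in millimetres.
    pitch : panorama pixels per millimetre of face surface.
    gutter_px : blank pixels separating face slots in the panorama.
    """

    edge_mm: float = 60.0
    pitch: float = 2.0
    gutter_px: int = 2
    faces: list[Face] = field(init=False)
    layout: dict[str, tuple[int, int, int, int]] = field(init=False)
    pano_shape: tuple[int, int] = field(init=False)

    def __post_init__(self) -> None:
        if self.edge_mm <= 0 or self.pitch <= 0:
            raise ValueError("edge_mm and pitch must be positive")
        self.faces = _cavity_faces(self.edge_mm)
        self._by_id = {f.face_id: f for f in self.faces}
        self._build_layout()

    # -- unfold layout -------------------------------------------------
    def _build_layout(self) -> None:
        g = self.gutter_px
        rows = [
            [f for f in self.faces if f.face_id.startswith("A")],
            [f for f in self.faces if f.face_id.startswith("B")],
        ]
        layout: dict[str, tuple[int, int, int, int]] = {}
        y = g
        total_w = 0
        for row in rows:
            x = g
            row_h = 0
            for f in row:
                w = int(round(f.su * self.pitch))
                h = int(round(f.sv * self.pitch))
                layout[f.face_id] = (x, y, w, h)
                x += w + g
                row_h = max(row_h, h)
            total_w = max(total_w, x)
            y += row_h + g
        self.layout = layout
        self.pano_shape = (y, total_w)  # (H, W)

    def face(self, face_id: str) -> Face:
        try:
            return self._by_id[face_id]
        except KeyError:
            raise KeyError(f"unknown face id: {face_id!r}") from None

    @property
    def face_ids(self) -> list[str]:
        return [f.face_id for f in self.faces]

    # -- surface <-> panorama ------------------------------------------
    def surface_to_panorama(self, face_id: str, uv) -> np.ndarray:
        """Map face uv in ``[0,1]^2`` to panorama pixel coordinates (x, y).

        Pixel centres sit at integer coordinates; uv = (0,0) maps to the
        centre of the slot's top-left pixel.
        """
        x0, y0, w, h = self.layout[self.face(face_id).face_id]
        uv = np.atleast_2d(np.asarray(uv, dtype=float))
        if np.any(uv < -1e-9) or np.any(uv > 1 + 1e-9):
            raise ValueError("uv coordinates must lie in [0,1]^2")
        px = x0 - 0.5 + uv[:, 0] * w
        py = y0 - 0.5 + uv[:, 1] * h
        return np.stack([px, py], axis=1)

    def panorama_to_surface(self, px) -> list[tuple[str, np.ndarray] | None]:
        """Invert :meth:`surface_to_panorama`; gutter pixels map to None."""
        px = np.atleast_2d(np.asarray(px, dtype=float))
        out: list[tuple[str, np.ndarray] | None] = []
        for x, y in px:
            hit = None
            for fid, (x0, y0, w, h) in self.layout.items():
                u = (x - x0 + 0.5) / w
                v = (y - y0 + 0.5) / h
                if 0 <= u <= 1 and 0 <= v <= 1:
                    hit = (fid, np.array([u, v]))
                    break
            out.append(hit)
        return out

    def face_id_map(self) -> np.ndarray:
        """Per-panorama-pixel face index (-1 in gutters), shape (H, W)."""
        H, W = self.pano_shape
        m = np.full((H, W), -1, dtype=np.int32)
        for i, f in enumerate(self.faces):
            x0, y0, w, h = self.layout[f.face_id]
            m[y0 : y0 + h, x0 : x0 + w] = i
        return m

    # -- geometry queries ----------------------------------------------
    def contains(self, pts: np.ndarray) -> np.ndarray:
        """True where points lie strictly inside the cavity volume."""
        p = np.atleast_2d(np.asarray(pts, dtype=float))
        L = self.edge_mm
        h = L / 2.0
        in_a = np.all((p > 0) & (p < L), axis=1)
        in_b = (
            (p[:, 0] > L)
            & (p[:, 0] < 2 * L)
            & (p[:, 1] > h)
            & (p[:, 1] < 3 * h)
            & (p[:, 2] > 0)
            & (p[:, 2] < L)
        )
        on_window = (
            np.isclose(p[:, 0], L)
            & (p[:, 1] > h)
            & (p[:, 1] < L)
            & (p[:, 2] > 0)
            & (p[:, 2] < L)
        )
        return in_a | in_b | on_window

    def cast_rays(
        self, origin: np.ndarray, dirs: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Nearest face hit for rays from ``origin`` (inside the cavity).

        Returns ``(face_index, uv, t)`` arrays; ``face_index`` is -1 where
        a ray escapes (numerically through a face edge).
        """
        origin = np.asarray(origin, dtype=float)
        d = np.atleast_2d(np.asarray(dirs, dtype=float))
        n_rays = d.shape[0]
        best_t = np.full(n_rays, np.inf)
        best_face = np.full(n_rays, -1, dtype=np.int32)
        best_uv = np.zeros((n_rays, 2))
        eps = 1e-9
        for i, f in enumerate(self.faces):
            n, dd = f.plane
            denom = d @ n
            with np.errstate(divide="ignore", invalid="ignore"):
                t = (dd - origin @ n) / denom
                valid = np.abs(denom) > eps
                t = np.where(valid, t, np.inf)
                pts = origin[None, :] + np.where(np.isfinite(t), t, 0.0)[:, None] * d
                rel = pts - f.origin[None, :]
                uu = rel @ f.u / f.su
                vv = rel @ f.v / f.sv
            ok = (
                (t > eps)
                & (t < best_t)
                & (uu >= -1e-9)
                & (uu <= 1 + 1e-9)
                & (vv >= -1e-9)
                & (vv <= 1 + 1e-9)
            )
            best_t[ok] = t[ok]
            best_face[ok] = i
            best_uv[ok, 0] = np.clip(uu[ok], 0.0, 1.0)
            best_uv[ok, 1] = np.clip(vv[ok], 0.0, 1.0)
        return best_face, best_uv, best_t

    def layout_table(self) -> dict:
        """JSON-serializable description of the unfold layout."""
        return {
            "edge_mm": self.edge_mm,
            "pitch": self.pitch,
            "gutter_px": self.gutter_px,
            "pano_shape": list(self.pano_shape),
            "slots": {fid: list(slot) for fid, slot in self.layout.items()},
        }


def build_double_cube(
    edge_mm: float = 60.0, pitch: float = 2.0, gutter_px: int = 2
) -> DoubleCubeModel:
    return DoubleCubeModel(edge_mm=edge_mm, pitch=pitch, gutter_px=gutter_px)
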