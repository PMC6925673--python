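"""Closed-chain registration and loop-consistency mismatch filtering.

An in-and-out endoscope pass visits the same wall twice, so the
pairwise registrations form a cycle whose composition must be the
identity.  The deviation from identity (the loop residual) is a
hardware-free consistency signal: it is distributed evenly over the
edges, correspondences that disagree with the corrected edges are
rejected, edges are re-estimated from the survivors, and the process
repeats while the residual keeps shrinking.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import registration as reg
from .phantom import Frame, FrameSequence
from .transforms import Similarity4

__all__ = [
    "ChainTransform",
    "ChainGraph",
    "ChainConfig",
    "build_chain",
    "closed_chain_filter",
    "default_registrar",
]


@dataclass
class ChainConfig:
    reproj_px: float = 2.0
    max_rounds: int = 10
    tol_px: float = 1e-3
    model: str = "similarity"  # or "homography"


@dataclass
class ChainTransform:
    source: int
    target: int
    transform: Similarity4
    src_pts: np.ndarray  # (N,2) points in source frame
    dst_pts: np.ndarray  # (N,2) matched points in target frame
    active: np.ndarray  # (N,) bool, False once rejected

    @property
    def n_active(self) -> int:
        return int(self.active.sum())

    def refit(self) -> None:
        self.transform = Similarity4.fit(
            self.src_pts[self.active], self.dst_pts[self.active]
        )


@dataclass
class ChainGraph:
    edges: list[ChainTransform]
    frame_shape: tuple[int, int]
    residual_log: list[dict] = field(default_factory=list)

    def loop_transform(self) -> Similarity4:
        """Composition of all edges around the loop."""
        L = Similarity4.identity()
        for e in self.edges:
            L = e.transform.compose(L)
        return L

    def loop_residual(self) -> dict:
        """Deviation of the loop composition from identity."""
        L = self.loop_transform()
        h, w = self.frame_shape
        corners = np.array([[0, 0], [w - 1, 0], [0, h - 1], [w - 1, h - 1]], float)
        px = float(np.linalg.norm(L.apply(corners) - corners, axis=1).mean())
        return {
            "rotation_deg": float(np.degrees(L.angle_rad)),
            "translation_px": float(np.linalg.norm(L.translation)),
            "log_scale": L.log_scale,
            "corner_px": px,
        }

    def panorama_transforms(self) -> list[Similarity4]:
        """Per-frame transforms into the first frame's coordinates."""
        out = [Similarity4.identity()]
        for e in self.edges:
            out.append(out[-1].compose(e.transform.inverse()))
        return out

    def to_json(self, path) -> None:
        data = {
            "edges": [
                {
                    "source": e.source,
                    "target": e.target,
                    "params": e.transform.params.tolist(),
                    "n_correspondences": len(e.src_pts),
                    "n_active": e.n_active,
                }
                for e in self.edges
            ],
            "residual_log": self.residual_log,
            "loop_residual": self.loop_residual(),
        }
        with open(path, "w") as fh:
            json.dump(data, fh, indent=1)


def default_registrar(config: reg.RegistrationConfig | None = None):
    """HPFT registrar: detect/match then verify; returns verified pairs."""
    cfg = config or reg.RegistrationConfig()

    def run(frame_a: Frame, frame_b: Frame) -> tuple[np.ndarray, np.ndarray]:
        corrs = reg.detect_and_match(frame_a, frame_b, cfg)
        reg.hpft_verify(frame_a, frame_b, corrs, cfg)
        kept = [c for c in corrs if c.verified]
        if len(kept) < 4:
            kept = corrs  # fall back to unverified matches
        return (
            np.stack([c.m for c in kept]),
            np.stack([c.m_prime for c in kept]),
        )

    return run


def build_chain(
    seq: FrameSequence,
    registrar=None,
    config: ChainConfig | None = None,
) -> ChainGraph:
    """Register every consecutive pair of a loop-closed sequence.

    The sequence convention is that the final frame repeats the first
    (the trajectory returns to its start), so the last edge closes the
    chain.  Raises on non-closed sequences, on loops with fewer than 3
    distinct frames, and on unregistrable pairs (naming the pair).
    """
    if not seq.loop_closed:
        raise ValueError("sequence is not loop-closed")
    n = len(seq.frames)
    if n < 4:  # last frame duplicates the first: < 3 distinct poses
        raise ValueError("a meaningful loop needs at least 3 distinct frames")
    registrar = registrar or default_registrar()
    edges = []
    for i in range(1, n):
        fa, fb = seq.frames[i - 1], seq.frames[i]
        try:
            src, dst = registrar(fa, fb)
        except Exception as exc:
            raise RuntimeError(f"cannot register frame pair ({i - 1}, {i}): {exc}") from exc
        if len(src) < 4:
            raise RuntimeError(
                f"cannot register frame pair ({i - 1}, {i}): "
                f"only {len(src)} correspondences"
            )
        T = Similarity4.fit(src, dst)
        edges.append(
            ChainTransform(
                source=i - 1,
                target=i,
                transform=T,
                src_pts=np.asarray(src, float),
                dst_pts=np.asarray(dst, float),
                active=np.ones(len(src), dtype=bool),
            )
        )
    graph = ChainGraph(edges=edges, frame_shape=seq.frames[0].gray.shape)
    graph.residual_log.append({"round": 0, **graph.loop_residual()})
    return graph


def closed_chain_filter(
    graph: ChainGraph,
    config: ChainConfig | None = None,
) -> tuple[ChainGraph, list[tuple[int, np.ndarray, np.ndarray]]]:
    """Distribute the loop residual, reject outliers, re-estimate edges.

    Each round: (1) the loop residual is split into equal per-edge
    shares in angle, log-scale and translation, giving a corrected
    version of every edge; (2) correspondences whose transfer error
    under the corrected edge exceeds ``reproj_px`` are rejected; (3)
    edges are re-fit from survivors.  Rounds that would increase the
    residual are rolled back, so the final residual never exceeds the
    initial one.

    Returns the filtered graph and the rejected correspondences as
    ``(edge index, m, m_prime)`` tuples.
    """
    cfg = config or ChainConfig()
    for e in graph.edges:
        if e.n_active < 4:
            raise RuntimeError(
                f"edge ({e.source}, {e.target}) has {e.n_active} "
                "correspondences (< 4)"
            )
    rejected: list[tuple[int, np.ndarray, np.ndarray]] = []
    m = len(graph.edges)
    prev = graph.loop_residual()["corner_px"]
    graph.residual_log.append({"round": 0, **graph.loop_residual()})
    for rnd in range(1, cfg.max_rounds + 1):
        L = graph.loop_transform()
        # equal per-edge share of the loop error, inverted to correct it
        D = Similarity4.from_components(
            -L.angle_rad / m, -L.log_scale / m, -L.translation / m
        )
        state = [(e.transform, e.active.copy()) for e in graph.edges]
        newly = []
        any_change = False
        for k, e in enumerate(graph.edges):
            corrected = D.compose(e.transform)
            err = corrected.transfer_errors(e.src_pts, e.dst_pts)
            # trim gradually: at most the worst ~20% per round, so a fit
            # skewed by outliers is not allowed to reject its own inliers
            thr = max(cfg.reproj_px, float(np.quantile(err[e.active], 0.8)))
            drop = e.active & (err > thr)
            if np.any(drop):
                keep = e.active & ~drop
                if keep.sum() < 4:
                    raise RuntimeError(
                        f"edge ({e.source}, {e.target}) left with "
                        f"{int(keep.sum())} correspondences (< 4)"
                    )
                e.active = keep
                e.refit()
                any_change = True
                newly.extend(
                    (k, e.src_pts[i].copy(), e.dst_pts[i].copy())
                    for i in np.flatnonzero(drop)
                )
        res = graph.loop_residual()
        if res["corner_px"] > prev + 1e-12:
            for e, (T, act) in zip(graph.edges, state):
                e.transform, e.active = T, act
            break
        rejected.extend(newly)
        graph.residual_log.append({"round": rnd, **res})
        prev = res["corner_px"]
        if not any_change:
            break
    return graph, rejected
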