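"""Optical-consistency texture fusion.

Stitching residue (registration error, specular mucosa reflections)
shows up as intensity differences where images meet.  Fusion minimizes

    E(c, T) = sum_k sum_x w * (I_k(x) - c(T_k(x)))^2  +  beta * sum_k D_k' D_k

over the panorama pixel estimates ``c`` (gray means) and one 4-DOF
similarity ``T_k = (r1, r2, t1, t2)`` per image, by alternating:

* colors: with T fixed the optimum c is the weighted mean of all source
  intensities splatted to each canvas pixel;
* transforms: with c fixed the warped coordinate is linear in the four
  parameters, so each image is updated by Gauss-Newton on the
  photometric residuals (a 4x4 normal system per step), with
  backtracking so that a step is only accepted if the energy drops.

``D_k`` is the deviation of ``T_k`` from the identity by default (the
literal parameter-vector regularizer, which penalizes the identity pose
itself, is available via ``literal_regularizer``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .phantom import Frame
from .transforms import Similarity4

__all__ = [
    "SeamResiduals",
    "FusionConfig",
    "FusionState",
    "seam_residuals",
    "fusion_energy",
    "energy_terms",
    "optimize_transform",
    "optimize_colors",
    "fuse",
]


@dataclass
class SeamResiduals:
    """Per-overlap-pixel seam differences ``e = I_i(x,y) - I_prev(x',y')``."""

    xy: np.ndarray  # (N,2) coordinates in image i
    xy_prime: np.ndarray  # (N,2) warped coordinates in image i-1
    e: np.ndarray  # (N,) intensity differences on [0,1]
    w: np.ndarray  # (N,) non-negative weights

    def __len__(self) -> int:
        return len(self.e)

    @property
    def rmse(self) -> float:
        return float(np.sqrt(np.mean(self.e**2)))


@dataclass
class FusionConfig:
    beta: float = 1e-3
    max_alt_iters: int = 10
    tol: float = 1e-6
    stride: int = 2
    max_halvings: int = 8
    gn_steps: int = 10
    literal_regularizer: bool = False
    margin_px: int = 24
    # Gaussian pre-smoothing (px) applied to both sides of the
    # photometric residual during transform steps: splatting already
    # low-passes the canvas, so matching it against the raw image biases
    # the alignment; band-limiting both sides removes that asymmetry
    smooth_sigma: float = 0.75
    # coarse-to-fine: early sweeps use a wider smoothing kernel so that
    # several-pixel initial misalignments stay inside the Gauss-Newton
    # basin, then anneal down to smooth_sigma
    coarse_sigma: float = 2.5
    coarse_sweeps: int = 4
    # one-time exhaustive integer-translation search radius (px) run on
    # the first sweep, which captures initializations outside the
    # Gauss-Newton basin
    search_px: int = 4
    # refine each consecutive pairwise transform photometrically (the
    # Eq.-3 seam energy) and recompose before the global alternation;
    # the pairwise problems have clean two-image optima and pull chain
    # initializations into the global basin
    pairwise_init: bool = True
    # gauge anchor: the photometric energy is invariant to one common
    # similarity applied to every transform; fixing the first image's
    # correction at identity removes that freedom
    anchor_first: bool = True


@dataclass
class FusionState:
    images: list[np.ndarray]
    masks: list[np.ndarray]
    base_transforms: list[Similarity4]  # chain-initial image -> panorama maps
    corrections: list[Similarity4]  # optimized per-image corrections
    config: FusionConfig
    origin: np.ndarray  # canvas (x0, y0) in panorama coordinates
    shape: tuple[int, int]  # canvas (H, W)
    canvas: np.ndarray | None = None  # c estimates
    weight_sum: np.ndarray | None = None
    color_sum: np.ndarray | None = None
    contributions: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)
    energy_history: list[float] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def beta(self) -> float:
        return self.config.beta

    @property
    def transforms(self) -> list[Similarity4]:
        """Full image -> panorama transforms, ``C_k o T_k_init``."""
        return [C.compose(T0) for C, T0 in zip(self.corrections, self.base_transforms)]

    def deltas(self) -> np.ndarray:
        """Per-image regularizer deviation vectors, shape (K, 4).

        The regularized quantity is the correction: its deviation from
        identity by default, its raw parameter vector in literal mode.
        """
        ident = np.zeros(4) if self.config.literal_regularizer else np.array([1.0, 0, 0, 0])
        return np.stack([C.params - ident for C in self.corrections])

    def canvas_coords(self, k: int, stride: int | None = None):
        """Stride-sampled valid pixels of image k and their canvas coords.

        Returns ``(base_pts, warped, vals)`` where ``base_pts`` are the
        image points already mapped by the base transform (the
        coordinates the correction acts on linearly).
        """
        stride = stride or self.config.stride
        img, mask = self.images[k], self.masks[k]
        yy, xx = np.mgrid[0 : img.shape[0] : stride, 0 : img.shape[1] : stride]
        sel = mask[yy, xx]
        pts = np.stack([xx[sel].astype(float), yy[sel].astype(float)], axis=1)
        base_pts = self.base_transforms[k].apply(pts)
        warped = self.corrections[k].apply(base_pts) - self.origin[None, :]
        return base_pts, warped, img[yy, xx][sel]


def _as_gray(x) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(x, Frame):
        return x.gray, x.valid_mask()
    arr = np.asarray(x, dtype=float)
    return arr, np.ones(arr.shape, dtype=bool)


def _bilinear(img: np.ndarray, xy: np.ndarray, fill=np.nan) -> np.ndarray:
    return ndimage.map_coordinates(
        img, np.stack([xy[:, 1], xy[:, 0]]), order=1, mode="constant", cval=fill
    )


# ---------------------------------------------------------------------
# pairwise seam residuals (Eq. 3 form)
# ---------------------------------------------------------------------

def seam_residuals(
    img_i,
    img_prev,
    T: Similarity4,
    stride: int = 2,
    weights: np.ndarray | None = None,
) -> SeamResiduals:
    """Seam differences between image i and image i-1 under ``T``.

    ``T`` maps image-i coordinates to image-(i-1) coordinates; one
    residual per overlap pixel on a ``stride``-subsampled grid, with
    bilinear lookup on the warped side.  Raises on empty overlap.
    """
    gi, mi = _as_gray(img_i)
    gp, mp = _as_gray(img_prev)
    yy, xx = np.mgrid[0 : gi.shape[0] : stride, 0 : gi.shape[1] : stride]
    sel = mi[yy, xx]
    pts = np.stack([xx[sel].astype(float), yy[sel].astype(float)], axis=1)
    warped = T.apply(pts)
    inb = (
        (warped[:, 0] >= 0)
        & (warped[:, 0] <= gp.shape[1] - 1)
        & (warped[:, 1] >= 0)
        & (warped[:, 1] <= gp.shape[0] - 1)
    )
    if inb.sum():
        mask_prev = _bilinear(mp.astype(float), warped[inb], fill=0.0) > 0.999
        keep = np.flatnonzero(inb)[mask_prev]
    else:
        keep = np.array([], dtype=int)
    if len(keep) == 0:
        raise ValueError("empty overlap between images under the given transform")
    pts, warped = pts[keep], warped[keep]
    e = gi[pts[:, 1].astype(int), pts[:, 0].astype(int)] - _bilinear(gp, warped)
    w = np.ones(len(e)) if weights is None else np.asarray(weights, float)[keep]
    return SeamResiduals(xy=pts, xy_prime=warped, e=e, w=w)


def align_pair(
    img_i,
    img_prev,
    T_init: Similarity4,
    sigmas: tuple[float, ...] = (2.5, 1.0, 0.5),
    search_px: int = 4,
    gn_steps: int = 12,
    stride: int = 2,
) -> Similarity4:
    """Photometric refinement of a single pairwise transform.

    ``T_init`` maps image-i coordinates into image-(i-1) coordinates;
    the seam energy ``sum e^2`` (Eq.-3 residuals) is minimized by an
    integer-translation scan followed by Gauss-Newton, coarse to fine.
    """
    gi, mi = _as_gray(img_i)
    gp, mp = _as_gray(img_prev)
    T = Similarity4.from_params(T_init.params)
    yy, xx = np.mgrid[0 : gi.shape[0] : stride, 0 : gi.shape[1] : stride]
    sel = mi[yy, xx]
    pts = np.stack([xx[sel].astype(float), yy[sel].astype(float)], axis=1)

    for si, sigma in enumerate(sigmas):
        gi_s = ndimage.gaussian_filter(gi, sigma, mode="nearest")
        gp_s = ndimage.gaussian_filter(gp, sigma, mode="nearest")
        gy, gx = np.gradient(gp_s)
        vals = gi_s[yy, xx][sel]

        def mean_energy(Tc: Similarity4) -> float:
            warped = Tc.apply(pts)
            inb = (
                (warped[:, 0] >= 0) & (warped[:, 0] <= gp.shape[1] - 1)
                & (warped[:, 1] >= 0) & (warped[:, 1] <= gp.shape[0] - 1)
            )
            if inb.sum() < 32:
                return np.inf
            ok = _bilinear(mp.astype(float), warped[inb], fill=0.0) > 0.999
            if ok.sum() < 32:
                return np.inf
            e = vals[inb][ok] - _bilinear(gp_s, warped[inb][ok])
            return float(np.mean(e**2))

        if si == 0 and search_px > 0:
            best = (mean_energy(T), T)
            for dx in range(-search_px, search_px + 1):
                for dy in range(-search_px, search_px + 1):
                    cand = Similarity4(T.r1, T.r2, T.t1 + dx, T.t2 + dy)
                    e_c = mean_energy(cand)
                    if e_c < best[0]:
                        best = (e_c, cand)
            T = best[1]

        for _ in range(gn_steps):
            warped = T.apply(pts)
            inb = (
                (warped[:, 0] >= 0) & (warped[:, 0] <= gp.shape[1] - 1)
                & (warped[:, 1] >= 0) & (warped[:, 1] <= gp.shape[0] - 1)
            )
            ok = _bilinear(mp.astype(float), warped[inb], fill=0.0) > 0.999
            p_in = pts[inb][ok]
            w_in = warped[inb][ok]
            if len(p_in) < 32:
                break
            e = gi_s[p_in[:, 1].astype(int), p_in[:, 0].astype(int)] - _bilinear(gp_s, w_in)
            cgx = _bilinear(gx, w_in, fill=0.0)
            cgy = _bilinear(gy, w_in, fill=0.0)
            x, y = p_in[:, 0], p_in[:, 1]
            J = -(
                cgx[:, None] * np.stack([x, -y, np.ones_like(x), np.zeros_like(x)], axis=1)
                + cgy[:, None] * np.stack([y, x, np.zeros_like(x), np.ones_like(x)], axis=1)
            )
            try:
                step = np.linalg.solve(J.T @ J + 1e-9 * np.eye(4), -(J.T @ e))
            except np.linalg.LinAlgError:
                break
            e_before = mean_energy(T)
            accepted = False
            scale = 1.0
            for _h in range(9):
                cand = Similarity4.from_params(T.params + scale * step)
                if mean_energy(cand) < e_before - 1e-15:
                    T = cand
                    accepted = True
                    break
                scale *= 0.5
            if not accepted or np.linalg.norm(scale * step) < 1e-10:
                break
    return T


# ---------------------------------------------------------------------
# energy
# ---------------------------------------------------------------------

def energy_terms(e: np.ndarray, w: np.ndarray | float, beta: float, deltas: np.ndarray) -> float:
    """``sum(w e^2) + beta * sum(deltas^2)`` — the loss in closed form."""
    e = np.asarray(e, dtype=float)
    if np.any(~np.isfinite(e)):
        raise ValueError("NaN/inf intensity in residuals")
    return float(np.sum(np.asarray(w, dtype=float) * e**2) + beta * np.sum(np.asarray(deltas, dtype=float) ** 2))


def _photo_residuals(state: FusionState, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Residuals of image k against the canvas: (e, canvas xy, base pts)."""
    pts, warped, vals = state.canvas_coords(k)
    H, W = state.shape
    inb = (
        (warped[:, 0] >= 0) & (warped[:, 0] <= W - 1)
        & (warped[:, 1] >= 0) & (warped[:, 1] <= H - 1)
    )
    pts, warped, vals = pts[inb], warped[inb], vals[inb]
    valid = _bilinear((state.weight_sum > 0).astype(float), warped, fill=0.0) > 0.999
    pts, warped, vals = pts[valid], warped[valid], vals[valid]
    e = vals - _bilinear(state.canvas, warped)
    return e, warped, pts


def fusion_energy(state: FusionState) -> float:
    """Full-state energy: photometric term over all images + regularizer."""
    if state.canvas is None:
        raise ValueError("canvas not initialized; run optimize_colors first")
    total = 0.0
    for k in range(len(state.images)):
        e, _, _ = _photo_residuals(state, k)
        if np.any(~np.isfinite(e)):
            raise ValueError("NaN intensity encountered")
        total += float(np.sum(e**2))
    return total + state.beta * float(np.sum(state.deltas() ** 2))


# ---------------------------------------------------------------------
# alternating steps
# ---------------------------------------------------------------------

def optimize_colors(state: FusionState) -> np.ndarray:
    """Exact color step: weighted mean of all splatted source intensities.

    Each image is resampled onto the canvas by bilinear splatting; the
    per-image accumulators are kept so seam evaluation can inspect the
    individual contributions.  Pixels with no contribution are invalid
    (weight 0).
    """
    H, W = state.shape
    csum = np.zeros((H, W))
    wsum = np.zeros((H, W))
    state.contributions = []
    for k in range(len(state.images)):
        pts, warped, vals = state.canvas_coords(k, stride=1)
        inb = (
            (warped[:, 0] > -1) & (warped[:, 0] < W)
            & (warped[:, 1] > -1) & (warped[:, 1] < H)
        )
        warped, vals = warped[inb], vals[inb]
        ck = np.zeros((H, W))
        wk = np.zeros((H, W))
        x0 = np.floor(warped[:, 0]).astype(int)
        y0 = np.floor(warped[:, 1]).astype(int)
        fx = warped[:, 0] - x0
        fy = warped[:, 1] - y0
        for dx, dy, wgt in (
            (0, 0, (1 - fx) * (1 - fy)),
            (1, 0, fx * (1 - fy)),
            (0, 1, (1 - fx) * fy),
            (1, 1, fx * fy),
        ):
            xs, ys = x0 + dx, y0 + dy
            ok = (xs >= 0) & (xs < W) & (ys >= 0) & (ys < H)
            np.add.at(ck, (ys[ok], xs[ok]), wgt[ok] * vals[ok])
            np.add.at(wk, (ys[ok], xs[ok]), wgt[ok])
        state.contributions.append((ck, wk))
        csum += ck
        wsum += wk
    with np.errstate(invalid="ignore", divide="ignore"):
        canvas = np.where(wsum > 0, csum / np.maximum(wsum, 1e-12), 0.0)
    state.canvas = np.clip(canvas, 0.0, 1.0)
    state.weight_sum = wsum
    state.color_sum = csum
    return state.canvas


def optimize_transform(
    state: FusionState, k: int, sigma: float | None = None, search_px: int = 0
) -> Similarity4:
    """Gauss-Newton update of ``T_k`` with the canvas fixed.

    The warped coordinate is linear in (r1, r2, t1, t2), so each step
    solves a 4x4 normal system built from canvas gradients; steps are
    halved (at most ``max_halvings`` times) until the energy of image
    k's terms decreases, otherwise the transform is left unchanged.
    """
    cfg = state.config
    beta = state.beta
    ident = np.zeros(4) if cfg.literal_regularizer else np.array([1.0, 0, 0, 0])

    # residuals against the leave-one-out canvas: the mean of the OTHER
    # images' contributions.  With c held in that form the step for T_k
    # is decoupled from image k's own splat, which would otherwise damp
    # every update (the image can never disagree with itself).
    if len(state.images) > 1 and state.color_sum is not None:
        ck, wk = state.contributions[k]
        w_loo = state.weight_sum - wk
        with np.errstate(invalid="ignore", divide="ignore"):
            c_loo = np.where(w_loo > 1e-9, (state.color_sum - ck) / np.maximum(w_loo, 1e-12), 0.0)
        c_ref, w_ref = np.clip(c_loo, 0.0, 1.0), w_loo
    else:
        c_ref, w_ref = state.canvas, state.weight_sum
    img_ref = state.images[k]
    if sigma is None:
        sigma = cfg.smooth_sigma
    if sigma > 0:
        # normalized convolution on BOTH sides: invalid canvas regions
        # must not smear into valid ones, and the image boundary must be
        # treated the same way or edge pixels acquire phantom residuals
        m = (w_ref > 1e-9).astype(float)
        num = ndimage.gaussian_filter(c_ref * m, sigma, mode="constant")
        den = ndimage.gaussian_filter(m, sigma, mode="constant")
        with np.errstate(invalid="ignore", divide="ignore"):
            c_ref = np.where(m > 0, num / np.maximum(den, 1e-9), 0.0)
        im = state.masks[k].astype(float)
        num_i = ndimage.gaussian_filter(img_ref * im, sigma, mode="constant")
        den_i = ndimage.gaussian_filter(im, sigma, mode="constant")
        with np.errstate(invalid="ignore", divide="ignore"):
            img_ref = np.where(im > 0, num_i / np.maximum(den_i, 1e-9), 0.0)
    gy, gx = np.gradient(c_ref)
    mask = state.masks[k]
    yy, xx = np.mgrid[0 : img_ref.shape[0] : cfg.stride, 0 : img_ref.shape[1] : cfg.stride]
    sel = mask[yy, xx]
    img_pts = np.stack([xx[sel].astype(float), yy[sel].astype(float)], axis=1)
    all_base = state.base_transforms[k].apply(img_pts)
    all_vals = img_ref[yy, xx][sel]

    def residuals():
        warped = state.corrections[k].apply(all_base) - state.origin[None, :]
        H, W = state.shape
        inb = (
            (warped[:, 0] >= 0) & (warped[:, 0] <= W - 1)
            & (warped[:, 1] >= 0) & (warped[:, 1] <= H - 1)
        )
        pts, warped, vals = all_base[inb], warped[inb], all_vals[inb]
        valid = _bilinear((w_ref > 1e-9).astype(float), warped, fill=0.0) > 0.999
        pts, warped, vals = pts[valid], warped[valid], vals[valid]
        return vals - _bilinear(c_ref, warped), warped, pts

    def local_energy() -> float:
        e, _, _ = residuals()
        d = state.corrections[k].params - ident
        return float(np.sum(e**2) / max(len(e), 1) * len(all_vals) + beta * np.sum(d**2))

    if search_px > 0:
        # exhaustive integer-shift scan of the correction translation
        base = state.corrections[k].params
        best_p, best_e = base, local_energy()
        for dx in range(-search_px, search_px + 1):
            for dy in range(-search_px, search_px + 1):
                if dx == 0 and dy == 0:
                    continue
                cand = base + np.array([0.0, 0.0, dx, dy])
                state.corrections[k] = Similarity4.from_params(cand)
                e_c = local_energy()
                if e_c < best_e:
                    best_p, best_e = cand, e_c
        state.corrections[k] = Similarity4.from_params(best_p)

    for _ in range(cfg.gn_steps):
        e, warped, base_pts = residuals()
        if len(e) < 8:
            state.warnings.append(f"image {k}: too little canvas overlap")
            break
        cgx = _bilinear(gx, warped, fill=0.0)
        cgy = _bilinear(gy, warped, fill=0.0)
        x, y = base_pts[:, 0], base_pts[:, 1]
        # d(warp)/d(r1,r2,t1,t2) rows: x' -> (x, -y, 1, 0); y' -> (y, x, 0, 1)
        J = -(
            cgx[:, None] * np.stack([x, -y, np.ones_like(x), np.zeros_like(x)], axis=1)
            + cgy[:, None] * np.stack([y, x, np.zeros_like(x), np.ones_like(x)], axis=1)
        )
        d = state.corrections[k].params - ident
        A = J.T @ J + beta * np.eye(4)
        b = -(J.T @ e + beta * d)
        try:
            step = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            state.warnings.append(f"image {k}: singular normal matrix, no update")
            break
        if not np.all(np.isfinite(step)):
            state.warnings.append(f"image {k}: non-finite step, no update")
            break
        e_before = local_energy()
        base = state.corrections[k].params
        accepted = False
        scale = 1.0
        for _h in range(cfg.max_halvings + 1):
            state.corrections[k] = Similarity4.from_params(base + scale * step)
            if local_energy() < e_before - 1e-15:
                accepted = True
                break
            scale *= 0.5
        if not accepted:
            state.corrections[k] = Similarity4.from_params(base)
            break
        if np.linalg.norm(scale * step) < 1e-10:
            break
    return state.transforms[k]


# ---------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------

def _canvas_geometry(images, transforms, margin: int) -> tuple[np.ndarray, tuple[int, int]]:
    lo = np.array([np.inf, np.inf])
    hi = -lo.copy()
    for img, T in zip(images, transforms):
        h, w = img.shape
        corners = np.array([[0, 0], [w - 1, 0], [0, h - 1], [w - 1, h - 1]], float)
        warped = T.apply(corners)
        lo = np.minimum(lo, warped.min(axis=0))
        hi = np.maximum(hi, warped.max(axis=0))
    origin = np.floor(lo).astype(float) - margin
    size = np.ceil(hi - origin).astype(int) + margin + 1
    return origin, (int(size[1]), int(size[0]))


def fuse(
    images,
    initial_transforms: list[Similarity4],
    config: FusionConfig | None = None,
) -> FusionState:
    """Alternate color and transform optimization until convergence.

    ``initial_transforms`` map each image into a common panorama frame
    (typically from the filtered chain).  Returns the final state with
    canvas, per-image transforms and the recorded energy history
    (non-increasing over accepted iterations).
    """
    cfg = config or FusionConfig()
    grays, masks = zip(*[_as_gray(im) for im in images])
    base = [Similarity4.from_params(T.params) for T in initial_transforms]
    if cfg.pairwise_init and len(base) > 1:
        refined = [base[0]]
        for k in range(1, len(base)):
            # relative map: image k -> image k-1 coordinates
            rel = base[k - 1].inverse().compose(base[k])
            rel = align_pair(grays[k], grays[k - 1], rel)
            refined.append(refined[-1].compose(rel))
        base = refined
    origin, shape = _canvas_geometry(grays, base, cfg.margin_px)
    state = FusionState(
        images=list(grays),
        masks=list(masks),
        base_transforms=base,
        corrections=[Similarity4.identity() for _ in base],
        config=cfg,
        origin=origin,
        shape=shape,
    )
    optimize_colors(state)
    energy = fusion_energy(state)
    state.energy_history.append(energy)
    first = 1 if cfg.anchor_first and len(state.images) > 1 else 0
    for sweep in range(cfg.max_alt_iters):
        sigma = cfg.coarse_sigma if sweep < cfg.coarse_sweeps else cfg.smooth_sigma
        search = cfg.search_px if sweep == 0 else 0
        snapshot = (
            [Similarity4.from_params(C.params) for C in state.corrections],
            state.canvas, state.weight_sum, state.color_sum,
            list(state.contributions),
        )
        for k in range(first, len(state.images)):
            optimize_transform(state, k, sigma=sigma, search_px=search)
        optimize_colors(state)
        new_energy = fusion_energy(state)
        if new_energy > energy + 1e-12:
            # the sweep made the global energy worse (transform steps
            # are accepted on their local leave-one-out objective):
            # roll the whole sweep back and stop
            (state.corrections, state.canvas, state.weight_sum,
             state.color_sum, state.contributions) = snapshot
            break
        improvement = energy - new_energy
        energy = new_energy
        state.energy_history.append(energy)
        if improvement < cfg.tol:
            break
    return state
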