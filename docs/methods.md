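# Methods

`gastropano` reconstructs a panorama of the gastric inner wall from an
endoscopic frame sequence and detects polyps on the unfolded panorama.
No clinical data ships with the package: every stage is exercised
against a synthetic gastric phantom whose ground truth is exact by
construction. This note records the models, the numerical choices, and
what the synthetic experiments do and do not demonstrate.

## The phantom

**Geometry.** The stomach cavity is approximated by two axis-aligned
cubes of edge `edge_mm` (default 60 mm) joined through a rectangular
opening; the second cube is offset by half an edge along y, which
leaves two wall strips on the junction plane and gives 12 exposed
planar interior faces. Planarity is the point: the map between two
views of the same face is an *exact* homography, computed analytically
from the camera poses (plane-induced homography), so registration,
chain filtering and fusion can all be scored against closed-form truth.

**Appearance.** Mucosa is band-limited value noise (four octaves, 6 to
48 cells per face) with darker vessel-like quadratic Bezier curves.
Polyps are circular blobs with a brightened dome and a brighter rim,
drawn into the face texture; their panorama-space boxes follow exactly
from the unfold layout. Degradations mimic endoscopic capture and are
applied *after* ground truth is recorded: additive clipped Gaussian
bright spots (specular reflections on wet mucosa) and zero-mean
Gaussian intensity noise with standard deviation equal to the "noise
scalar" on the [0,1] scale; the robustness grid is
{0.01, 0.05, 0.1, 0.2, 0.5}. All randomness flows from one integer
seed; identical seeds give bit-identical sequences.

**What the phantom does not model:** peristaltic deformation, fluid and
bubble artifacts, view-dependent shading, real mucosal texture
statistics. Passing tests show the algorithms are correct and stable
under controlled noise and speculars, not that clinical performance
matches the published clinical figures.

## Calibration

Equidistant 4-coefficient fisheye model
(`theta_d = theta (1 + k1 th^2 + ... + k4 th^8)`), the standard
parametrization for endoscope-like wide-angle lenses. Calibration
detects inner chessboard corners (Harris + subpixel refinement),
orders them by principal-axis row splitting at the largest gaps, and
initializes intrinsics by Zhang's homography method. Refinement is
staged Levenberg-Marquardt on pixel reprojection error: first with
distortion pinned at zero (the initialization is pinhole-biased), then
all parameters free. Two guards matter in practice: a graded ridge on
k (stronger on the nearly unidentifiable higher orders) keeps
coefficients the data cannot constrain at zero without biasing the
focal estimate, and views whose per-view RMS is a gross outlier
(mis-ordered corners) are dropped and the fit repeated. The RMS
reprojection error is always reported. Undistortion inverse-maps each
ideal pinhole pixel through the model with bilinear interpolation;
pixels sampling outside the captured frame are zeroed and excluded
from a validity mask that the feature detector honors.

## Registration (HPFT)

Initial features are SIFT keypoints (scikit-image) matched with a 0.8
ratio test and cross-check, capped at 200 correspondences sorted by
descriptor distance. The frame-to-frame homography `m' ~ rho H m` is
estimated by normalized DLT; the projectively redundant scale `rho` is
folded into the `H[2,2] = 1` normalization and reported. Robust
estimation is seeded RANSAC (2 px symmetric transfer threshold, 500
iterations) with a DLT refit on the consensus set.

Homographic patch verification subdivides frame A as a quadtree (split
into 4 quadrants from the patch center; minimum patch 16 px, maximum
depth 4). Each patch gets a local homography (robustly fit from the
correspondences it contains, inheriting its parent's otherwise) and a
similarity score: symmetric Kullback-Leibler divergence between
32-bin intensity histograms of the patch and of its H-warped
counterpart in frame B (threshold 0.15). A correspondence is verified
when its patch passes the KL test *and* its own transfer error under
the patch homography is at most 2 px; the second condition is what
rejects individually wrong matches inside a correctly-registered patch
— a pure per-patch rule would verify any outlier whose patch happens
to pass. Patches that reach the size/depth limit without passing
reject their correspondences. Known limitation (by design of the
histogram reduction): constant-intensity patches have zero KL
divergence and verify regardless of geometric error.

## Closed-chain filtering

An in-and-out pass is a cycle of pairwise registrations whose
composition must be the identity. Edges default to 4-DOF similarities
`(r1, r2, t1, t2)` (linear part `[[r1, -r2], [r2, r1]]`), the same
family the fusion stage optimizes; the loop residual is summarized by
the mean corner displacement of the composed loop. Filtering
alternates: (1) split the loop residual into equal per-edge shares in
angle, log-scale and translation and correct each edge; (2) reject
correspondences whose transfer error under the corrected edge exceeds
2 px — trimming at most the worst ~20% per round so that an edge fit
skewed by outliers cannot reject its own inliers; (3) refit edges from
survivors. Rounds that would increase the residual are rolled back, so
the final residual never exceeds the initial one; the loop stops at a
fixed point or after 10 rounds.

## Optical-consistency fusion

The fusion energy is

    E(c, T) = sum_k sum_x w (I_k(x) - c(T_k(x)))^2 + beta sum_k D_k' D_k

over panorama gray values `c` and one 4-DOF similarity per image.
Alternating minimization:

* **Colors.** With T fixed, the optimal c is the weighted mean of all
  source intensities; images are bilinearly splatted onto the canvas
  and per-image accumulators are kept for seam evaluation. Weights
  default to 1 (feathering optional).
* **Transforms.** With c fixed the warped coordinate is linear in the
  four parameters, so Gauss-Newton steps solve a 4x4 normal system per
  image, with step halving (at most 8) and acceptance only on energy
  decrease. Each image is aligned against the leave-one-out canvas
  (the other images' mean): aligning against a canvas containing the
  image's own splat damps every update. Both sides of the residual are
  band-limited with a mask-normalized Gaussian (0.75 px; 2.5 px on the
  first sweeps) because splatting already low-passes the canvas and
  the asymmetry otherwise biases alignment.

Two structural choices stabilize the joint problem. First, transforms
are parametrized as corrections composed with the chain-derived
initialization, and the regularizer `beta D'D` (beta = 1e-3 on the
[0,1] intensity scale) penalizes the correction's deviation from
identity: penalizing deviation of the *global* transform from identity
would drag the whole mosaic toward the origin, and the literal
parameter-vector form (available via `literal_regularizer`) penalizes
the identity pose itself. Second, before the global alternation each
consecutive pairwise transform is refined photometrically on the
pairwise seam residuals (integer-shift scan then coarse-to-fine
Gauss-Newton) and the chain is recomposed: the pairwise problems have
clean two-image optima, and without this the global alternation can
stall in mutually-consistent but misaligned configurations. The first
image's correction is held at identity to fix the gauge (the energy is
invariant to one common similarity).

Grayscale drives the optimization; color is composited per channel
with the optimized transforms and weights at export. The recorded
energy history is non-increasing by construction (steps and sweeps are
only accepted on decrease).

## Double-cube projection

Each panorama pixel is lifted through the fixed 2-row unfold layout
(per-face slots with 2 px gutters, pitch in px/mm, documented in the
output sidecar) to a surface point, projected into every frame that
sees it — visibility checked by casting the ray against the cavity
geometry (disable via `zbuffer=False`) — and filled with the weighted
mean of the frame samples. The layout is injective by construction and
the surface <-> panorama mapping inverts to well under half a pixel.
The layout is a stated convention of this package, not a reconstruction
of any particular published unfolding.

## Selective single-shot detection

Polyps occupy a tiny fraction of a panorama, so nearly all anchors are
background. The detector is a small convolutional network implemented
directly on numpy (manual backpropagation, Adam, float64,
deterministic given the seed): three 3x3 conv blocks with 2x2 max
pooling give feature maps at strides 4 and 8; 1x1 heads emit, per
anchor (one scale per level — 10 and 18 px — and aspect ratios 1, 1.5,
0.67), four SSD-style box offsets and two class logits. Head weights
are initialized small and the class biases to a ~1% foreground prior,
which keeps the first epochs stable for any trunk initialization. Anchors whose
centers fall in panorama gutters are masked out of training and
inference, and predicted boxes are clipped to the face slot under
their center. Input normalization is per-image mean/std over valid
pixels.

Training assigns anchors by IOU (positive at 0.5, the best anchor per
truth box forced positive), and the confidence loss runs over the
positives plus the *selected* negatives only: negatives sorted by
confidence loss (most confidently wrong first), top `3 x #positives`
kept, ties broken toward lower anchor index, everything else
discarded. Localization is smooth-L1 over positives; both terms are
normalized by the positive count. The `mining="all"` ablation trains
on every negative under the same budget. The benchmark problem — 40
training and 10 held-out phantom panoramas (126 x 344 px at 1 px/mm,
2-4 polyps of 4-6.5 mm each), 20 epochs — is sized for a single CPU
core; the clinical-scale network behind the published accuracies is
out of scope.

## Evaluation

* **Detection tallies:** greedy one-to-one matching in descending
  confidence at IOU > 0.5. Recall in count-based (clinical-style)
  tallies counts reference findings with an associated detection;
  accuracy is the fraction of detections localized at IOU > 0.5 —
  that convention is the only one consistent with the published
  contingency rows. Percentages are reported to one decimal.
* **Texture error:** the published metric's definition is not
  reproducible from its citation, so this package defines the
  "gastropano texture error": per canvas pixel with two or more
  contributions, the mean pairwise absolute difference of the
  contributed intensities; region scores are means over masks, overall
  the coverage-weighted mean. Scores are not numerically comparable
  with the published clinical table and are never presented as such.
* **FB robustness:** a feature's forward-backward error is the
  distance from its start to its position after mapping into the other
  frame and back. Plain matching uses independent ratio-test matching
  in both directions (features without matches fail); HPFT uses the
  better of the feature's own match cycle and the patch-homography
  field (estimated independently per direction) — HPFT builds on the
  same initial matches, so its evidence is a structural superset.
  Counts of sub-threshold features per noise scalar are averaged over
  5 seeds; 200 initial features per condition, detection on a 1 px
  noise-suppressed copy for both methods. The monotone-degradation
  check allows a 2-count tolerance on the seed means: at the floor,
  one or two spurious self-consistent matches on pure noise flicker
  between conditions.

## Reproducibility and problem sizes

Every stochastic step (texture synthesis, trajectory jitter, noise,
RANSAC, weight init, epoch shuffling) derives from explicit integer
seeds; single-threaded runs are bit-reproducible. Benchmarks
(`gastropano.benchmarks`) use 160x120 frames for loop experiments,
320x240 for the 200-feature FB protocol, 7-9 frame loops, and the
detection problem above; these sizes are the package's chosen study
conditions, and all headline numbers are recomputed from them at run
time by `scripts/acceptance.py`.
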