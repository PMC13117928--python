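# Methods

## Pipeline

The package implements a two-stage mass-analysis pipeline. Stage one
produces candidate lesions as axis-aligned boxes with confidence scores in
[0, 1]; stage two crops each box (plus padding), enhances the crop, and
refines it into a binary lesion mask with a Chan–Vese active contour. All
coordinates are 0-based and half-open with x = column, y = row; all internal
intensities are floats in [0, 1], converted only at the 8/16-bit PNG/TIFF
I/O boundary.

Preprocessing follows the screening convention: the full image is resized
anisotropically to 640×640 (bilinear for intensities, nearest-neighbor for
masks, coordinate scaling for boxes), and each detected ROI is enhanced with
CLAHE followed by a 3×3 median filter. CLAHE is applied per ROI, not to the
full image, because the contrast that matters is local to the candidate
mass. The CLAHE `clip_limit` is exposed in the familiar integer-histogram
convention (default 2.0, tiles 8×8) and mapped internally to the normalized
clip fraction `clip/256` of scikit-image's implementation; the tile grid is
reduced automatically on small ROIs.

## Segmentation model

The Chan–Vese functional is minimized over (c1, c2, φ):

- `c1`, `c2` are the smoothed-Heaviside-weighted means of `u0` inside and
  outside the contour and are refreshed after every φ update (the exact
  minimizers given φ).
- φ follows the explicit gradient-descent update
  `φ += dt · δ_ε(φ) · [μ κ(φ) − ν − λ1 (u0 − c1)² + λ2 (u0 − c2)²]`
  with curvature `κ = div(∇φ / (|∇φ| + η))` by central differences and
  reflecting boundaries.
- `H_ε(z) = ½(1 + (2/π) arctan(z/ε))` and `δ_ε(z) = ε/(π(ε² + z²))` are the
  arctan-regularized Heaviside/delta pair. Their tails are heavy (∝ ε/z), so
  hard-partition limits are approached only linearly in ε; tests that probe
  the crisp limit scale φ accordingly.

Defaults and their meaning:

| parameter | default | role |
|---|---|---|
| `mu` | 3 | contour-length penalty on [0,1] intensities; larger → rounder masks |
| `nu` | 0 | signed-area penalty (off) |
| `lambda1`, `lambda2` | 1, 1 | inside/outside region-fit weights |
| `epsilon` | 1.0 | Heaviside smoothing width in level-set units |
| `dt` | 0.5 | explicit time step |
| `n_iter` | 436 | iteration budget |
| `init_radius` | 40 px | initialization-circle radius |
| `reinit_every` | 20 | signed-distance reinitialization period |
| `eta` | 1e-8 | curvature denominator guard |

Initialization is a signed-distance circle centered on the detected box
(after cropping, the ROI center — the only reading that places the seed on
the candidate mass). On ROIs smaller than 100 px the radius is clipped to
0.4× the shorter ROI side so the seed stays inside the crop.

**Reinitialization is on by default (every 20 steps).** The explicit
`δ_ε`-weighted update only modifies φ in a band around the contour, which
steepens |∇φ| there and slows the contour's geometric speed; without
reinitialization the contour stalls well before the iteration budget is
spent (a centered disk benchmark converges to DICE ≈ 0.80 instead of
≈ 1.0). Rebuilding a signed-distance profile every 20 steps keeps |∇φ| ≈ 1
and restores the nominal speed at negligible cost; much more frequent
reinitialization is counterproductive because each rebuild snaps the zero
level set to pixel resolution. Reinitialization occasionally bumps the
energy by a small amount, which is why a small fraction of steps (bounded at
5% in the tests) may increase it; the trend is strictly downward.

The mask rule is {φ ≥ 0} (ties inside). Divergence of the explicit scheme is
detected (non-finite φ) and reported with advice to lower `dt`;
degenerate partitions (one side numerically empty) raise rather than divide
by ~0. A fully empty or fully full final mask is logged as degenerate — the
expected outcome on ROIs with no data force, such as the false-positive
background crops a weak detector produces.

## Detection

- **oracle**: replays ground-truth boxes, optionally dropping each with
  probability `drop_prob` and jittering corners by uniform ±`jitter_px`
  noise; confidence is `1 − max|perturbation|/jitter_px` (1.0 unjittered).
  It decouples segmentation quality from detector quality.
- **blob**: scale-normalized negative Laplacian-of-Gaussian responses over a
  geometric σ grid (default 8–24 px, 6 scales ≈ mass radii 11–34 px); local
  maxima above `response_floor` become boxes of side 2√2·σ; confidence is the
  response divided by the image's maximal response — usable for the
  threshold sweep but not calibrated across images.
- **external**: reads YOLO-format label files (optional sixth confidence
  column) written by any third-party detector.

All detectors feed greedy NMS (suppress iff IoU > 0.5 with a kept box;
confidence ties broken lexicographically by (x0, y0) for reproducibility)
and a top-10 cap per image.

## Evaluation protocol

Matching is the standard one-match-per-ground-truth rule: predictions in
descending confidence greedily claim the unmatched ground truth of highest
IoU ≥ 0.5. Precision and recall use 0/0 := 1 (an empty prediction set
issues no false alarms). Average precision pools predictions across images
and integrates the precision envelope over recall (all-point
interpolation); with a single class this equals mAP50.

The threshold sweep evaluates every grid value (default 0.4–0.9, step 0.1)
fold-wise under a stratified k-fold assignment (stratified on lesion
severity when known, else lesion count; seeded per-class shuffle plus a
carried round-robin counter keeps both fold sizes and per-fold class counts
within one of proportionality). The pivot is the threshold of maximal mean
mAP50 (ties to the lower threshold), and each threshold's fold-wise mAP50
values are compared against the pivot's with a two-sided Mann–Whitney U test
(exact null when the smaller sample has ≤ 10 values and no ties, otherwise
the tie- and continuity-corrected normal approximation; all-constant pooled
samples are defined as p = 1).

Segmentation is scored per image on composite masks: the union of pasted
ROI masks against the union of ground-truth lesion masks. DICE uses
2|A∩B|/(|A|+|B|) with both-empty := 1. HD95 extracts 4-connected boundary
pixels, pools the two directed nearest-neighbor distance multisets, and
takes the 95th percentile (linear interpolation); a `max_directed` variant
is config-selectable. When exactly one mask is empty the frame diagonal is
returned as a bounded, scale-aware sentinel — this is what makes mean HD95
heavy-tailed relative to median HD95 when occasional images fail entirely.

ROIs are padded by 12 px before cropping (config `roi_pad_px`) so the
contour sees a background ring even around a tight box; tight boxes inscribe
the lesion, leaving only corner background otherwise.

## Phantom generator

The generator emulates the statistics the pipeline depends on, not anatomy:

- a half-ellipse "breast" support (bright ≈ 0.30 base) on a dark (0.02)
  background, filled with Gaussian-smoothed unit-variance noise at σ = 12 px
  scaled to ±0.05 — a stand-in for fibroglandular texture;
- i.i.d. Gaussian sensor noise (σ = 0.03 default);
- star-shaped lesions `r(θ) = R(1 + a·cos(kθ))` with additive contrast
  0.4–0.6 and Gaussian edge blur σ = 1.5 px. Benign lesions are round
  (k = 0); malignant ones are spiculated (k ∈ [5, 8], a ∈ [0.15, 0.30]);
  default mix 40% malignant, radii 18–32 px, 1–2 lesions per image,
  640 px frames, 30 images.

Lesions are placed by rejection sampling (≤ 100 retries, loud failure)
with their outer disk fully inside the breast support and ≥ 4 px clear of
other lesions. Generation is bit-deterministic in the spec (identical seeds
give byte-identical files). Ground truth is exact: per-lesion masks and
tight boxes derived from the rasterized shape.

What the phantoms do **not** model: pectoral muscle, calcifications,
compression artifacts, vessel/ductal structure, intensity inhomogeneity
fields, or lesion texture. Passing tests therefore demonstrate correctness
of the algorithms and protocol under controlled statistics — low-contrast
blobs in textured backgrounds — not clinical performance on real
mammograms.

## Problem sizes and known limitations

The test suite and the acceptance script run on a 30-image, 640 px phantom
study set (1–2 lesions per image), a size chosen so a full end-to-end run
completes in well under a minute on one CPU while still exercising
fold-wise statistics; the segmentation benchmark is a 128 px ROI with a
radius-30 disk at contrast 0.6 and noise σ = 0.02.

Known limitations:

- The length prior (μ = 3) smooths spiculated margins: spicule tips are
  truncated, so DICE on strongly spiculated lesions plateaus around
  0.85–0.90 versus ≈ 0.98 on round lesions. Lowering μ trades this against
  noise robustness.
- Blob confidences are per-image normalized; cross-image threshold sweeps
  with the blob detector measure ranking within images, not calibration.
- The explicit scheme is not unconditionally stable; with much larger `dt`
  or `mu` it can oscillate (divergence is detected, not prevented).
- Two-phase only: one contour per ROI, no multi-lesion separation within a
  single ROI and no shape priors.
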