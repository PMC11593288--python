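# Methods

This note documents the models, conventions, and design choices behind
`hepatomorph`, in the order the pipeline runs.

## Problem setting

A sagittal B-mode section of the left hepatic lobe shows two morphological
correlates of fibrosis: thinning of the lobe (a smaller minor axis of the
section) and irregularity of the dorsal surface. The pipeline quantifies
both from a binary segmentation mask of the lobe: classical particle-style
shape descriptors for the thinning signal, and a contour-roughness
statistic for the surface signal, followed by ordinal trend tests against
fibrosis stage (F0–F4) and ROC analysis of dichotomized endpoints (≥F3,
F4). The package assumes one lobe per image, an approximately horizontal
lateral orientation (the front/rear split cuts at the leftmost and
rightmost contour vertices), and pixel units throughout — no physical
calibration is applied, matching how such features are reported in
practice.

## Raster and contour conventions

These conventions fix the absolute scale of every length-derived feature
and are therefore stated explicitly:

* Coordinates: x rightward, y downward, 0-based pixel centers.
* Foreground components are 8-connected; background holes are 4-connected
  and are filled before morphometry. Particles below `min_size` (default
  64 px) are rejected as noise.
* The contour is the Moore-neighbor trace through boundary **pixel
  centers** (Jacob's stopping criterion). Consecutive vertices are one
  axial (length 1) or one diagonal (length √2) step apart; the perimeter
  is the polygon arc length with those weights, and the area is the
  shoelace area of the same polygon. A filled s×s square therefore has
  Perimeter 4(s−1) and Area (s−1)².
* Consequences of this convention, measured on rasterized discs: the
  polygon encloses ≈ π(r−½)² (−1.9 % at r = 50), and the staircase
  overestimates a smooth perimeter by ≈ 5 % (asymptotically 1.0548×), so
  the Circularity of a digitized disc plateaus near 0.89 rather than 1.
  This is the familiar behavior of pixel-chain perimeters in classical
  particle analyzers; corner-weighted corrections (0.948/1.340) would
  remove the bias but break the exact square identities above, and are not
  applied.
* Angles (FeretAngle, ellipse Angle) are reported in degrees in [0, 180),
  measured counter-clockwise from +x in the y-up frame, i.e. image-frame
  angles are negated.
* Square padding appends black pixels at the bottom or right, keeping the
  original content at the top-left so annotation coordinates stay valid.

## Shape descriptors

* **Feret / MinFeret** — maximum pairwise distance over convex-hull
  vertices and minimum caliper width over hull-edge directions (rotating
  calipers). Ties between maximal pairs are broken by smallest angle, then
  smallest FeretX; the reported (FeretX, FeretY) endpoint is the leftmost
  of the pair (ties: smaller y). A collinear point set has MinFeret 0.
* **Major / Minor / Angle** — equal-area moment ellipse: orientation and
  axis ratio from the eigendecomposition of the second-order central
  moments of the foreground pixels (with the +1/12 per-pixel square
  correction), then both axes rescaled so the ellipse area equals the
  pixel count. The alternative pure 2√λ scaling agrees for true ellipses
  but is off by a shape-dependent constant otherwise; the equal-area
  convention is the one used by the classical tool this feature set
  follows.
* **Circularity** is capped at 1.0: raster perimeter underestimation on
  very smooth small shapes can push the raw ratio above 1.
* **Solidity** uses the hull of the traced polygon (Qhull) and shoelace
  areas; tests verify it against an independent exact polygon library.

## Synthetic cohort generator

The generator stands in for clinical data; it defines the study conditions
under which the pipeline is validated.

* **Base shape**: superellipse |x/a|^p + |y/b|^p = 1. The exponent p
  ("bluntness", default drawn U(2.3, 2.7)) gives a two-parameter control
  of margin blunting between an ellipse (p = 2) and a box. A horizontal
  shear (factor 0.08) tilts the section into the caudal wedge profile of a
  real sagittal view. Rotation up to ±8° and small center jitter emulate
  probe variability.
* **Rear-surface roughness**: the dorsal half of the boundary (y > 0
  before rotation) is displaced along the outward normal by a sum of
  `rough_n_waves` random-phase sinusoids, normalized so the peak
  displacement equals `rough_amplitude` (drawn U(4, 9) px for rough
  subjects), windowed by sin²θ so the perturbation vanishes at the lateral
  tips. Only the rear is perturbed, because surface irregularity in
  fibrosis is a dorsal finding.
* **Stage effects**: each subject's minor semi-axis is a baseline draw
  N(88, 8) px multiplied by (1 − 0.10·stage) — a 10 % thinning per stage
  step; the rough-label probability rises with stage as
  (0.05, 0.15, 0.25, 0.40, 0.60), which pools to ≈ 26 % rough under the
  default 5/11/13/11/3 stage counts, matching the ≈ 27:73 rough:smooth
  prevalence of the reference population. The geometric defaults (major
  semi-axis N(170, 12) px on a 512×512 canvas) were chosen once so the
  lobe fills a realistic fraction of the field of view; smaller canvases
  scale the geometry proportionally.
* **Rasterization**: polygon scanline fill at 2× supersampling with
  majority pooling (the single-resolution fill is inclusive by about half
  a pixel; supersampling halves that bias to ≈ 0.2 px per edge).
* **Pseudo-B-mode rendering**: multiplicative Rayleigh speckle, spatially
  correlated by a Gaussian filter (σ = 1.2 px), around mean levels 140
  (parenchyma) and 38 (background), with a bright 1–2 px capsule line
  along the boundary. This reproduces the gross intensity structure that a
  threshold-based segmenter faces — not wave physics: there is no
  depth-dependent attenuation, shadowing, refraction, or anisotropic
  point-spread function. Passing segmentation tests on these images shows
  the pipeline's plumbing is correct at realistic contrast, not that the
  baseline segmenter would survive clinical image quality.
* Determinism: a cohort is byte-identical for a fixed config; truth-only
  generation (`rasterize=False`) consumes the identical random stream, so
  ground-truth parameters match a full run.

## Surface-roughness classification

The roughness score is the RMS of the component of (polyline − its
moving-average smoothing) perpendicular to the smoothed tangent, computed
after resampling the polyline at 1 px arc-length spacing and trimming the
half-window at each end. The tangential component is discarded because it
carries parametrization noise, not surface geometry. For a sinusoidal
corrugation of amplitude A with wavelength well below the window the score
converges to A/√2; a straight or slowly curving arc scores ≈ 0; a smooth
traced raster contour scores ≈ 0.4 px (staircase noise floor), which sets
the scale of the default window (31 px) and fallback threshold (0.5 px).
In the pipeline the threshold is instead calibrated by maximizing balanced
accuracy on a separately-seeded labeled cohort, mirroring a
train/evaluate split. The score-plus-threshold classifier is a
deterministic, auditable stand-in for a learned classifier; any external
scorer can be evaluated through the same reporting path. Augmentation
(rotation ±10°, translation ±10 % of each canvas dimension, no scaling,
nearest-neighbor) is applied to the rough class only, reflecting its
scarcity; the translation bound is interpreted per axis.

Focal loss uses the natural logarithm and γ default 2, the canonical
setting of the original loss; it is provided for training external
classifiers and enters no result computed here.

## Statistics

* **Jonckheere–Terpstra**: JT = Σ over ordered group pairs of
  Mann–Whitney counts with ties counted ½. `method="auto"` enumerates the
  full permutation null only when the pooled n ≤ 12 **and** the number of
  distinct arrangements is ≤ 20 000 (the multinomial coefficient explodes
  well before n does); otherwise it uses the normal approximation with the
  tie-corrected null variance. A seeded 100 000-draw Monte-Carlo
  permutation mode is available as a cross-check. Two-sided p-values
  (2·min(P≥, P≤), capped at 1, for the permutation methods) are the
  default, matching the common statistical-package default; the
  measured type-I error of the default pipeline test under the null
  generator is ≈ 4–5 % at nominal 5 % over 1000 replicates.
* **AUROC** is the pairwise concordance (rank-sum identity). With
  orientation "auto" the marker is flipped when low values indicate the
  positive class — as with Minor, where a thin lobe means advanced
  fibrosis — so reported AUROCs are ≥ 0.5 with the orientation stated.
  Operating points maximize Youden's J over observed cutoffs (the
  convention when a published table does not state how its
  sensitivity/specificity pairs were chosen); F1 = 2TP/(2TP+FP+FN) at that
  cutoff.
* **Confusion reconstruction** rounds sensitivity·n_pos and
  specificity·n_neg to integers and warns when the printed rate is not
  integer-consistent with the class size (relative rounding error above
  1 %).
* Reported tables round to 3 decimals. The feature-by-stage table includes
  all 16 descriptors, Roundness included, even though published stage-trend
  tables commonly omit it. No multiple-testing correction is applied —
  raw p-values are reported, as is usual for this analysis; callers can
  adjust externally.

## Problem sizes

The test suite validates oracle equivalence on 100 random polygons,
parameter recovery on five 43-subject cohorts (the reference stage
distribution) plus pooled per-stage means, the null type-I rate on 1000
truth-only replicates, and law-of-large-numbers generator checks at 200
subjects per stage. The acceptance script runs one full 43-subject
image-level cohort plus the 1000 truth-only null replicates; the type-I
replication uses generated truth values rather than re-measured masks
because the test statistic's null calibration is unaffected by
measurement noise that is independent of stage.

## Known limitations

* The synthetic shapes are star-shaped smooth outlines; real lobes show
  concavities at vessel indentations, partial occlusion by bowel gas, and
  annotation noise, none of which are modeled.
* The baseline segmenter is a global-threshold method; it is a pipeline
  stand-in, not a competitive segmentation model.
* The roughness statistic measures mid-frequency corrugation relative to
  the smoothing window; very long-wavelength undulation (≫ window) is
  treated as shape, not roughness.
* Dice loss is reported per image and as the raw-count aggregate 1 − F;
  batch-averaged variants used by some training frameworks will differ.
* With only 3 subjects at F4 in the default cohort, F4-endpoint operating
  points are highly variable across seeds; this mirrors the reference
  population rather than a fixable defect.
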