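# hepatomorph

Contour morphometry of the sagittal left-liver-lobe section for ultrasound
fibrosis staging.

With advancing hepatic fibrosis the left lobe of the liver thins, its
margin blunts, and its dorsal (rear) surface becomes irregular. These signs
are visible in a standardized sagittal B-mode section, and they can be
quantified: segment the lobe, trace its contour, and measure the classical
particle-analysis shape descriptors — the minor axis of the best-fitting
ellipse (`Minor`) and the minimum caliper width (`MinFeret`) act as markers
of lobe thinning, while rear-contour roughness tracks surface nodularity.

`hepatomorph` implements that analysis as a tested, fully reproducible
pipeline for researchers in quantitative ultrasound and medical image
analysis. Because clinical B-mode images of this kind are not publicly
deposited, the package includes a first-class synthetic cohort generator
that emulates the relevant geometry with known ground truth, so every stage
of the analysis is testable end to end.

## What it computes

**Shape descriptors** (`hepatomorph.shapes`) from a binary mask of the
lobe: Area, Perimeter, Circularity = 4πA/P², Solidity = A/A_hull,
Feret/FeretAngle/FeretX/FeretY and MinFeret by rotating calipers,
Major/Minor/Angle from the equal-area moment-fitted ellipse, bounding-box
Width/Height, AspectRatio = Major/Minor, Roundness = 4A/(π·Major²).
The contour is the Moore-traced polygon through boundary pixel centers;
perimeter steps are 1 (axial) and √2 (diagonal).

**Rear-surface roughness** (`hepatomorph.surface`): the contour is cut at
its leftmost/rightmost vertices into front and rear polylines; the
roughness score is the RMS perpendicular residual of the rear polyline
against its moving-average smoothing (window 31 px). A threshold
calibrated on a labeled set turns the score into a smooth/rough call; per
class and overall accuracies are reported. Focal loss
FL(p_t) = −(1−p_t)^γ ln p_t and the bounded affine augmentation (±10°,
±10 % translation) used when training a neural classifier on contour
images are provided alongside.

**Segmentation metrics** (`hepatomorph.segeval`): IoU = TP/(TP+FP+FN),
F = TP/(TP+(FP+FN)/2), Dice loss = 1−F, linked by F = 2·IoU/(1+IoU);
plus a classical Otsu-based baseline segmenter.

**Statistics** (`hepatomorph.stats`): Jonckheere–Terpstra trend test of
each feature across ordered fibrosis stages F0–F4 (exact enumeration,
Monte-Carlo permutation, or tie-corrected normal approximation), AUROC by
pairwise concordance with Youden-index operating points for the ≥F3 and F4
endpoints, and confusion-matrix/F1 reconstruction from printed
sensitivity/specificity and class sizes.

**Synthetic cohorts** (`hepatomorph.synth`): superellipse lobe sections
with a sheared caudal wedge, optional random-phase sinusoidal perturbation
of the rear surface, and speckle-textured pseudo-B-mode rendering. Stage
effects are injected with known magnitude: the minor semi-axis shrinks by
a configurable fraction per stage (default 10 %), and rough-surface
prevalence rises with stage. The default cohort has 43 subjects with stage
counts 5/11/13/11/3.

## Worked example

```python
import numpy as np
from hepatomorph import synth, shapes, segeval, stats

records = synth.generate_cohort(synth.CohortConfig(seed=1))
rec = records[0]

pred = segeval.baseline_segmenter(rec.image)     # classical segmentation
m = segeval.seg_metrics(pred, rec.mask)
print(f"IoU={m.IoU:.3f} F={m.F:.3f}")            # IoU=0.985 F=0.993

f = shapes.shape_features(pred)
print(f"Minor={f.Minor:.1f} Circularity={f.Circularity:.3f}")
#   Minor=199.7 Circularity=0.797  (a thick, smooth F0 lobe)

stages = np.array([r.stage for r in records])
minors = np.array([
    shapes.shape_features(segeval.baseline_segmenter(r.image)).Minor
    for r in records
])
res = stats.jonckheere_terpstra([minors[stages == s] for s in range(5)])
print(f"JT z={res.z:.2f}, two-sided p={res.p_value:.2e}")
#   JT z=-6.74, two-sided p=1.56e-11  (Minor falls with stage)

d = stats.roc_auc(minors, stages >= 3)
print(f"AUROC(>=F3)={d.auroc:.3f}, orientation={d.orientation}")
#   AUROC(>=F3)=1.000, orientation=low_positive
```

The per-stage means of the measured Minor axis in this cohort are
179.9 / 170.1 / 147.6 / 121.7 / 110.1 px for F0–F4: the injected thinning
is recovered by the full segment-then-measure chain, and the negative JT z
confirms the decreasing trend (low Minor indicates advanced fibrosis,
hence the flipped ROC orientation).

The same analysis is available from the shell:

```sh
hepatomorph run --seed 1 --out run1/
```

writes the cohort (PNG masks/images), `features.csv` (the 16 descriptors
per subject), `segmentation.csv`, `surface_report.csv`, `trend.csv`
(feature-by-stage JT p-values), `diagnostics.csv` (sens/spec/F1/AUROC per
feature for the ≥F3 and F4 endpoints), and a `manifest.json` recording the
seed and versions. Reruns with the same seed are byte-identical.

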