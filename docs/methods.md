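# Methods

## Problem and model

Each axial slice of a CT or MRI series is assigned one anatomical body region.
The output vocabularies are fixed: 17 classes for CT and 18 for MRI (breast is
imaged with dedicated MRI protocols only), ordered alphabetically on canonical
snake_case names so that a classifier output index is stable across runs and
checkpoints. The classifier itself works over the *internal* vocabulary, which
appends one transitional class, `abdomen_chest`, for slices at the
thoraco-abdominal junction; the series-level rule engine resolves it before
anything is reported, so it is never a final label.

Regions are delimited along the patient cranio-caudal axis by named anatomical
landmark pairs (e.g. knee: distal sixth of the femur → proximal sixth of the
tibia). We adopt the DICOM patient-coordinate convention throughout: larger z
is more cranial.

## Ground truth geometry

An annotator places one thin axis-aligned 3D box per region, in patient
coordinates. The box labels every slice — of every series sharing the same
frame of reference — whose *centre* z position falls in the half-open interval
`[z_min, z_max)`. Centre-based membership is the only unambiguous reading for
thin boxes; the half-open convention prevents double labeling at shared
landmarks (the lesser trochanter bounds both pelvis and thigh, T11/T12 are
shared between the thoracic and lumbar spine intervals). Where two boxes still
claim a slice, an explicit precedence list resolves the tie; the default puts
the three spine classes first and the remaining regions in vocabulary order.
This list is a declared convention of this package — a multi-class framework
forces one label per slice, and no canonical resolution exists — and it is
configurable wherever it is consumed.

## Exclusion criteria

Series: only primary axial acquisitions are classified; scouts/localizers,
multiplanar reformats and secondary captures are dropped (keyword-based
detection from SeriesDescription/ImageType, configurable, since no standard
rule exists). Images: obliquity ≤ 45° (inclusive boundary, unit-tested both
sides), more than 8 bits stored, single channel, ≥ 1000 pixels, pixel data
present. Obliquity is computed as the angle between the slice normal and the
patient z axis, which covers doubly-oblique acquisitions with a single number.
Filtering never raises; every removal is logged with exactly one reason, so
`retained + excluded == input` and filtering is idempotent.

## Preprocessing

Per image, with per-image statistics: clip to `[mean − 4σ, mean + 4σ]`,
normalize by `(x − mean)/(2σ)`, copy the channel to three, resize preserving
aspect ratio (bilinear, longer side → 224) and zero-pad centred to 224 × 224.
Normalization runs before padding so the pad value 0 codes for the image mean.
Note the arithmetic: the clip bounds map to ±2, not ±1 — the chain's true
output range is [−2, 2], and the tests pin that. A constant image (σ = 0) is
mapped to all zeros: it carries no anatomical signal and this avoids a
division by zero.

## Classifier

The desk-scale backbone (`compact`) is a fixed uniform average-pooling
convolution (kernel = stride = 8, giving a 28 × 28 feature map from one of the
three identical channels) followed by a fully connected softmax network
(default one hidden layer of 128 units) trained with categorical
cross-entropy (scikit-learn `MLPClassifier`, Adam, lr 1e−3, batch 32, 10
epochs by default). These hyperparameters are package defaults, config-driven.
A `resnet50v2_pretrained` transfer-learning adapter slot exists for
deployments with a deep-learning runtime and published ImageNet weights; the
test suite never requires it.

Training augmentation samples, per image and per epoch with probability
`apply_prob` (default 0.5), a random affine map: rotation in ±π/10,
translation and shear up to 10% of image size in both directions, scaling up
to 20% in both directions, bilinear resampling. Bounds are property-tested
over 10⁴ draws.

Active learning ranks studies by mean slice uncertainty, defined as
1 − max probability (normalized entropy available via config), descending,
ties broken by study id; the top k (default 200) are returned for annotation.

## Series-level rule engine

All stages transform the probability vectors and re-take the argmax, because a
"moving average" over categorical labels is undefined; this also keeps the
stages composable — smoothing cannot resurrect a class whose mass was removed.
Fixed order:

1. **Transitional merge** — the target is whichever of abdomen/chest has more
   argmax slices in the series; absence of both, or a tie, resolves to abdomen
   (by analogy with the stated abdomen fallback). Every slice's
   `abdomen_chest` mass moves to the target.
2. **Breast series rule** (MRI only) — if ≥ 50% (inclusive) of slices are
   breast, the whole series becomes breast (one-hot vectors: the rule is a
   series-level hard decision).
3. **Outlier removal** — an interior run of length 1 whose flanking labels
   agree takes the mean of the flanking vectors (argmax-preserving when the
   flanks agree); endpoints untouched; iterated to a fixed point with a cap.
   A minimal isolated-run rule was chosen because no specific routine is
   canonical; a window-majority variant can be swapped in.
4. **Smoothing** — centred window-3 moving average of the per-class
   probability sequences, truncated at the edges, renormalized.
5. **Threshold** — slices with confidence < 0.5 are marked indeterminate and
   excluded from confusion-matrix accumulation; the boundary is inclusive
   (exactly 0.5 is kept).

## Evaluation

Confusion matrices have rows = predictions, columns = ground truth. Per-class
one-vs-rest sensitivity TP/(TP+FN), specificity TN/(TN+FP), F1 = 2PR/(P+R);
weighted aggregates use true-class supports as weights, so weighted
sensitivity equals micro-accuracy when every image is evaluated (tested as an
identity). Classes without ground-truth support are excluded from the
weighting with a warning.

Adjacent slices are nearly identical, so CIs must not treat them as
independent. Each bootstrap iteration resamples studies with replacement
(study-level resampling respects patient independence; the outer resampling
unit is a design choice of this package), keeps one randomly selected series
per study, and greedily subsamples each series from a randomly offset start so
that consecutive kept slices are at least `max(10 mm, slice thickness)` apart.
Percentile CIs (2.5/97.5 for the default 95% level) are reported; the
percentile method is the simplest defensible default and is config-switchable.
A coverage experiment (200 repeats of a known-accuracy synthetic classifier)
is part of the test suite.

Confounder association uses Pearson's chi-squared (no continuity correction)
on the image-level correct/incorrect × factor table and Cramér's V
= sqrt(χ²/(n·(min(r,c)−1))). The DICOM-tag audit counts a study as accurate
for a tag iff the mapped free-text value is among the study's image-derived
regions; unmapped or empty values are inaccurate.

## Study design

Patient-stratified splitting: per region, patient ids are shuffled (seeded)
and split at ⌊0.75·n⌋; a patient imaged in several regions is stratified by
their first-listed region and all their studies share one partition. Floor
rounding is a documented choice. The survey sample-size model returns
⌈z²(1−p)/(r²p)⌉ independent samples (43 at p = 0.90, 95% CI, 10% relative
error) times a `design_effect` — the images-per-independent-sample factor is
exposed as an explicit parameter rather than a hard-coded constant, because
correlated slices inflate the raw image count by a cohort-dependent factor.

## Synthetic phantoms

The generator's contract is *distinguishable, geometry-consistent* classes,
not anatomical realism. Each region renders as a deterministic texture — a
filled disc whose vertical position, radius and brightness encode the region,
plus a concentric ring for alternating classes — with seeded Gaussian noise
(default σ = 8 on a 0–400 intensity scale, i.e. a few percent of dynamic
range), 96 × 96 pixels, 5 mm slice spacing and thickness. Distinct vertical
positions make the classes separable even from row-mean intensity profiles; a
nearest-centroid check on noiseless phantoms (> 95% slice accuracy) is kept in
the suite as a learnability oracle. Region boundaries blend the two adjacent
textures linearly over a 10 mm transition zone to emulate the ambiguous
junction slices that dominate real misclassifications; within a chest/abdomen
transition the *training* label is the transitional class while box-derived
truth remains chest or abdomen. Study compositions cycle through 22 templates
(every single region plus four multi-region trunk exams), and acquisition
metadata (manufacturer, contrast, sequence family) is sampled from
configurable categorical distributions.

What passing tests on phantoms do **not** show: robustness to real anatomical
variability, pathology, implants, field-of-view truncation, or protocol
diversity — phantom textures are far easier than anatomy, so absolute
accuracy numbers on phantoms only validate the pipeline mechanics and the
statistical machinery, not clinical performance.

## Reproducibility and problem sizes

One global seed is fanned out via `numpy.random.SeedSequence(seed).spawn()`
to the stages (train cohort, test cohort, training, bootstrap) in a fixed
order, so any stage reruns identically in isolation. The packaged experiment
(`scripts/acceptance.py`) uses 132 training patients (≈ 200 slices per class)
and 50 held-out test studies — sizes chosen so the full run completes in a few
minutes on one CPU while every class keeps a three-digit training count; the
test suite uses smaller cohorts of the same structure.

## Known limitations

* One label per slice by design; slices genuinely containing two regions
  (shoulders in chest images) are forced to a single class.
* The transitional-merge / breast-override / outlier-replacement probability
  transformations are this package's concrete reading of series-level rules
  that are stated at label level only; labels match the stated behaviour, the
  vector semantics are documented above.
* The compact backbone is intentionally small; it is sufficient for phantom
  textures but is not a clinical-grade feature extractor.
* DICOM support covers single-frame grayscale files with standard geometry
  tags; multi-frame and exotic transfer syntaxes are logged and skipped.
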