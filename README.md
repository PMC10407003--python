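# bodyregion

Anatomical body-region classification of CT and MRI slice stacks.

PACS archives routinely mislabel what anatomy a scan covers: free-text
`BodyPartExamined` tags are unstandardized, cover only one "main" region, and
are frequently wrong — which breaks hanging protocols, comparison-study
retrieval, and automated cohort building for imaging AI. This package
implements a pixel-based alternative: a multi-class 2D classifier assigns one
of 17 (CT) or 18 (MRI) body regions — head, neck, chest, breast (MRI only),
abdomen, pelvis/hip, thigh, knee, calf, foot, shoulder, arm, elbow, forearm,
hand, and the cervical/thoracic/lumbar spine — to every axial slice, and a
series-level rule engine plus smoothing turns the per-slice labels into
consistent series- and study-level region sets.

It is aimed at imaging-informatics researchers and engineers who need the
*methodology* — ground-truth geometry, preprocessing, rule engine, evaluation
statistics — as tested, reusable components, exercised end-to-end on seedable
synthetic phantom studies rather than on any clinical corpus.

## What is implemented

* **Vocabularies & landmarks** (`bodyregion.schema`): the fixed CT/MRI class
  vocabularies, the internal transitional `abdomen_chest` class, and the
  anatomical landmark intervals delimiting each region along the patient
  cranio-caudal axis.
* **Data model & exclusion filters** (`bodyregion.imaging`): the
  patient → study → series → image hierarchy, DICOM reading/writing, and the
  inclusion criteria (axial obliquity ≤ 45°, > 8 bits stored, grayscale,
  ≥ 1000 pixels, primary axial series only), with a complete exclusion log.
* **Ground truth from thin 3D boxes** (`bodyregion.annotation`): boxes in
  patient coordinates propagate to every series sharing a frame of reference;
  half-open z-intervals and a precedence list resolve each slice to one label.
* **Preprocessing** (`bodyregion.preprocess`): per-image clip to
  mean ± 4σ, normalize by (x − mean)/(2σ), replicate to three channels,
  aspect-preserving resize with centred zero padding to 224 × 224.
* **Classifier** (`bodyregion.classifier`): a compact pooled-feature neural
  classifier trained with categorical cross-entropy under a random affine
  augmentation policy (rotation ± π/10, translation/shear ≤ 10%, scaling
  ≤ 20%, bilinear), plus the active-learning uncertainty ranking (top-k most
  uncertain studies).
* **Rule engine & smoothing** (`bodyregion.postprocess`): merge the
  transitional class into the predominant of abdomen/chest, the ≥ 50% breast
  series rule, isolated-outlier removal, window-3 moving-average smoothing,
  and the 0.5 confidence threshold.
* **Evaluation** (`bodyregion.evaluation`): confusion matrices (rows =
  predictions, columns = truth), weighted F1/sensitivity/specificity,
  spatially aware bootstrap CIs (≥ 10 mm slice spacing, one series per study
  per iteration), Cramér's V + chi-squared confounder association, and the
  DICOM-tag accuracy audit.
* **Study design** (`bodyregion.study_design`): patient-stratified 75/25
  splits and the survey sample-size model
  n = ⌈z²(1−p)/(r²p)⌉ × design effect.
* **Synthetic phantoms** (`bodyregion.synthetic`) and **orchestration**
  (`bodyregion.pipeline`, `bodyregion.cli`).

## Worked example

`examples/03_train_and_postprocess.py` trains the compact classifier on a
22-patient 18-class phantom cohort and classifies a held-out chest+abdomen
study:

```
trained on 770 slices; cross-entropy per epoch:
  1.686 0.564 0.401 0.365 0.330 0.254 0.244 0.232
per-slice accuracy raw 0.975 -> post-processed 0.975
post-processed labels (caudal -> cranial):
  abdomen abdomen ... abdomen chest chest ... chest
```

The loss falls as the network learns the region textures; the post-processed
label sequence changes class exactly once, at the thoraco-abdominal junction —
the transitional `abdomen_chest` predictions were merged into the predominant
neighbour and isolated flips removed. `examples/04_spatial_bootstrap_evaluation.py`
adds the spatially aware bootstrap:

```
evaluated images: 769 (indeterminate below 0.5: 1)
weighted_sensitivity: 99.7%  (95% CI 99.2-100.0)
weighted_f1: 99.7%  (95% CI 99.2-100.0)
weighted_specificity: 100.0%  (95% CI 99.8-100.0)
```

The CI resamples studies (not slices), picks one series per study per
iteration, and enforces 10 mm minimum slice spacing, so it reflects the number
of effectively independent images rather than the raw slice count.

A thin CLI mirrors the library: `bodyregion simulate|split|train|infer|
evaluate|audit-tags|end-to-end` (see `bodyregion --help`).

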