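"""Uncertainty ranking, ground-truth audit arithmetic, and the DICOM-tag audit.

Three smaller capabilities around the classifier: selecting the most
uncertain studies for annotation, quantifying inter-reader label consistency,
and measuring how unreliable free-text DICOM body-part tags are.
"""

import numpy as np

from bodyregion import audit_labels, rank_uncertain
from bodyregion.evaluation import audit_dicom_tags
from bodyregion.postprocess import PredictionSequence, SlicePrediction


def fake_sequence(confidence, n=10):
    p = np.full(4, (1 - confidence) / 3)
    p[0] = confidence
    entries = [(float(i), SlicePrediction(probabilities=p)) for i in range(n)]
    return PredictionSequence(entries=entries, class_names=("a", "b", "c", "d"))


# Active learning: studies the model is least sure about rank first.
studies = {"confident": [fake_sequence(0.95)],
           "borderline": [fake_sequence(0.55)],
           "confused": [fake_sequence(0.30)]}
print("annotation queue:", rank_uncertain(studies, k=2))

# Ground-truth audit: a second reader reviews and the discrepancy rate is reported.
truth_a = {f"s{i}": "head" for i in range(1455)}
truth_b = dict(truth_a, **{f"s{i}": "neck" for i in range(4)})
report = audit_labels(truth_a, truth_b)
print(f"audit: {report.n_discrepant}/{report.n_reviewed} discrepant = {report.error_rate}%")

# Tag audit: free-text body-part tags vs image-derived study regions.
tags = {"BodyPartExamined": {"s1": "CHEST", "s2": "", "s3": "ABDOMEN", "s4": "HEAD"}}
truth = {"s1": {"chest", "abdomen"}, "s2": {"knee"}, "s3": {"pelvis_hip"}, "s4": {"head"}}
print("tag accuracy:", audit_dicom_tags(tags, truth))
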