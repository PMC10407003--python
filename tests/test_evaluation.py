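import numpy as np
import pytest

from bodyregion.evaluation import (
    BootstrapConfig,
    ConfusionMatrix,
    accumulate_confusion,
    association,
    audit_dicom_tags,
    bootstrap_ci,
    compute_metrics,
    spatial_sample,
)
from bodyregion.postprocess import PredictionSequence, SlicePrediction

NAMES = ("head", "neck", "chest")


def onehot_seq(pred_labels, uids=None, zs=None, indeterminate=None, names=NAMES, series_uid="se"):
    uids = uids or [f"im{i}" for i in range(len(pred_labels))]
    zs = zs or [float(10 * i) for i in range(len(pred_labels))]
    flags = indeterminate or [False] * len(pred_labels)
    entries = []
    for label, uid, z, flag in zip(pred_labels, uids, zs, flags):
        p = np.zeros(len(names))
        p[names.index(label)] = 1.0
        entries.append((z, SlicePrediction(probabilities=p, image_uid=uid, indeterminate=flag)))
    return PredictionSequence(entries=entries, class_names=names, series_uid=series_uid)


class TestAccumulate:
    def test_perfect_predictions_are_diagonal(self):
        seq = onehot_seq(["head", "neck", "chest"])
        truth = {"im0": "head", "im1": "neck", "im2": "chest"}
        cm = accumulate_confusion([seq], truth, NAMES)
        assert np.array_equal(cm.counts, np.eye(3, dtype=int))

    def test_all_indeterminate_gives_zero_matrix(self):
        seq = onehot_seq(["head", "neck"], indeterminate=[True, True])
        cm = accumulate_confusion([seq], {"im0": "head", "im1": "neck"}, NAMES)
        assert cm.total == 0

    def test_hand_tallied_counts(self):
        # 2 correct heads, 1 neck predicted as head
        seq = onehot_seq(["head", "head", "head"])
        truth = {"im0": "head", "im1": "head", "im2": "neck"}
        cm = accumulate_confusion([seq], truth, ("head", "neck"))
        assert cm.counts.tolist() == [[2, 1], [0, 0]]

    def test_label_outside_vocabulary_rejected(self):
        seq = onehot_seq(["head"])
        with pytest.raises(ValueError, match="outside vocabulary"):
            accumulate_confusion([seq], {"im0": "toe"}, NAMES)

    def test_rows_are_predictions_columns_truth(self):
        seq = onehot_seq(["neck"])
        cm = accumulate_confusion([seq], {"im0": "head"}, NAMES)
        assert cm.counts[NAMES.index("neck"), NAMES.index("head")] == 1


class TestMetrics:
    def test_two_class_hand_arithmetic(self):
        # rows = predictions: sens A = 8/10 = 0.8, sens B = 9/10 = 0.9,
        # equal supports so weighted = 0.85
        cm = ConfusionMatrix(np.array([[8, 1], [2, 9]]), ("A", "B"))
        report = compute_metrics(cm)
        assert report.per_class["A"].sensitivity == pytest.approx(0.8)
        assert report.per_class["B"].sensitivity == pytest.approx(0.9)
        assert report.weighted_sensitivity == pytest.approx(0.85)

    def test_diagonal_matrix_all_metrics_one(self):
        cm = ConfusionMatrix(np.diag([5, 3, 2]), NAMES)
        report = compute_metrics(cm)
        assert report.weighted_f1 == pytest.approx(1.0)
        assert report.weighted_sensitivity == pytest.approx(1.0)
        assert report.weighted_specificity == pytest.approx(1.0)

    def test_class_entirely_missed_has_zero_sensitivity(self):
        cm = ConfusionMatrix(np.array([[5, 3], [0, 0]]), ("A", "B"))
        assert compute_metrics(cm).per_class["B"].sensitivity == 0.0

    def test_unsupported_class_excluded_with_warning(self, caplog):
        cm = ConfusionMatrix(np.array([[5, 0], [1, 0]]), ("A", "B"))
        with caplog.at_level("WARNING"):
            report = compute_metrics(cm)
        assert "B" not in report.per_class

    def test_matches_brute_force_tally_on_random_matrices(self):
        """Independent oracle: expand the matrix to (pred, true) pairs and tally."""
        rng = np.random.default_rng(0)
        for _ in range(1000):
            k = int(rng.integers(2, 5))
            counts = rng.integers(0, 6, size=(k, k))
            if counts.sum(axis=0).min() == 0:  # ensure every class has support
                counts[rng.integers(k), :] += 1
                np.fill_diagonal(counts, counts.diagonal() + 1)
            cm = ConfusionMatrix(counts, tuple(f"c{i}" for i in range(k)))
            report = compute_metrics(cm)
            pairs = [
                (i, j) for i in range(k) for j in range(k) for _ in range(counts[i, j])
            ]
            n = len(pairs)
            w_sens = w_spec = w_f1 = 0.0
            for c in range(k):
                support = sum(1 for _, t in pairs if t == c)
                tp = sum(1 for p, t in pairs if p == c and t == c)
                fp = sum(1 for p, t in pairs if p == c and t != c)
                fn = support - tp
                tn = n - tp - fp - fn
                sens = tp / support
                prec = tp / (tp + fp) if tp + fp else 0.0
                f1 = 2 * prec * sens / (prec + sens) if prec + sens else 0.0
                spec = tn / (tn + fp)
                w_sens += support / n * sens
                w_spec += support / n * spec
                w_f1 += support / n * f1
            assert report.weighted_sensitivity == pytest.approx(w_sens)
            assert report.weighted_specificity == pytest.approx(w_spec)
            assert report.weighted_f1 == pytest.approx(w_f1)

    def test_weighted_sensitivity_equals_micro_accuracy(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            k = int(rng.integers(2, 6))
            counts = rng.integers(1, 10, size=(k, k))
            cm = ConfusionMatrix(counts, tuple(f"c{i}" for i in range(k)))
            micro = counts.diagonal().sum() / counts.sum()
            assert compute_metrics(cm).weighted_sensitivity == pytest.approx(micro)

    def test_agrees_with_sklearn_weighted_recall(self):
        from sklearn.metrics import recall_score

        rng = np.random.default_rng(2)
        y_true = rng.integers(0, 3, 200)
        y_pred = np.where(rng.random(200) < 0.8, y_true, rng.integers(0, 3, 200))
        counts = np.zeros((3, 3), dtype=int)
        np.add.at(counts, (y_pred, y_true), 1)
        report = compute_metrics(ConfusionMatrix(counts, NAMES))
        assert report.weighted_sensitivity == pytest.approx(
            recall_score(y_true, y_pred, average="weighted")
        )


class TestSpatialSample:
    def test_greedy_keeps_every_other_5mm_slice(self):
        # zero-offset stub makes the greedy scan deterministic
        kept = spatial_sample([0, 5, 10, 15, 20], 10.0, _FixedRng(0.0))
        assert kept.tolist() == [0, 2, 4]

    def test_slices_12mm_apart_all_kept(self):
        kept = spatial_sample([0, 12, 24, 36], 10.0, _FixedRng(0.0))
        assert kept.tolist() == [0, 1, 2, 3]

    def test_single_slice_kept(self):
        kept = spatial_sample([5.0], 10.0, np.random.default_rng(0))
        assert kept.tolist() == [0]

    def test_slice_thickness_raises_effective_gap(self):
        kept = spatial_sample([0, 10, 20], 10.0, _FixedRng(0.0), slice_thickness=15.0)
        assert kept.tolist() == [0, 2]  # 15 mm thick slices need >= 15 mm spacing

    def test_pairwise_spacing_property_over_random_series(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            n = int(rng.integers(1, 60))
            z = np.sort(rng.uniform(0, 300, n))
            kept = spatial_sample(z, 10.0, rng)
            kz = z[kept]
            if len(kz) > 1:
                assert np.diff(kz).min() >= 10.0

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError):
            spatial_sample([10, 0], 10.0, np.random.default_rng(0))


class _FixedRng:
    """Minimal stand-in generator returning a fixed uniform draw (synthetic test stub)."""

    def __init__(self, value: float):
        self.value = value

    def uniform(self, lo, hi):
        return self.value


class TestBootstrap:
    def _cohort(self, rng, n_studies=10, n_slices=12, accuracy=0.9):
        studies, truth = [], {}
        for s in range(n_studies):
            labels, uids = [], []
            for i in range(n_slices):
                uid = f"s{s}-im{i}"
                ti = int(rng.integers(3))
                true = NAMES[ti]
                pred = true if rng.random() < accuracy else NAMES[(ti + 1 + int(rng.integers(2))) % 3]
                truth[uid] = true
                labels.append(pred)
                uids.append(uid)
            studies.append([onehot_seq(labels, uids=uids, series_uid=f"se{s}")])
        return studies, truth

    def test_perfect_classifier_ci_is_unity(self):
        rng = np.random.default_rng(0)
        studies, truth = self._cohort(rng, accuracy=2.0)  # always correct
        report = bootstrap_ci(studies, truth, NAMES, BootstrapConfig(n_iterations=50, seed=1))
        lo, hi = report.cis["weighted_sensitivity"]
        assert lo == pytest.approx(1.0) and hi == pytest.approx(1.0)

    def test_same_seed_identical_bounds(self):
        rng = np.random.default_rng(1)
        studies, truth = self._cohort(rng)
        cfg = BootstrapConfig(n_iterations=50, seed=7)
        a = bootstrap_ci(studies, truth, NAMES, cfg)
        b = bootstrap_ci(studies, truth, NAMES, cfg)
        assert a.cis == b.cis

    def test_too_few_iterations_rejected(self):
        rng = np.random.default_rng(2)
        studies, truth = self._cohort(rng, n_studies=3)
        with pytest.raises(ValueError):
            bootstrap_ci(studies, truth, NAMES, BootstrapConfig(n_iterations=5))

    def test_ci_width_shrinks_with_cohort_size(self):
        rng = np.random.default_rng(3)
        widths = []
        for n in (8, 64):
            studies, truth = self._cohort(np.random.default_rng(42), n_studies=n)
            rep = bootstrap_ci(studies, truth, NAMES, BootstrapConfig(n_iterations=200, seed=5))
            lo, hi = rep.cis["weighted_sensitivity"]
            widths.append(hi - lo)
        assert widths[1] < widths[0]


class TestAssociation:
    def test_perfectly_associated_table_v_is_one(self):
        flags = [True] * 10 + [False] * 10
        levels = ["x"] * 10 + ["y"] * 10
        res = association(flags, levels)
        assert res.cramers_v == pytest.approx(1.0)

    def test_proportional_table_v_is_zero(self):
        flags = [True, False] * 20
        levels = (["x", "x"] * 10) + (["y", "y"] * 10)
        res = association(flags, levels)
        assert res.chi2 == pytest.approx(0.0)
        assert res.cramers_v == pytest.approx(0.0)

    def test_textbook_2x2_against_brute_force_oracle(self):
        # table [[30, 10], [20, 20]]: chi2 from first principles
        flags = [True] * 30 + [False] * 10 + [True] * 20 + [False] * 20
        levels = ["x"] * 40 + ["y"] * 40
        observed = np.array([[30.0, 20.0], [10.0, 20.0]])  # correct x/y; incorrect x/y
        row = observed.sum(axis=1, keepdims=True)
        col = observed.sum(axis=0, keepdims=True)
        expected = row @ col / observed.sum()
        chi2_oracle = float(((observed - expected) ** 2 / expected).sum())
        res = association(flags, levels)
        assert res.chi2 == pytest.approx(chi2_oracle)
        assert res.cramers_v == pytest.approx(np.sqrt(chi2_oracle / 80))

    def test_degenerate_table_rejected(self):
        with pytest.raises(ValueError):
            association([True, True], ["x", "x"])


class TestTagAudit:
    def test_mapped_tag_in_truth_set_is_accurate(self):
        acc = audit_dicom_tags(
            {"BodyPartExamined": {"st0": "CHEST"}},
            {"st0": {"chest", "abdomen"}},
        )
        assert acc["BodyPartExamined"] == 100.0

    def test_empty_tag_inaccurate(self):
        acc = audit_dicom_tags({"BodyPartExamined": {"st0": ""}}, {"st0": {"chest"}})
        assert acc["BodyPartExamined"] == 0.0

    def test_three_of_four_accurate_is_75_percent(self):
        tags = {"PT": {"s1": "HEAD", "s2": "NECK", "s3": "KNEE", "s4": "ELBOW"}}
        truth = {"s1": {"head"}, "s2": {"neck"}, "s3": {"knee"}, "s4": {"forearm"}}
        assert audit_dicom_tags(tags, truth) == {"PT": 75.0}

    def test_unmapped_value_inaccurate(self):
        acc = audit_dicom_tags({"BP": {"s1": "GARBLED"}}, {"s1": {"head"}})
        assert acc["BP"] == 0.0
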