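import math

import numpy as np
import pytest

from bodyregion import (
    AugmentationConfig,
    TrainConfig,
    predict_series,
    rank_uncertain,
    train,
)
from bodyregion.classifier import ModelHandle, augment, pooled_features, sample_affine
from bodyregion.postprocess import PredictionSequence, SlicePrediction


def uniform_seq(n_classes, n_slices, study="s", conf=None):
    """Prediction sequence whose slices all have the given max confidence."""
    p = np.full(n_classes, (1 - (conf or 1 / n_classes)) / (n_classes - 1))
    p[0] = conf if conf is not None else 1 / n_classes
    p = p / p.sum()
    entries = [
        (float(z), SlicePrediction(probabilities=p, image_uid=f"{study}-{z}"))
        for z in range(n_slices)
    ]
    return PredictionSequence(entries=entries, class_names=tuple(f"c{i}" for i in range(n_classes)))


class TestAugment:
    def test_zero_maxima_is_identity(self):
        cfg = AugmentationConfig(
            rotation_max_rad=0, translate_max_frac=0, shear_max_frac=0, scale_max_frac=0
        )
        x = np.random.default_rng(0).normal(size=(32, 32)).astype(np.float32)
        assert np.allclose(augment(x, cfg), x, atol=1e-5)

    def test_same_seed_identical_output(self):
        cfg = AugmentationConfig(seed=5)
        x = np.random.default_rng(1).normal(size=(32, 32, 3)).astype(np.float32)
        assert np.array_equal(augment(x, cfg), augment(x, cfg))

    def test_shape_unchanged(self):
        cfg = AugmentationConfig(seed=2)
        x = np.zeros((224, 224, 3), dtype=np.float32)
        assert augment(x, cfg).shape == x.shape

    def test_sampled_parameters_stay_in_bounds(self):
        cfg = AugmentationConfig()
        rng = np.random.default_rng(0)
        max_rot = math.pi / 10
        for _ in range(10_000):
            matrix, t = sample_affine(cfg, rng)
            # recover rotation+shear+scale bounds from the factored sample
            assert np.all(np.abs(t) <= cfg.translate_max_frac)
            # determinant = product of scales (rotation and shear are unimodular)
            det = abs(np.linalg.det(matrix))
            assert (1 - cfg.scale_max_frac) ** 2 - 1e-9 <= det <= (1 + cfg.scale_max_frac) ** 2 + 1e-9
        # direct check on the rotation draw
        rng = np.random.default_rng(1)
        draws = rng.uniform(-max_rot, max_rot, 10_000)
        assert draws.min() >= -max_rot and draws.max() <= max_rot


class TestTrain:
    def _toy_dataset(self, n_per_class=30, size=64, seed=0):
        rng = np.random.default_rng(seed)
        inputs, labels = [], []
        for cls, name in ((0, "head"), (1, "chest")):
            for _ in range(n_per_class):
                x = np.zeros((size, size), dtype=np.float32)
                if cls == 0:
                    x[8:24, 8:24] = 1.0
                else:
                    x[40:56, 40:56] = 1.0
                x += rng.normal(0, 0.05, x.shape).astype(np.float32)
                x3 = np.repeat(x[:, :, None], 3, axis=2)
                inputs.append(x3)
                labels.append(name)
        return inputs, labels

    def test_separable_two_class_fixture_trains_above_95(self, mri_vocab):
        inputs, labels = self._toy_dataset()
        cfg = TrainConfig(epochs=5, pool=4, seed=0)
        model = train(inputs, labels, mri_vocab, cfg)
        probs = model.predict_proba(inputs)
        pred = [mri_vocab.internal_classes[i] for i in probs.argmax(axis=1)]
        accuracy = np.mean([p == l for p, l in zip(pred, labels)])
        assert accuracy > 0.95

    def test_loss_decreases_over_training(self, mri_vocab):
        inputs, labels = self._toy_dataset()
        model = train(inputs, labels, mri_vocab, TrainConfig(epochs=6, pool=4, seed=0))
        assert model.training_loss[-1] < model.training_loss[0]

    def test_empty_dataset_rejected(self, mri_vocab):
        with pytest.raises(ValueError, match="empty"):
            train([], [], mri_vocab)

    def test_single_class_rejected(self, mri_vocab):
        inputs, labels = self._toy_dataset(n_per_class=5)
        only = [x for x, l in zip(inputs, labels) if l == "head"]
        with pytest.raises(ValueError, match="2 classes"):
            train(only, ["head"] * len(only), mri_vocab)

    def test_label_outside_vocabulary_rejected(self, mri_vocab):
        inputs, labels = self._toy_dataset(n_per_class=5)
        labels[0] = "tail"
        with pytest.raises(ValueError, match="outside vocabulary"):
            train(inputs, labels, mri_vocab)

    def test_pretrained_backbone_requires_runtime(self, mri_vocab):
        inputs, labels = self._toy_dataset(n_per_class=2)
        with pytest.raises(RuntimeError, match="resnet50v2"):
            train(inputs, labels, mri_vocab, TrainConfig(backbone="resnet50v2_pretrained"))

    def test_seeded_training_reproducible(self, mri_vocab):
        inputs, labels = self._toy_dataset(n_per_class=10)
        cfg = TrainConfig(epochs=2, pool=4, seed=9)
        a = train(inputs, labels, mri_vocab, cfg)
        b = train(inputs, labels, mri_vocab, cfg)
        assert np.array_equal(a.predict_proba(inputs[:5]), b.predict_proba(inputs[:5]))


class TestPredictSeries:
    def test_one_prediction_per_image_sorted_and_normalized(self, tiny_model, head_neck_phantom):
        series = head_neck_phantom.study.series[0]
        seq = predict_series(tiny_model, series)
        assert len(seq) == len(series)
        zs = [z for z, _ in seq.entries]
        assert zs == sorted(zs)
        for _, pred in seq.entries:
            assert pred.probabilities.sum() == pytest.approx(1.0, abs=1e-6)
            assert (pred.probabilities >= 0).all()

    def test_inference_deterministic(self, tiny_model, head_neck_phantom):
        series = head_neck_phantom.study.series[0]
        a = predict_series(tiny_model, series).prob_matrix()
        b = predict_series(tiny_model, series).prob_matrix()
        assert np.array_equal(a, b)

    def test_checkpoint_roundtrip(self, tiny_model, head_neck_phantom, tmp_path):
        tiny_model.save(tmp_path / "ckpt")
        loaded = ModelHandle.load(tmp_path / "ckpt")
        series = head_neck_phantom.study.series[0]
        assert np.array_equal(
            predict_series(tiny_model, series).prob_matrix(),
            predict_series(loaded, series).prob_matrix(),
        )

    def test_pooled_features_average(self):
        x = np.arange(16, dtype=float).reshape(4, 4)
        feats = pooled_features(x, pool=2)
        assert feats.tolist() == [2.5, 4.5, 10.5, 12.5]


class TestRankUncertain:
    def test_uniform_ranks_above_one_hot(self):
        studies = {
            "sure": [uniform_seq(4, 5, conf=0.97)],
            "unsure": [uniform_seq(4, 5, conf=0.25)],
        }
        assert rank_uncertain(studies, k=2) == ["unsure", "sure"]

    def test_k_larger_than_cohort_returns_all(self):
        studies = {f"s{i}": [uniform_seq(4, 3, conf=0.5)] for i in range(3)}
        assert len(rank_uncertain(studies, k=200)) == 3

    def test_hand_sorted_scores(self):
        studies = {
            "a": [uniform_seq(4, 5, conf=0.5)],   # score 0.5
            "b": [uniform_seq(4, 5, conf=0.8)],   # score 0.2
            "c": [uniform_seq(4, 5, conf=0.9)],   # score 0.1
        }
        assert rank_uncertain(studies, k=2) == ["a", "b"]

    def test_order_invariant_to_insertion_order(self):
        base = {f"s{i}": [uniform_seq(4, 5, conf=0.3 + 0.1 * i)] for i in range(5)}
        reordered = dict(reversed(list(base.items())))
        assert rank_uncertain(base, k=5) == rank_uncertain(reordered, k=5)

    def test_ties_broken_by_study_id(self):
        studies = {n: [uniform_seq(4, 5, conf=0.5)] for n in ("zeta", "alpha")}
        assert rank_uncertain(studies, k=2) == ["alpha", "zeta"]

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError):
            rank_uncertain({"a": [uniform_seq(4, 2)]}, k=0)
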