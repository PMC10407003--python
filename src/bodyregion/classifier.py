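"""Multi-class 2D slice classifier, augmentation policy, and uncertainty ranking.

Two backbones are exposed behind one training interface:

* ``compact`` — the desk-scale default: a fixed uniform average-pooling
  convolution (stride = kernel, default 8, so a 224×224 input becomes a 28×28
  feature map) followed by a small fully connected network with a softmax head
  trained on categorical cross-entropy (scikit-learn ``MLPClassifier`` with
  log-loss).  Fast enough to train on a laptop CPU in minutes.
* ``resnet50v2_pretrained`` — a transfer-learning adapter around an
  ImageNet-pretrained ResNet50V2; it requires a deep-learning runtime with
  published weights and raises a clear error when none is importable.

Training augments each image independently per epoch with random affine
deformations: rotation within ±π/10, translation and shear up to 10% of the
image size, scaling up to 20% in both directions, bilinear resampling.
"""

from __future__ import annotations

import json
import math
import pickle
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Optional, Sequence

import numpy as np
from pydantic import BaseModel, field_validator
from scipy import ndimage
from sklearn.neural_network import MLPClassifier

from .imaging import Series
from .postprocess import PredictionSequence, SlicePrediction
from .preprocess import preprocess_image
from .schema import RegionVocabulary

PREPROCESSING_VERSION = "clip4sd-norm2sd-3ch-pad224/v1"


class AugmentationConfig(BaseModel):
    """Random affine deformation policy applied during training."""

    rotation_max_rad: float = math.pi / 10
    translate_max_frac: float = 0.10
    shear_max_frac: float = 0.10
    scale_max_frac: float = 0.20
    interpolation_order: int = 1  # bilinear
    apply_prob: float = 0.5
    seed: int = 0

    @field_validator("translate_max_frac", "shear_max_frac", "scale_max_frac", "apply_prob")
    @classmethod
    def _frac(cls, v):
        if not 0 <= v <= 1:
            raise ValueError("fractions must be in [0, 1]")
        return v

    @field_validator("rotation_max_rad")
    @classmethod
    def _rot(cls, v):
        if not 0 <= v <= math.pi:
            raise ValueError("rotation_max_rad must be in [0, pi]")
        return v


def sample_affine(cfg: AugmentationConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Sample a forward affine map (matrix, translation) within the policy bounds."""
    theta = rng.uniform(-cfg.rotation_max_rad, cfg.rotation_max_rad)
    shear_x = rng.uniform(-cfg.shear_max_frac, cfg.shear_max_frac)
    shear_y = rng.uniform(-cfg.shear_max_frac, cfg.shear_max_frac)
    scale_r = 1.0 + rng.uniform(-cfg.scale_max_frac, cfg.scale_max_frac)
    scale_c = 1.0 + rng.uniform(-cfg.scale_max_frac, cfg.scale_max_frac)
    rot = np.array([[math.cos(theta), -math.sin(theta)], [math.sin(theta), math.cos(theta)]])
    shear = np.array([[1.0, shear_y], [shear_x, 1.0]])
    scale = np.diag([scale_r, scale_c])
    matrix = rot @ shear @ scale
    return matrix, np.array(
        [rng.uniform(-cfg.translate_max_frac, cfg.translate_max_frac),
         rng.uniform(-cfg.translate_max_frac, cfg.translate_max_frac)]
    )


def augment(
    model_input: np.ndarray,
    cfg: AugmentationConfig,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Apply one random affine deformation; shape and label are unchanged.

    With no explicit generator the config seed is used, so two calls with the
    same seed produce identical output.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    arr = np.asarray(model_input, dtype=np.float32)
    single = arr.ndim == 2
    plane = arr if single else arr[:, :, 0]
    h, w = plane.shape
    matrix, t_frac = sample_affine(cfg, rng)
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    translation = t_frac * np.array([h, w])
    inv = np.linalg.inv(matrix)
    offset = center - inv @ (center + translation)
    out_plane = ndimage.affine_transform(
        plane, inv, offset=offset, order=cfg.interpolation_order,
        mode="constant", cval=0.0, output=np.float32,
    )
    if single:
        return out_plane
    return np.repeat(out_plane[:, :, None], arr.shape[2], axis=2)


class TrainConfig(BaseModel):
    """Training configuration; loss is fixed to categorical cross-entropy."""

    backbone: Literal["compact", "resnet50v2_pretrained"] = "compact"
    epochs: int = 10
    batch_size: int = 32
    learning_rate: float = 1e-3
    hidden_units: tuple[int, ...] = (128,)
    pool: int = 8  # average-pooling kernel/stride of the compact backbone
    augmentation: AugmentationConfig = AugmentationConfig()
    seed: int = 0

    @field_validator("epochs", "batch_size", "pool")
    @classmethod
    def _pos(cls, v):
        if v < 1:
            raise ValueError("must be >= 1")
        return v


def pooled_features(model_input: np.ndarray, pool: int = 8) -> np.ndarray:
    """Compact-backbone feature stage: uniform average pooling of channel 0, flattened."""
    plane = np.asarray(model_input)
    if plane.ndim == 3:
        plane = plane[:, :, 0]
    h, w = plane.shape
    h2, w2 = (h // pool) * pool, (w // pool) * pool
    pooled = plane[:h2, :w2].reshape(h2 // pool, pool, w2 // pool, pool).mean(axis=(1, 3))
    return pooled.ravel().astype(np.float32)


@dataclass
class ModelHandle:
    """Trained classifier: backbone config, fitted head, vocabulary, history."""

    vocabulary: RegionVocabulary
    mlp: MLPClassifier
    pool: int
    training_loss: list[float] = field(default_factory=list)
    preprocessing_version: str = PREPROCESSING_VERSION

    def predict_proba(self, model_inputs: Sequence[np.ndarray]) -> np.ndarray:
        """Class-probability matrix (n, K) over the internal classes; rows sum to 1."""
        if len(model_inputs) == 0:
            return np.zeros((0, len(self.vocabulary.internal_classes)))
        feats = np.stack([pooled_features(x, self.pool) for x in model_inputs])
        return self.mlp.predict_proba(feats)

    def save(self, directory: "str | Path") -> None:
        """Checkpoint directory: pickled weights + vocabulary JSON + preprocessing tag."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        with open(d / "model.pkl", "wb") as fh:
            pickle.dump({"mlp": self.mlp, "pool": self.pool, "loss": self.training_loss}, fh)
        (d / "vocabulary.json").write_text(self.vocabulary.to_json())
        (d / "preprocessing.json").write_text(
            json.dumps({"version": self.preprocessing_version})
        )

    @classmethod
    def load(cls, directory: "str | Path") -> "ModelHandle":
        from .schema import build_vocabulary

        d = Path(directory)
        with open(d / "model.pkl", "rb") as fh:
            payload = pickle.load(fh)
        vocab_meta = json.loads((d / "vocabulary.json").read_text())
        version = json.loads((d / "preprocessing.json").read_text())["version"]
        return cls(
            vocabulary=build_vocabulary(vocab_meta["modality"]),
            mlp=payload["mlp"],
            pool=payload["pool"],
            training_loss=payload["loss"],
            preprocessing_version=version,
        )


def train(
    inputs: Sequence[np.ndarray],
    labels: Sequence[str],
    vocabulary: RegionVocabulary,
    cfg: Optional[TrainConfig] = None,
) -> ModelHandle:
    """Train the slice classifier on preprocessed model inputs.

    ``inputs`` are chain outputs (224×224×3); ``labels`` are internal class
    names.  Each epoch independently augments a random subset of the images
    (probability ``apply_prob`` per image) before one pass of minibatch
    cross-entropy optimization.  Seeded runs are reproducible.
    """
    cfg = cfg or TrainConfig()
    if cfg.backbone == "resnet50v2_pretrained":
        raise RuntimeError(
            "the resnet50v2_pretrained backbone requires a deep-learning runtime "
            "with published ImageNet weights (e.g. tensorflow.keras); install one "
            "and use the adapter, or use the 'compact' backbone"
        )
    if len(inputs) == 0:
        raise ValueError("empty training dataset")
    classes = set(labels)
    if len(classes) < 2:
        raise ValueError("training requires at least 2 classes")
    unknown = classes - set(vocabulary.internal_classes)
    if unknown:
        raise ValueError(f"labels outside vocabulary: {sorted(unknown)}")

    class_index = {name: i for i, name in enumerate(vocabulary.internal_classes)}
    y = np.array([class_index[l] for l in labels])
    all_classes = np.arange(len(vocabulary.internal_classes))
    rng = np.random.default_rng(cfg.seed)

    mlp = MLPClassifier(
        hidden_layer_sizes=cfg.hidden_units,
        solver="adam",
        learning_rate_init=cfg.learning_rate,
        batch_size=cfg.batch_size,
        random_state=cfg.seed,
    )
    base_feats = np.stack([pooled_features(x, cfg.pool) for x in inputs])
    history: list[float] = []
    for _ in range(cfg.epochs):
        feats = base_feats.copy()
        aug_mask = rng.random(len(inputs)) < cfg.augmentation.apply_prob
        for i in np.flatnonzero(aug_mask):
            feats[i] = pooled_features(augment(inputs[i], cfg.augmentation, rng), cfg.pool)
        order = rng.permutation(len(inputs))
        mlp.partial_fit(feats[order], y[order], classes=all_classes)
        history.append(float(mlp.loss_))
    return ModelHandle(vocabulary=vocabulary, mlp=mlp, pool=cfg.pool, training_loss=history)


def predict_series(model: ModelHandle, series: Series) -> PredictionSequence:
    """One prediction per retained image, ordered by slice position."""
    images = sorted(series.images, key=lambda im: im.z_position)
    inputs = [preprocess_image(im.pixels) for im in images]
    probs = model.predict_proba(inputs)
    entries = [
        (im.z_position, SlicePrediction(probabilities=p, image_uid=im.image_uid))
        for im, p in zip(images, probs)
    ]
    return PredictionSequence(
        entries=entries,
        modality=series.modality,
        class_names=model.vocabulary.internal_classes,
        series_uid=series.series_uid,
    )


def uncertainty_score(seq: PredictionSequence, method: str = "confidence") -> float:
    """Per-study ingredient of active learning: mean slice uncertainty.

    ``confidence`` scores 1 − max probability per slice; ``entropy`` uses the
    normalized Shannon entropy of the probability vector.
    """
    scores = []
    for _, pred in seq.entries:
        p = pred.probabilities
        if method == "confidence":
            scores.append(1.0 - float(p.max()))
        elif method == "entropy":
            nz = p[p > 0]
            scores.append(float(-(nz * np.log(nz)).sum() / math.log(len(p))))
        else:
            raise ValueError(f"unknown uncertainty method {method!r}")
    return float(np.mean(scores)) if scores else 0.0


def rank_uncertain(
    studies: Mapping[str, Sequence[PredictionSequence]],
    k: int = 200,
    method: str = "confidence",
) -> list[str]:
    """Top-k most uncertain studies for annotation enrichment.

    The study score is the mean over all its images of the per-slice
    uncertainty; ties are broken by study id; returns min(k, n) ids in
    descending score order.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    scored = []
    for study_id, seqs in studies.items():
        if not any(seq.entries for seq in seqs):
            raise ValueError(f"study {study_id} has no predictions")
        per_image = [
            1.0 - float(pred.probabilities.max())
            if method == "confidence"
            else uncertainty_score(
                PredictionSequence(
                    entries=[(z, pred)], modality=seqs[0].modality,
                    class_names=seqs[0].class_names,
                ),
                method,
            )
            for seq in seqs
            for z, pred in seq.entries
        ]
        scored.append((float(np.mean(per_image)), study_id))
    scored.sort(key=lambda t: (-t[0], t[1]))
    return [sid for _, sid in scored[:k]]
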