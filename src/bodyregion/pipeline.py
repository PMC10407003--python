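"""End-to-end orchestration: simulate → filter → annotate → train → infer → evaluate.

One global seed is fanned out to every stochastic stage through
``numpy.random.SeedSequence(seed).spawn()`` children taken in a fixed,
documented order (train cohort, test cohort, training, bootstrap), so any
stage can be rerun in isolation reproducibly.  Every artifact directory
receives the resolved configuration and a version tag; two runs with
identical configs produce identical reports.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
from pydantic import BaseModel, Field

from . import __version__
from .classifier import ModelHandle, TrainConfig, predict_series, train
from .evaluation import (
    BootstrapConfig,
    ConfusionMatrix,
    MetricReport,
    accumulate_confusion,
    bootstrap_ci,
    compute_metrics,
    write_report,
)
from .imaging import FilterConfig, filter_images, filter_series
from .postprocess import PostprocessConfig, PredictionSequence, postprocess_series
from .preprocess import preprocess_image
from .schema import Modality, build_vocabulary
from .synthetic import PhantomStudy, default_compositions, generate_cohort

logger = logging.getLogger(__name__)

_STAGES = ("train_cohort", "test_cohort", "training", "bootstrap")


class PipelineError(RuntimeError):
    """Raised when a stage fails; carries the stage name for context."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


def stage_seeds(seed: int) -> dict[str, int]:
    """Derive one sub-seed (< 2^31) per stochastic stage, in a fixed order."""
    children = np.random.SeedSequence(seed).spawn(len(_STAGES))
    return {
        name: int(child.generate_state(1)[0] % (2**31 - 1))
        for name, child in zip(_STAGES, children)
    }


class RunConfig(BaseModel):
    """Resolved configuration of one end-to-end synthetic run."""

    modality: Modality = Modality.MRI
    n_train_patients: int = 44
    n_test_patients: int = 22
    # phantom geometry/noise, forwarded to the generator
    slice_spacing_mm: float = 5.0
    slice_thickness_mm: float = 5.0
    image_size: int = 96
    noise_sd: float = 8.0
    transition_zone_mm: float = 10.0
    n_series: int = 1
    filter: FilterConfig = Field(default_factory=FilterConfig)
    train: TrainConfig = Field(default_factory=TrainConfig)
    postprocess: PostprocessConfig = Field(default_factory=PostprocessConfig)
    bootstrap: Optional[BootstrapConfig] = None
    seed: int = 0


@dataclass
class EvaluationReport:
    """Everything the evaluation computes for one run."""

    confusion: ConfusionMatrix
    metrics: MetricReport
    n_indeterminate: int
    study_regions: dict[str, set[str]]
    training_loss: list[float] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "metrics": self.metrics.to_dict(),
            "n_indeterminate": self.n_indeterminate,
            "study_regions": {k: sorted(v) for k, v in self.study_regions.items()},
            "training_loss": self.training_loss,
        }


def _phantom_overrides(cfg: RunConfig) -> dict:
    return dict(
        slice_spacing_mm=cfg.slice_spacing_mm,
        slice_thickness_mm=cfg.slice_thickness_mm,
        image_size=cfg.image_size,
        noise_sd=cfg.noise_sd,
        transition_zone_mm=cfg.transition_zone_mm,
        n_series=cfg.n_series,
    )


def build_training_set(
    cohort: Sequence[PhantomStudy], cfg: RunConfig
) -> tuple[list[np.ndarray], list[str]]:
    """Filter every study and preprocess retained slices with internal labels."""
    inputs: list[np.ndarray] = []
    labels: list[str] = []
    for phantom in cohort:
        study, _ = filter_series(phantom.study)
        study, _ = filter_images(study, cfg.filter)
        for series in study.series:
            for im in series.images:
                label = phantom.internal_truth.get(im.image_uid)
                if label is None:
                    continue
                inputs.append(preprocess_image(im.pixels))
                labels.append(label)
    return inputs, labels


def infer_study(
    model: ModelHandle, phantom: PhantomStudy, cfg: RunConfig
) -> list[PredictionSequence]:
    """Filter, classify and post-process every series of one study."""
    study, _ = filter_series(phantom.study)
    study, _ = filter_images(study, cfg.filter)
    return [
        postprocess_series(predict_series(model, series), cfg.postprocess)
        for series in study.series
        if len(series)
    ]


def derive_study_regions(
    per_study: Mapping[str, Sequence[PredictionSequence]],
) -> dict[str, set[str]]:
    """Study-level region set: union of series-level non-indeterminate labels."""
    out: dict[str, set[str]] = {}
    for study_uid, seqs in per_study.items():
        regions: set[str] = set()
        for seq in seqs:
            labels = seq.labels()
            regions.update(
                label
                for (z, p), label in zip(seq.entries, labels)
                if not p.indeterminate
            )
        out[study_uid] = regions
    return out


def run_end_to_end(cfg: RunConfig, out_dir: "str | Path | None" = None) -> EvaluationReport:
    """Full synthetic experiment; deterministic under ``cfg.seed``.

    Generates a training and a held-out test cohort, applies the exclusion
    filters, trains the slice classifier on box-derived labels, classifies and
    post-processes every test series, and evaluates weighted metrics (with
    spatially aware bootstrap CIs when a bootstrap config is set).
    """
    seeds = stage_seeds(cfg.seed)
    overrides = _phantom_overrides(cfg)
    comps = default_compositions(cfg.modality)
    vocab = build_vocabulary(cfg.modality)

    def _run_stage(name, fn):
        try:
            return fn()
        except PipelineError:
            raise
        except Exception as e:  # noqa: BLE001 - re-raised with stage context
            raise PipelineError(name, str(e)) from e

    train_cohort = _run_stage(
        "train_cohort",
        lambda: generate_cohort(
            cfg.n_train_patients, comps, seed=seeds["train_cohort"],
            modality=cfg.modality, balanced=True, **overrides,
        ),
    )
    test_cohort = _run_stage(
        "test_cohort",
        lambda: generate_cohort(
            cfg.n_test_patients, comps, seed=seeds["test_cohort"],
            modality=cfg.modality, balanced=True, **overrides,
        ),
    )
    inputs, labels = _run_stage("preprocess", lambda: build_training_set(train_cohort, cfg))
    train_cfg = cfg.train.model_copy(update={"seed": seeds["training"]})
    model = _run_stage("train", lambda: train(inputs, labels, vocab, train_cfg))

    per_study: dict[str, list[PredictionSequence]] = {}
    truth: dict[str, str] = {}
    for phantom in test_cohort:
        per_study[phantom.study.study_uid] = _run_stage(
            "infer", lambda p=phantom: infer_study(model, p, cfg)
        )
        truth.update(phantom.truth)

    all_seqs = [s for seqs in per_study.values() for s in seqs]
    confusion = _run_stage(
        "evaluate",
        lambda: accumulate_confusion(all_seqs, truth, vocab.output_names),
    )
    if cfg.bootstrap is not None:
        boot_cfg = cfg.bootstrap.model_copy(update={"seed": seeds["bootstrap"]})
        metrics = _run_stage(
            "evaluate",
            lambda: bootstrap_ci(
                list(per_study.values()), truth, vocab.output_names, boot_cfg,
                slice_thickness=cfg.slice_thickness_mm,
            ),
        )
    else:
        metrics = _run_stage("evaluate", lambda: compute_metrics(confusion))
    n_indeterminate = sum(
        1 for seq in all_seqs for _, p in seq.entries if p.indeterminate
    )
    report = EvaluationReport(
        confusion=confusion,
        metrics=metrics,
        n_indeterminate=n_indeterminate,
        study_regions=derive_study_regions(per_study),
        training_loss=model.training_loss,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "run_config.json").write_text(
            json.dumps({"version": __version__, "config": json.loads(cfg.model_dump_json())}, indent=2)
        )
        (out / "report.json").write_text(json.dumps(report.to_dict(), indent=2))
        write_report(metrics, confusion, out)
        model.save(out / "checkpoint")
    return report
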