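"""End-to-end orchestration: raw sequence -> features -> LOO-CV -> scores.

Glue between the stage modules: prepares one patient (stabilize, scale,
project, detect reflections, downsample curves, build sampling regions)
and runs whole-cohort cross-validated benchmarks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classifier import PatientData, run_loo_cv
from .config import PipelineConfig
from .synthetic import generate_cohort
from .dynamics import compute_features, detect_reflections, project_video
from .evaluate import confusion_from_labels, metrics_from_confusion, pixelwise_metrics
from .io import VideoSequence
from .stabilize import stabilize_sequence
from .trainset import build_sampling_regions, central_disc_mask, choose_disk_radius


def prepare_patient(
    seq: VideoSequence,
    label: str,
    annotation_mask: np.ndarray | None = None,
    config: PipelineConfig | None = None,
    roi_mask: np.ndarray | None = None,
    stabilize: bool = True,
) -> PatientData:
    """Run the per-patient feature pipeline up to the classifier input.

    ``annotation_mask`` (last-frame coordinates) is required for positive
    patients; ``roi_mask`` defaults to the central disc also used for
    negative-pixel selection.
    """
    config = config or PipelineConfig()
    if label not in ("positive", "negative"):
        raise ValueError(f"label must be positive/negative, got {label!r}")
    if label == "positive" and (annotation_mask is None or not np.any(annotation_mask)):
        raise ValueError("positive patients need a nonempty annotation mask")

    if stabilize:
        seq, _ = stabilize_sequence(seq)
    scalar = project_video(seq)
    reflections = detect_reflections(scalar, config.reflection_threshold)
    features = compute_features(scalar, config.discard_first, config.n_curve_points)

    size = seq.shape[0]
    central = central_disc_mask(size, config.central_mask_radius_frac)
    if roi_mask is None:
        roi_mask = central
    if label == "positive":
        annotation_mask = np.asarray(annotation_mask, bool)
        erode_r, dilate_r = choose_disk_radius(annotation_mask,
                                               config.disk_radius_override)
        regions = build_sampling_regions(annotation_mask, erode_r, dilate_r,
                                         central, config.border_margin)
        positive_region = regions.positive_region
        negative_region = regions.negative_region
    else:
        regions = build_sampling_regions(np.zeros((size, size), bool), 1, 1,
                                         central, config.border_margin)
        positive_region = None
        negative_region = regions.negative_region

    return PatientData(
        patient_id=seq.patient_id, label=label, features=features,
        reflection_mask=reflections, valid_mask=seq.valid_mask,
        roi_mask=roi_mask, positive_region=positive_region,
        negative_region=negative_region, annotation_mask=annotation_mask,
    )


@dataclass
class BenchmarkResult:
    """Cohort-level LOO-CV outcome with sequence and pixel scores."""

    fold_results: list
    confusion: "object"
    sensitivity: float | None
    specificity: float | None
    accuracy: float | None
    lesion_ious: dict  # patient_id -> IoU vs truth (positive patients)


def benchmark_cohort(patients: list, config: PipelineConfig | None = None,
                     rng_seed: int = 0) -> BenchmarkResult:
    """LOO-CV over prepared patients plus sequence/pixel metric roll-up."""
    config = config or PipelineConfig()
    results = run_loo_cv(patients, config, rng_seed)
    truth = [p.label for p in patients]
    pred = [r.prediction.decision for r in results]
    cm = confusion_from_labels(truth, pred)
    report = metrics_from_confusion(cm)
    ious = {}
    for p, r in zip(patients, results):
        if p.label == "positive" and p.annotation_mask is not None:
            pm = pixelwise_metrics(r.prediction.region_labels > 0, p.annotation_mask)
            ious[p.patient_id] = pm.iou
    return BenchmarkResult(fold_results=results, confusion=cm,
                           sensitivity=report.sensitivity,
                           specificity=report.specificity,
                           accuracy=report.accuracy, lesion_ious=ious)


def run_phantom_benchmark(
    n_positive: int = 20,
    n_negative: int = 20,
    rng_seed: int = 0,
    config: PipelineConfig | None = None,
    **phantom_overrides,
) -> tuple:
    """Full phantom study: generate a cohort, run every pipeline stage,
    and score the LOO-CV outcome. Returns (patients, BenchmarkResult).

    The phantom truth lesion mask doubles as the colposcopist annotation,
    drawn in last-frame coordinates as in the acquisition protocol.
    """
    config = config or PipelineConfig()
    cohort = generate_cohort(n_positive, n_negative, seed=rng_seed,
                             **phantom_overrides)
    patients = []
    for _, seq, truth in cohort:
        mask = truth.lesion_mask if truth.patient_label == "positive" else None
        patients.append(prepare_patient(seq, truth.patient_label, mask, config))
    result = benchmark_cohort(patients, config, rng_seed=rng_seed)
    return patients, result
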