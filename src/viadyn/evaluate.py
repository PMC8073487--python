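"""Sequence-level and pixel-level scoring.

Confusion-matrix metrics, Cohen's kappa between raters, pixel-wise
IoU against annotation masks, and a study-style aggregate report:
per-rater metrics, rater means, and algorithm-minus-mean improvements in
percentage points. All arithmetic runs on exact fractions; rounding only
happens at display.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        for name in ("tp", "tn", "fp", "fn"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a nonnegative integer, got {v}")
        if self.total == 0:
            raise ValueError("confusion matrix must have at least one count")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricReport:
    """Proportion metrics; ``None`` marks an undefined denominator."""

    accuracy: float | None = None
    precision: float | None = None
    sensitivity: float | None = None
    specificity: float | None = None
    kappa: float | None = None
    iou: float | None = None
    rounding: int = 2

    def rounded(self) -> dict:
        out = {}
        for name in ("accuracy", "precision", "sensitivity", "specificity",
                     "kappa", "iou"):
            v = getattr(self, name)
            out[name] = None if v is None else round(v, self.rounding)
        return out


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


def metrics_from_confusion(cm: ConfusionMatrix) -> MetricReport:
    """accuracy, precision, sensitivity, specificity from raw counts.

    A metric whose denominator is zero is reported as undefined (None),
    never as 0.
    """
    return MetricReport(
        accuracy=_ratio(cm.tp + cm.tn, cm.total),
        precision=_ratio(cm.tp, cm.tp + cm.fp),
        sensitivity=_ratio(cm.tp, cm.tp + cm.fn),
        specificity=_ratio(cm.tn, cm.tn + cm.fp),
    )


def confusion_from_labels(truth: list, pred: list,
                          positive="positive") -> ConfusionMatrix:
    t = np.asarray([x == positive for x in truth])
    p = np.asarray([x == positive for x in pred])
    if t.shape != p.shape:
        raise ValueError("label lists must have equal length")
    return ConfusionMatrix(tp=int((t & p).sum()), tn=int((~t & ~p).sum()),
                           fp=int((~t & p).sum()), fn=int((t & ~p).sum()))


def cohen_kappa(rater_a: list, rater_b: list) -> float:
    """Chance-corrected agreement between two paired label lists.

    kappa = (p_o - p_e) / (1 - p_e); if both marginals are degenerate and
    the raters agree everywhere (p_e = p_o = 1), kappa is 1 by convention.
    """
    a = list(rater_a)
    b = list(rater_b)
    if len(a) != len(b) or not a:
        raise ValueError("rater lists must be nonempty and of equal length")
    n = len(a)
    categories = sorted(set(a) | set(b), key=str)
    p_o = sum(x == y for x, y in zip(a, b)) / n
    p_e = sum((a.count(c) / n) * (b.count(c) / n) for c in categories)
    if p_e == 1.0:
        return 1.0 if p_o == 1.0 else 0.0
    return (p_o - p_e) / (1.0 - p_e)


def pixelwise_metrics(pred_mask: np.ndarray, annot_mask: np.ndarray) -> MetricReport:
    """Per-pixel confusion over the full grid, plus IoU.

    IoU = |pred AND annot| / |pred OR annot|, undefined when the union is
    empty.
    """
    pred = np.asarray(pred_mask, bool)
    annot = np.asarray(annot_mask, bool)
    if pred.shape != annot.shape:
        raise ValueError("masks must share a shape")
    cm = ConfusionMatrix(tp=int((pred & annot).sum()),
                         tn=int((~pred & ~annot).sum()),
                         fp=int((pred & ~annot).sum()),
                         fn=int((~pred & annot).sum()))
    report = metrics_from_confusion(cm)
    union = int((pred | annot).sum())
    report.iou = None if union == 0 else int((pred & annot).sum()) / union
    return report


def mean_std_excluding_undefined(values: list) -> tuple:
    """Mean and population standard deviation over the defined entries;
    returns (None, None, n_excluded) when nothing is defined."""
    defined = [v for v in values if v is not None]
    n_excluded = len(values) - len(defined)
    if not defined:
        return None, None, n_excluded
    arr = np.asarray(defined, float)
    return float(arr.mean()), float(arr.std()), n_excluded


METRIC_NAMES = ("accuracy", "precision", "sensitivity", "specificity")


def aggregate_report(algorithm: ConfusionMatrix, raters: dict) -> dict:
    """Study-style sequence-level report.

    ``raters`` maps rater name -> ConfusionMatrix. Returns per-rater
    metrics, the across-rater mean of each metric, and the algorithm's
    improvement over that mean in percentage points — all computed on
    unrounded fractions, with a parallel 2-dp display rendering.
    """
    algo = metrics_from_confusion(algorithm)
    per_rater = {name: metrics_from_confusion(cm) for name, cm in raters.items()}
    means = {}
    improvements = {}
    for metric in METRIC_NAMES:
        vals = [getattr(r, metric) for r in per_rater.values()]
        mean, _, _ = mean_std_excluding_undefined(vals)
        means[metric] = mean
        a = getattr(algo, metric)
        improvements[metric] = None if (mean is None or a is None) \
            else (a - mean) * 100.0
    return {
        "algorithm": algo,
        "raters": per_rater,
        "rater_mean": means,
        "improvement_pp": improvements,
        "display": {
            "algorithm": algo.rounded(),
            "rater_mean": {m: None if v is None else round(v, 2)
                           for m, v in means.items()},
            "improvement_pp": {m: None if v is None else round(v, 2)
                               for m, v in improvements.items()},
        },
    }
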