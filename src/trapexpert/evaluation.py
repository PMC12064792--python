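"""Detection and classification metrics for single- and two-stage pipelines.

Per-class precision, recall and F1 (with support), their macro / weighted /
micro aggregates, image-level confusion matrices, box IoU, and mAP@0.5 with
all-point interpolated average precision (a 101-point option is available
for parity with common YOLO tooling).

Precision = TP/(TP+FP) measures the accuracy of positive predictions; recall
= TP/(TP+FN) the ability to find all true instances; F1 is their harmonic
mean.  With heavily imbalanced species abundances, accuracy alone
over-weights dominant classes, so the per-class F1 table is the primary
evaluation surface.  The zero-division convention is 0 throughout (a class
with no predictions has precision 0, one with no truths recall 0).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .dataset_io import BoundingBox
from .grouping import ConfusionMatrix

__all__ = [
    "ClassMetrics",
    "EvaluationReport",
    "build_confusion_matrix",
    "f1_score",
    "classification_report",
    "iou",
    "map_at_50",
    "published_benchmark",
]


@dataclass(frozen=True)
class ClassMetrics:
    label: str
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float
    support: int


@dataclass(frozen=True)
class EvaluationReport:
    """Per-class metrics plus confusion matrix and aggregate F1 scores.

    ``micro_f1`` equals overall accuracy for single-label classification;
    ``weighted_f1`` weights each class F1 by its support; ``macro_f1`` is the
    unweighted mean, most sensitive to rare species.
    """

    per_class: tuple[ClassMetrics, ...]
    confusion: ConfusionMatrix
    macro_f1: float
    weighted_f1: float
    micro_f1: float
    map50: float | None = None

    def __getitem__(self, label: str) -> ClassMetrics:
        for m in self.per_class:
            if m.label == label:
                return m
        raise KeyError(label)

    @property
    def accuracy(self) -> float:
        total = self.confusion.counts.sum()
        return float(np.trace(self.confusion.counts) / total) if total else 0.0

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                dict(label=m.label, precision=m.precision, recall=m.recall,
                     f1=m.f1, support=m.support)
                for m in self.per_class
            ]
        )

    def to_csv(self, path: str | Path) -> None:
        df = self.to_dataframe()
        footer = pd.DataFrame(
            [
                dict(label="macro avg", precision=np.nan, recall=np.nan,
                     f1=self.macro_f1, support=int(df["support"].sum())),
                dict(label="weighted avg", precision=np.nan, recall=np.nan,
                     f1=self.weighted_f1, support=int(df["support"].sum())),
                dict(label="micro avg", precision=self.micro_f1, recall=self.micro_f1,
                     f1=self.micro_f1, support=int(df["support"].sum())),
            ]
        )
        pd.concat([df, footer], ignore_index=True).to_csv(path, index=False)


def build_confusion_matrix(
    truth: Sequence[str], predicted: Sequence[str], labels: Sequence[str]
) -> ConfusionMatrix:
    """Count image-level (true, predicted) label pairs into a confusion
    matrix over the given label order."""
    if len(truth) != len(predicted):
        raise ValueError(
            f"{len(truth)} truths vs {len(predicted)} predictions"
        )
    index = {lab: i for i, lab in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=np.int64)
    for t, p in zip(truth, predicted):
        if t not in index:
            raise KeyError(f"true label {t!r} not in label order")
        if p not in index:
            raise KeyError(f"predicted label {p!r} not in label order")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(tuple(labels), counts)


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if not (0 <= precision <= 1 and 0 <= recall <= 1):
        raise ValueError("precision and recall must lie in [0, 1]")
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def classification_report(
    truth: Sequence[str], predicted: Sequence[str], labels: Sequence[str]
) -> EvaluationReport:
    """Per-class precision/recall/F1 with macro, weighted and micro averages,
    all derived from the image-level confusion matrix."""
    cm = build_confusion_matrix(truth, predicted, labels)
    counts = cm.counts
    per_class = []
    for i, lab in enumerate(labels):
        tp = int(counts[i, i])
        fp = int(counts[:, i].sum() - tp)
        fn = int(counts[i, :].sum() - tp)
        p = tp / (tp + fp) if tp + fp else 0.0
        r = tp / (tp + fn) if tp + fn else 0.0
        per_class.append(
            ClassMetrics(lab, tp, fp, fn, p, r, f1_score(p, r), tp + fn)
        )
    supports = np.array([m.support for m in per_class])
    f1s = np.array([m.f1 for m in per_class])
    macro = float(f1s.mean()) if len(f1s) else 0.0
    weighted = float((supports * f1s).sum() / supports.sum()) if supports.sum() else 0.0
    # single-label micro: TP aggregated over classes == correct predictions
    total = counts.sum()
    micro = float(np.trace(counts) / total) if total else 0.0
    return EvaluationReport(tuple(per_class), cm, macro, weighted, micro)


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection-over-union of two normalised boxes, in [0, 1]."""
    ax0, ay0, aw, ah = a.to_corner()
    bx0, by0, bw, bh = b.to_corner()
    ix = max(0.0, min(ax0 + aw, bx0 + bw) - max(ax0, bx0))
    iy = max(0.0, min(ay0 + ah, by0 + bh) - max(ay0, by0))
    inter = ix * iy
    union = aw * ah + bw * bh - inter
    return inter / union if union > 0 else 0.0


def _average_precision(
    recalls: np.ndarray, precisions: np.ndarray, interpolation: str
) -> float:
    """Area under the interpolated precision-recall curve."""
    mrec = np.concatenate([[0.0], recalls, [1.0]])
    mpre = np.concatenate([[0.0], precisions, [0.0]])
    # precision envelope: max precision at any recall >= r
    for i in range(len(mpre) - 2, -1, -1):
        mpre[i] = max(mpre[i], mpre[i + 1])
    if interpolation == "all_point":
        idx = np.flatnonzero(mrec[1:] != mrec[:-1]) + 1
        return float(np.sum((mrec[idx] - mrec[idx - 1]) * mpre[idx]))
    if interpolation == "101pt":
        grid = np.linspace(0.0, 1.0, 101)
        return float(np.mean(np.interp(grid, mrec, mpre)))
    raise ValueError(f"unknown interpolation {interpolation!r}")


def map_at_50(
    predictions: Sequence[tuple[str, str, float, BoundingBox]],
    truths: Sequence[tuple[str, str, BoundingBox]],
    iou_threshold: float = 0.5,
    interpolation: str = "all_point",
) -> tuple[dict[str, float], float]:
    """Mean average precision at an IoU threshold (0.5 by default).

    ``predictions`` are (image_id, label, confidence, box); ``truths`` are
    (image_id, label, box).  Per class, detections sorted by descending
    confidence are greedily matched (highest IoU first) to still-unmatched
    ground-truth boxes in the same image; a match requires IoU >= threshold.
    AP is the area under the interpolated precision-recall curve; mAP is the
    unweighted mean over classes with at least one ground truth.  Classes
    with detections but no truths are excluded from the mean and reported
    with AP = NaN.
    """
    classes = sorted({t[1] for t in truths} | {p[1] for p in predictions})
    ap: dict[str, float] = {}
    with_truth = []
    for cls in classes:
        cls_truth: dict[str, list[BoundingBox]] = {}
        for image_id, lab, box in truths:
            if lab == cls:
                cls_truth.setdefault(image_id, []).append(box)
        n_truth = sum(len(v) for v in cls_truth.values())
        cls_preds = sorted(
            (p for p in predictions if p[1] == cls),
            key=lambda p: (-p[2], p[0]),
        )
        if n_truth == 0:
            ap[cls] = float("nan")
            continue
        with_truth.append(cls)
        matched: dict[str, set[int]] = {k: set() for k in cls_truth}
        tp = np.zeros(len(cls_preds))
        for i, (image_id, _lab, _conf, box) in enumerate(cls_preds):
            candidates = cls_truth.get(image_id, [])
            best_iou, best_j = 0.0, -1
            for j, tbox in enumerate(candidates):
                if j in matched.get(image_id, set()):
                    continue
                v = iou(box, tbox)
                if v > best_iou:
                    best_iou, best_j = v, j
            if best_j >= 0 and best_iou >= iou_threshold:
                matched[image_id].add(best_j)
                tp[i] = 1.0
        if len(cls_preds) == 0:
            ap[cls] = 0.0
            continue
        cum_tp = np.cumsum(tp)
        precisions = cum_tp / np.arange(1, len(cls_preds) + 1)
        recalls = cum_tp / n_truth
        ap[cls] = _average_precision(recalls, precisions, interpolation)
    mean_ap = float(np.mean([ap[c] for c in with_truth])) if with_truth else 0.0
    return ap, mean_ap


def published_benchmark() -> pd.DataFrame:
    """Per-species precision/recall/F1/support reported for a published
    24-species (plus background) Mediterranean camera-trap benchmark, for
    both a single-stage global detector and the two-stage expert pipeline.

    Columns: code, common_name, group, precision_single, recall_single,
    f1_single, precision_two, recall_two, f1_two, support.  The support
    column doubles as the default relative-abundance profile of the
    simulator, and the group column records the four appearance groups
    (large/medium/small mammals and micromammals).
    """
    with resources.files("trapexpert.data").joinpath("published_metrics.csv").open() as fh:
        return pd.read_csv(fh)
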