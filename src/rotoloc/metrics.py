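"""Detection evaluation: matching, average precision, confusion metrics,
and patient-level cross-validation folds.

Beyond the usual precision/recall/mAP50, the evaluation also reports
specificity, the Matthews correlation coefficient (MCC) and the error rate
(ERR), which require a true-negative count. TN is not defined in standard
box detection; here it is an image-level convention: an image contributes
one TN for a class when it contains neither a ground-truth box nor a
prediction of that class. This is a declared stand-in, not a community
standard, and is flagged in the report.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .geometry import Box, ObjectClass, iou


class UndefinedMetricError(ValueError):
    """A metric was requested whose value is undefined on this input."""


@dataclass
class GroundTruthSet:
    """Ground-truth boxes per image, with the patient each image came from.

    ``boxes`` maps image id -> list of Box; ``patients`` maps image id ->
    patient id. Every image must have a patient id: the patient is the
    unit of data partitioning, so images without provenance cannot be
    placed in a fold.
    """

    boxes: dict[str, list[Box]]
    patients: dict[str, str]

    def __post_init__(self) -> None:
        missing = set(self.boxes) - set(self.patients)
        if missing:
            raise ValueError(f"images missing patient ids: {sorted(missing)[:5]}")

    @property
    def image_ids(self) -> list[str]:
        return sorted(self.boxes)

    def class_count(self, class_id: ObjectClass) -> int:
        return sum(
            sum(1 for b in bs if b.class_id is class_id) for bs in self.boxes.values()
        )


@dataclass
class MatchResult:
    """Per-class confusion counts from greedy IoU matching."""

    tp: dict[ObjectClass, int] = field(default_factory=dict)
    fp: dict[ObjectClass, int] = field(default_factory=dict)
    fn: dict[ObjectClass, int] = field(default_factory=dict)
    tn: dict[ObjectClass, int] = field(default_factory=dict)
    matches: list[tuple[str, ObjectClass, float, float]] = field(default_factory=list)
    """(image id, class, prediction confidence, IoU) per matched pair."""


def match_detections(
    preds: Mapping[str, Sequence[Box]],
    gts: GroundTruthSet,
    iou_threshold: float = 0.5,
) -> MatchResult:
    """Greedy one-to-one matching of predictions to ground truth.

    Per image and class, predictions are taken in descending confidence;
    each claims the unmatched ground-truth box with the highest IoU at or
    above the threshold. Leftover predictions are FP, leftover ground
    truths FN. TN follows the image-level convention described in the
    module docstring.
    """
    if not 0.0 < iou_threshold < 1.0:
        raise ValueError(f"iou_threshold must lie in (0, 1), got {iou_threshold}")
    result = MatchResult()
    for cls in ObjectClass:
        result.tp[cls] = result.fp[cls] = result.fn[cls] = result.tn[cls] = 0
    for image_id in gts.image_ids:
        gt_boxes = gts.boxes[image_id]
        pred_boxes = list(preds.get(image_id, ()))
        for cls in ObjectClass:
            g = [b for b in gt_boxes if b.class_id is cls]
            p = sorted(
                (b for b in pred_boxes if b.class_id is cls),
                key=lambda b: -b.confidence,
            )
            taken = [False] * len(g)
            n_matched = 0
            for pb in p:
                best, best_iou = -1, iou_threshold
                for j, gb in enumerate(g):
                    if taken[j]:
                        continue
                    v = iou(pb, gb)
                    if v >= best_iou:
                        best, best_iou = j, v
                if best >= 0:
                    taken[best] = True
                    n_matched += 1
                    result.matches.append((image_id, cls, pb.confidence, best_iou))
            result.tp[cls] += n_matched
            result.fp[cls] += len(p) - n_matched
            result.fn[cls] += len(g) - n_matched
            if not g and not p:
                result.tn[cls] += 1
    return result


def average_precision_50(
    preds: Mapping[str, Sequence[Box]],
    gts: GroundTruthSet,
    class_id: ObjectClass,
    iou_threshold: float = 0.5,
) -> float:
    """Average precision at IoU 0.5 with all-points interpolation.

    Predictions of the class are pooled across images, sorted by
    confidence, and greedily matched per image; the precision envelope is
    integrated over recall. Raises if the class has no ground truth, since
    recall -- and hence AP -- is undefined there.
    """
    n_gt = gts.class_count(class_id)
    if n_gt == 0:
        raise UndefinedMetricError(
            f"AP for {class_id.name} is undefined: no ground-truth boxes"
        )
    records: list[tuple[float, bool]] = []  # (confidence, is_tp)
    for image_id in gts.image_ids:
        g = [b for b in gts.boxes[image_id] if b.class_id is class_id]
        p = sorted(
            (b for b in preds.get(image_id, ()) if b.class_id is class_id),
            key=lambda b: -b.confidence,
        )
        taken = [False] * len(g)
        for pb in p:
            best, best_iou = -1, iou_threshold
            for j, gb in enumerate(g):
                if taken[j]:
                    continue
                v = iou(pb, gb)
                if v >= best_iou:
                    best, best_iou = j, v
            if best >= 0:
                taken[best] = True
                records.append((pb.confidence, True))
            else:
                records.append((pb.confidence, False))
    if not records:
        return 0.0
    records.sort(key=lambda r: -r[0])
    tp = np.cumsum([r[1] for r in records])
    fp = np.cumsum([not r[1] for r in records])
    recall = tp / n_gt
    precision = tp / (tp + fp)
    # precision envelope + area under the stepwise curve
    mrec = np.concatenate(([0.0], recall, [1.0]))
    mpre = np.concatenate(([1.0], precision, [0.0]))
    mpre = np.maximum.accumulate(mpre[::-1])[::-1]
    idx = np.where(mrec[1:] != mrec[:-1])[0]
    return float(np.sum((mrec[idx + 1] - mrec[idx]) * mpre[idx + 1]))


@dataclass
class ClassMetrics:
    precision: Optional[float]
    recall: Optional[float]
    map50: Optional[float]
    specificity: Optional[float]
    mcc: float
    err: Optional[float]


@dataclass
class MetricsReport:
    """Per-class and pooled metrics, mirroring the per-class rows of the
    published evaluation tables (precision, recall, mAP50, specificity,
    MCC, ERR per class, then pooled)."""

    per_class: dict[ObjectClass, ClassMetrics]
    pooled: ClassMetrics
    tn_convention: str = (
        "TN counted per image and class: 1 when the image has neither "
        "ground truth nor predictions of that class (non-standard, declared)"
    )

    def to_dict(self) -> dict:
        def cm(c: ClassMetrics) -> dict:
            return {
                "precision": c.precision,
                "recall": c.recall,
                "mAP50": c.map50,
                "specificity": c.specificity,
                "MCC": c.mcc,
                "ERR": c.err,
            }

        out = {cls.name.lower(): cm(m) for cls, m in self.per_class.items()}
        out["all"] = cm(self.pooled)
        out["tn_convention"] = self.tn_convention
        return out

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def format_table(self) -> str:
        rows = []
        names = {ObjectClass.SLOT: "cutter slot", ObjectClass.TUMOR: "tumor"}
        fmt = lambda v: "  n/a" if v is None else f"{v:.3f}"
        for metric in ("precision", "recall", "map50", "specificity", "mcc", "err"):
            label = {"map50": "mAP50", "mcc": "MCC", "err": "ERR"}.get(metric, metric.capitalize())
            for cls in (ObjectClass.TUMOR, ObjectClass.SLOT):
                rows.append(
                    f"{label}({names[cls]})\t{fmt(getattr(self.per_class[cls], metric))}"
                )
            rows.append(f"{label}(all)\t{fmt(getattr(self.pooled, metric))}")
        return "\n".join(rows)


def _confusion(tp: int, fp: int, fn: int, tn: int, ap: Optional[float]) -> ClassMetrics:
    def ratio(num: int, den: int) -> Optional[float]:
        return num / den if den > 0 else None

    precision = ratio(tp, tp + fp)
    recall = ratio(tp, tp + fn)
    specificity = ratio(tn, tn + fp)
    err = ratio(fp + fn, tp + tn + fp + fn)
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = 0.0 if denom == 0 else (tp * tn - fp * fn) / math.sqrt(denom)
    return ClassMetrics(precision, recall, ap, specificity, mcc, err)


def confusion_metrics(
    m: MatchResult,
    ap: Optional[Mapping[ObjectClass, float]] = None,
) -> MetricsReport:
    """Turn matching counts (and optional per-class AP values) into the
    full report. Metrics with a zero denominator are reported as None
    (undefined) rather than 0; MCC defaults to 0 when any marginal is zero."""
    per_class: dict[ObjectClass, ClassMetrics] = {}
    for cls in ObjectClass:
        if min(m.tp[cls], m.fp[cls], m.fn[cls], m.tn[cls]) < 0:
            raise ValueError("confusion counts must be non-negative")
        per_class[cls] = _confusion(
            m.tp[cls], m.fp[cls], m.fn[cls], m.tn[cls],
            None if ap is None else ap.get(cls),
        )
    tp = sum(m.tp.values()); fp = sum(m.fp.values())
    fn = sum(m.fn.values()); tn = sum(m.tn.values())
    pooled_ap = None
    if ap is not None and len(ap) == len(ObjectClass):
        pooled_ap = float(np.mean([ap[c] for c in ObjectClass]))
    pooled = _confusion(tp, fp, fn, tn, pooled_ap)
    return MetricsReport(per_class=per_class, pooled=pooled)


def evaluate(
    preds: Mapping[str, Sequence[Box]],
    gts: GroundTruthSet,
    iou_threshold: float = 0.5,
) -> MetricsReport:
    """Convenience wrapper: match, compute per-class AP where defined,
    and assemble the report."""
    m = match_detections(preds, gts, iou_threshold)
    ap: dict[ObjectClass, float] = {}
    for cls in ObjectClass:
        if gts.class_count(cls) > 0:
            ap[cls] = average_precision_50(preds, gts, cls, iou_threshold)
    return confusion_metrics(m, ap)


def patient_fold_split(
    gts: GroundTruthSet, k: int = 3, seed: int = 0
) -> list[set[str]]:
    """Split image ids into k folds keeping each patient's images together.

    Patients are shuffled deterministically by seed and dealt round-robin
    so fold sizes differ by at most one patient.
    """
    patients = sorted(set(gts.patients.values()))
    if k > len(patients):
        raise ValueError(
            f"cannot make {k} folds from {len(patients)} patients"
        )
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(patients))
    folds: list[set[str]] = [set() for _ in range(k)]
    assignment = {p: i % k for i, p in enumerate(order)}
    for image_id in gts.image_ids:
        folds[assignment[gts.patients[image_id]]].add(image_id)
    return folds
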