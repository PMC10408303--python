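"""VOC-style detection scoring at a fixed IoU threshold.

Detections are matched greedily in descending confidence: each detection
claims the highest-IoU still-unmatched ground truth of its image, counting
as a true positive when IoU strictly exceeds the threshold and as a false
positive otherwise; ground truths left unclaimed are false negatives.
Sweeping the confidence axis yields the precision-recall curve; average
precision is the area under its upper envelope (all-point interpolation),
and mAP is the arithmetic mean of the per-class APs (classes with no
ground truth have undefined AP and are excluded rather than scored 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .boxes import iou_matrix
from .model import CLASS_NAMES
from .postprocess import Detection

#: Default matching threshold used throughout.
DEFAULT_IOU_THRESHOLD = 0.5


@dataclass(frozen=True)
class GroundTruth:
    image_id: str
    box: np.ndarray
    label: str


@dataclass(frozen=True)
class PRCurve:
    """Precision/recall swept over detection confidences (descending)."""

    thresholds: np.ndarray
    recall: np.ndarray
    precision: np.ndarray


@dataclass(frozen=True)
class ClassReport:
    tp: int
    fp: int
    fn: int
    ap: float | None
    pr_curve: PRCurve | None


@dataclass(frozen=True)
class EvalReport:
    per_class: dict[str, ClassReport]
    iou_threshold: float

    @property
    def map(self) -> float:
        aps = [r.ap for r in self.per_class.values() if r.ap is not None]
        return mean_ap(aps)

    def __str__(self) -> str:
        lines = [f"IoU threshold: {self.iou_threshold:.2f}"]
        for name, r in self.per_class.items():
            ap = "n/a" if r.ap is None else f"{100 * r.ap:6.2f}%"
            lines.append(f"{name:<12} AP {ap}   Tp {r.tp}  Fp {r.fp}  Fn {r.fn}")
        lines.append(f"{'mAP':<12}    {100 * self.map:6.2f}%")
        return "\n".join(lines)

    def as_dict(self) -> dict:
        return {
            "iou_threshold": self.iou_threshold,
            "map": self.map,
            "per_class": {
                name: {"ap": r.ap, "tp": r.tp, "fp": r.fp, "fn": r.fn}
                for name, r in self.per_class.items()
            },
        }


def _match_flags(dets, gts, iou_thresh: float) -> np.ndarray:
    """True-positive flags for detections sorted by descending score.

    ``dets``: list of (image_id, box, score); ``gts``: list of
    (image_id, box).  Returns the tp flag per detection in score order.
    """
    order = sorted(range(len(dets)), key=lambda i: (-dets[i][2], i))
    gt_by_image: dict[str, list[np.ndarray]] = {}
    for image_id, box in gts:
        gt_by_image.setdefault(image_id, []).append(np.asarray(box, dtype=np.float64))
    matched: dict[str, np.ndarray] = {
        img: np.zeros(len(boxes), dtype=bool) for img, boxes in gt_by_image.items()
    }
    flags = np.zeros(len(dets), dtype=bool)
    for rank, i in enumerate(order):
        image_id, box, _ = dets[i]
        boxes = gt_by_image.get(image_id)
        if not boxes:
            continue
        free = ~matched[image_id]
        if not free.any():
            continue
        ious = iou_matrix(np.asarray(box, dtype=np.float64)[None, :], np.stack(boxes))[0]
        ious = np.where(free, ious, -1.0)
        j = int(ious.argmax())
        if ious[j] > iou_thresh:
            matched[image_id][j] = True
            flags[rank] = True
    return flags


def confusion_counts(dets, gts, iou_thresh: float = DEFAULT_IOU_THRESHOLD):
    """(Tp, Fp, Fn) for one class over an image set.

    True negatives have no meaningful box-level count in detection and are
    not reported.
    """
    flags = _match_flags(list(dets), list(gts), iou_thresh)
    tp = int(flags.sum())
    return tp, int(len(flags) - tp), int(len(list(gts)) - tp)


def average_precision(dets, gts, iou_thresh: float = DEFAULT_IOU_THRESHOLD):
    """PR curve and all-point-interpolated AP for one class.

    Raises on an empty ground-truth set, where AP is undefined.
    """
    dets = list(dets)
    gts = list(gts)
    if len(gts) == 0:
        raise ValueError("AP is undefined for a class with no ground-truth objects")
    if len(dets) == 0:
        return PRCurve(np.empty(0), np.empty(0), np.empty(0)), 0.0
    flags = _match_flags(dets, gts, iou_thresh)
    scores = np.sort(np.asarray([d[2] for d in dets]))[::-1]
    tp_cum = np.cumsum(flags)
    fp_cum = np.cumsum(~flags)
    recall = tp_cum / len(gts)
    precision = tp_cum / (tp_cum + fp_cum)
    curve = PRCurve(thresholds=scores, recall=recall, precision=precision)

    # integrate the precision envelope over recall (all-point interpolation)
    r = np.concatenate([[0.0], recall, [1.0]])
    p = np.concatenate([[0.0], precision, [0.0]])
    for i in range(len(p) - 2, -1, -1):
        p[i] = max(p[i], p[i + 1])
    steps = np.nonzero(r[1:] != r[:-1])[0]
    ap = float(np.sum((r[steps + 1] - r[steps]) * p[steps + 1]))
    return curve, ap


def mean_ap(per_class_ap) -> float:
    """Arithmetic mean over classes with defined AP."""
    aps = [a for a in per_class_ap if a is not None]
    if not aps:
        raise ValueError("mean_ap requires at least one defined per-class AP")
    return float(np.mean(aps))


def evaluate_detections(
    detections: dict[str, list[Detection]],
    ground_truths: list[GroundTruth],
    iou_thresh: float = DEFAULT_IOU_THRESHOLD,
    class_names: tuple[str, ...] = CLASS_NAMES,
    point_score_threshold: float = 0.5,
) -> EvalReport:
    """Full per-class report over a dataset.

    ``detections`` maps image id to its detection list.  AP uses every
    detection; the Tp/Fp/Fn operating point uses only detections with
    score >= ``point_score_threshold``.
    """
    per_class: dict[str, ClassReport] = {}
    for name in class_names:
        dets = [
            (image_id, d.box, d.score)
            for image_id, dlist in detections.items()
            for d in dlist
            if d.label == name
        ]
        gts = [(g.image_id, g.box) for g in ground_truths if g.label == name]
        if not gts:
            per_class[name] = ClassReport(tp=0, fp=len(dets), fn=0, ap=None, pr_curve=None)
            continue
        curve, ap = average_precision(dets, gts, iou_thresh)
        point_dets = [d for d in dets if d[2] >= point_score_threshold]
        tp, fp, fn = confusion_counts(point_dets, gts, iou_thresh)
        per_class[name] = ClassReport(tp=tp, fp=fp, fn=fn, ap=ap, pr_curve=curve)
    return EvalReport(per_class=per_class, iou_threshold=iou_thresh)
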