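"""From raw head outputs to final detections.

Pipeline: sigmoid over class logits -> score threshold with per-level
top-k pre-selection -> delta decoding against anchors with clipping ->
per-class greedy NMS -> optionally the crop-first cross-class rule.

Crop-first non-maximal suppression addresses duplicate predictions where
one object is reported as both crop and weed: detections are split into
the sugar-beet (crop) group and the weed group, and every weed box whose
IoU with any sugar-beet box strictly exceeds the threshold is deleted.
Crop boxes are never removed, so an ambiguous object is resolved as crop -
the asymmetry a weeding robot wants, since destroying a crop is the costly
mistake.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .boxes import box_area, decode, iou_matrix, validate_boxes
from .model import CLASS_NAMES

CROP_LABEL = CLASS_NAMES[0]


@dataclass(frozen=True)
class Detection:
    """A scored, class-labelled axis-aligned box."""

    box: np.ndarray  # (4,) x_min, y_min, x_max, y_max
    label: str
    score: float

    def __post_init__(self):
        validate_boxes(self.box)
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score must lie in [0, 1], got {self.score}")

    def as_record(self, image_id: str = "") -> dict:
        x1, y1, x2, y2 = (float(v) for v in np.asarray(self.box, dtype=float))
        return {
            "image_id": image_id,
            "label": self.label,
            "score": float(self.score),
            "x_min": x1,
            "y_min": y1,
            "x_max": x2,
            "y_max": y2,
        }


@dataclass(frozen=True)
class NMSConfig:
    """Post-processing profile.

    The default is the dense evaluation profile (low score threshold for a
    full PR sweep, crop-first off: the cross-class rule is an operating-
    point decision and would let near-noise crop candidates delete
    confident weed boxes if run over the dense set).
    :meth:`deployment` gives the in-field profile: confidence 0.5 with
    crop-first suppression at IoU 0.5.
    """

    score_threshold: float = 0.05
    class_nms_iou: float = 0.5
    crop_first_enabled: bool = False
    crop_first_iou: float = 0.5
    top_k: int = 1000

    def __post_init__(self):
        for name in ("score_threshold", "class_nms_iou", "crop_first_iou"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")

    @classmethod
    def deployment(cls, crop_first: bool = True) -> "NMSConfig":
        return cls(score_threshold=0.5, crop_first_enabled=crop_first)


def _sort_order(boxes: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """Descending score; ties broken by larger area, then input order."""
    areas = box_area(boxes)
    return np.lexsort((np.arange(len(scores)), -areas, -scores))


def standard_nms(dets: list[Detection], iou_thresh: float) -> list[Detection]:
    """Greedy single-class NMS; strictly-greater overlaps are suppressed.

    Keeps the highest-scoring box, removes every remaining box with
    IoU > ``iou_thresh`` against a kept box; output sorted by descending
    score.  All detections must share one class label.
    """
    if not dets:
        return []
    labels = {d.label for d in dets}
    if len(labels) > 1:
        raise ValueError(f"standard_nms is per-class; got mixed labels {sorted(labels)}")
    boxes = np.stack([np.asarray(d.box, dtype=np.float64) for d in dets])
    scores = np.asarray([d.score for d in dets])
    order = _sort_order(boxes, scores)
    keep: list[int] = []
    suppressed = np.zeros(len(dets), dtype=bool)
    for idx in order:
        if suppressed[idx]:
            continue
        keep.append(idx)
        remaining = order[~suppressed[order] & (order != idx)]
        if len(remaining):
            overlaps = iou_matrix(boxes[idx : idx + 1], boxes[remaining])[0]
            suppressed[remaining[overlaps > iou_thresh]] = True
    return [dets[i] for i in keep]


def crop_first_nms(dets: list[Detection], iou_thresh: float) -> list[Detection]:
    """Delete weed boxes overlapping any crop box with IoU > ``iou_thresh``.

    Crop (sugar-beet) detections pass through untouched; with no crop
    detections the input is returned unchanged.  Input order is preserved.
    """
    crops = [d for d in dets if d.label == CROP_LABEL]
    if not crops:
        return list(dets)
    crop_boxes = np.stack([np.asarray(d.box, dtype=np.float64) for d in crops])
    out: list[Detection] = []
    for d in dets:
        if d.label == CROP_LABEL:
            out.append(d)
            continue
        overlaps = iou_matrix(np.asarray(d.box, dtype=np.float64)[None, :], crop_boxes)[0]
        if not np.any(overlaps > iou_thresh):
            out.append(d)
    return out


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def decode_detections(
    outputs: list[tuple[np.ndarray, np.ndarray]],
    anchors: dict[int, np.ndarray] | list[np.ndarray],
    config: NMSConfig = NMSConfig(),
    image_size: tuple[int, int] | None = None,
    class_names: tuple[str, ...] = CLASS_NAMES,
) -> list[Detection]:
    """Final detections for one image.

    ``outputs`` is the per-level list of ``(class_logits, box_deltas)``
    arrays shaped ``(A_l, K)`` / ``(A_l, 4)`` (a leading batch axis of one
    is squeezed); ``anchors`` the matching per-level anchor sets.
    """
    if isinstance(anchors, dict):
        anchors = [anchors[lv] for lv in sorted(anchors)]
    if len(outputs) != len(anchors):
        raise ValueError(f"{len(outputs)} output levels but {len(anchors)} anchor levels")
    candidates: list[Detection] = []
    for (logits, deltas), level_anchors in zip(outputs, anchors):
        logits = np.asarray(logits, dtype=np.float64)
        deltas = np.asarray(deltas, dtype=np.float64)
        if logits.ndim == 3:
            if logits.shape[0] != 1:
                raise ValueError("decode_detections processes one image at a time")
            logits, deltas = logits[0], deltas[0]
        if len(logits) != len(level_anchors):
            raise ValueError(
                f"level has {len(logits)} predictions but {len(level_anchors)} anchors"
            )
        scores = _sigmoid(logits)
        anchor_idx, class_idx = np.nonzero(scores >= config.score_threshold)
        if len(anchor_idx) == 0:
            continue
        flat_scores = scores[anchor_idx, class_idx]
        if len(flat_scores) > config.top_k:
            top = np.argpartition(-flat_scores, config.top_k)[: config.top_k]
            anchor_idx, class_idx, flat_scores = anchor_idx[top], class_idx[top], flat_scores[top]
        boxes = decode(deltas[anchor_idx], level_anchors[anchor_idx], image_size=image_size)
        for b, k, s in zip(boxes, class_idx, flat_scores):
            candidates.append(Detection(box=b, label=class_names[k], score=float(s)))
    final: list[Detection] = []
    for name in class_names:
        final.extend(
            standard_nms([d for d in candidates if d.label == name], config.class_nms_iou)
        )
    if config.crop_first_enabled:
        final = crop_first_nms(final, config.crop_first_iou)
    return sorted(final, key=lambda d: -d.score)
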