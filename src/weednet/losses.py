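"""Anchor matching and the training objective.

The total loss is the sum of a focal classification term over all
non-ignored anchors and a smooth-L1 regression term over positive anchors,
each normalised by the number of positive anchors:

    L_total = (1/N_pos) * sum_i L_cls,i  +  (1/N_pos) * sum_j L_reg,j

Classification uses independent per-class sigmoids (background is the
all-negative state), with the focal form

    L_cls = -alpha_t * (1 - p_t)**gamma * log(p_t)

where ``p_t = p`` for a positive label and ``1 - p`` otherwise, and
``alpha_t`` is ``alpha`` / ``1 - alpha`` correspondingly.  Regression
applies smooth L1 elementwise to the difference between predicted and
target anchor-relative deltas.

Because the network substrate propagates gradients only from the raw head
outputs, :func:`detection_loss` also returns the analytic gradients of the
scalar objective with respect to the class logits and box deltas; the
trainer seeds backpropagation with them.  The gradients are verified
against finite differences in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .boxes import encode, iou_matrix

#: Anchor-state codes in MatchResult.states
NEGATIVE = -1
IGNORE = -2

_P_CLAMP = 1e-6


@dataclass(frozen=True)
class FocalParams:
    """alpha in [0, 1] balances classes; gamma >= 0 focuses on hard examples.

    gamma = 0 with alpha_t = 1 reduces the loss to plain cross-entropy.
    """

    alpha: float = 0.25
    gamma: float = 2.0

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must lie in [0, 1], got {self.alpha}")
        if self.gamma < 0:
            raise ValueError(f"gamma must be non-negative, got {self.gamma}")


@dataclass
class MatchResult:
    """Per-anchor assignment: gt index if positive, NEGATIVE or IGNORE."""

    states: np.ndarray  # (A,) int; >= 0 -> index into gt list

    @property
    def positive_mask(self) -> np.ndarray:
        return self.states >= 0

    @property
    def negative_mask(self) -> np.ndarray:
        return self.states == NEGATIVE

    @property
    def ignore_mask(self) -> np.ndarray:
        return self.states == IGNORE

    @property
    def npos(self) -> int:
        return int(self.positive_mask.sum())


@dataclass(frozen=True)
class LossBundle:
    cls: float
    reg: float

    @property
    def total(self) -> float:
        return self.cls + self.reg


def match_anchors(
    anchors: np.ndarray,
    gt_boxes: np.ndarray,
    pos_iou: float = 0.5,
    neg_iou: float = 0.4,
) -> MatchResult:
    """Max-IoU assignment: >= pos_iou positive, < neg_iou negative, else ignored.

    Each positive anchor is assigned to its highest-IoU ground truth; IoU
    ties resolve to the lowest ground-truth index.  With no ground truths
    every anchor is negative.
    """
    n = len(np.atleast_2d(anchors))
    gt_boxes = np.asarray(gt_boxes, dtype=np.float64).reshape(-1, 4)
    if len(gt_boxes) == 0:
        return MatchResult(states=np.full(n, NEGATIVE, dtype=np.int64))
    ious = iou_matrix(anchors, gt_boxes)
    best_gt = ious.argmax(axis=1)
    best_iou = ious[np.arange(n), best_gt]
    states = np.full(n, IGNORE, dtype=np.int64)
    states[best_iou < neg_iou] = NEGATIVE
    pos = best_iou >= pos_iou
    states[pos] = best_gt[pos]
    return MatchResult(states=states)


def focal_loss(p, y, params: FocalParams = FocalParams()) -> np.ndarray:
    """Elementwise focal loss on probabilities ``p`` with binary labels ``y``."""
    p = np.asarray(p, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    p = np.clip(p, _P_CLAMP, 1.0 - _P_CLAMP)
    pt = np.where(y == 1, p, 1.0 - p)
    at = np.where(y == 1, params.alpha, 1.0 - params.alpha)
    return -at * (1.0 - pt) ** params.gamma * np.log(pt)


def smooth_l1(x) -> np.ndarray:
    """0.5 x^2 for |x| < 1, |x| - 0.5 otherwise (continuous at the knee)."""
    x = np.asarray(x, dtype=np.float64)
    if not np.all(np.isfinite(x)):
        raise ValueError("smooth_l1 requires finite input")
    ax = np.abs(x)
    return np.where(ax < 1.0, 0.5 * x * x, ax - 0.5)


def _smooth_l1_grad(x: np.ndarray) -> np.ndarray:
    return np.clip(x, -1.0, 1.0)


def _focal_with_logits(z: np.ndarray, y: np.ndarray, params: FocalParams):
    """Focal loss and its gradient w.r.t. logits ``z`` (elementwise)."""
    p = 1.0 / (1.0 + np.exp(-z.astype(np.float64)))
    p = np.clip(p, _P_CLAMP, 1.0 - _P_CLAMP)
    pt = np.where(y == 1, p, 1.0 - p)
    at = np.where(y == 1, params.alpha, 1.0 - params.alpha)
    logpt = np.log(pt)
    one_minus = 1.0 - pt
    loss = -at * one_minus**params.gamma * logpt
    # d loss / d pt, then chain through d pt / d z = +-p(1-p)
    g = params.gamma
    dl_dpt = at * (g * one_minus ** (g - 1.0) * logpt - one_minus**g / pt) if g > 0 else -at / pt
    dpt_dz = np.where(y == 1, 1.0, -1.0) * p * (1.0 - p)
    return loss, dl_dpt * dpt_dz


def detection_loss(
    cls_logits: np.ndarray,
    reg_deltas: np.ndarray,
    anchors: np.ndarray,
    gt_boxes: np.ndarray,
    gt_labels: np.ndarray,
    match: MatchResult | None = None,
    params: FocalParams = FocalParams(),
    num_classes: int = 2,
):
    """Scalar objective and analytic gradients for one image.

    Parameters are the flattened per-anchor head outputs (``(A, K)`` logits
    and ``(A, 4)`` deltas), the matching anchor boxes, and the ground-truth
    boxes/label indices.  Returns ``(bundle, d_logits, d_deltas)`` where the
    gradients are of ``bundle.total`` (already N_pos-normalised; the
    normaliser is clamped to >= 1 so empty images are well defined).
    """
    a = np.asarray(anchors, dtype=np.float64).reshape(-1, 4)
    gt_boxes = np.asarray(gt_boxes, dtype=np.float64).reshape(-1, 4)
    gt_labels = np.asarray(gt_labels, dtype=np.int64).reshape(-1)
    if match is None:
        match = match_anchors(a, gt_boxes)
    states = match.states
    npos = match.npos
    norm = max(npos, 1)

    # classification over positive + negative anchors
    targets = np.zeros((len(a), num_classes), dtype=np.float64)
    pos = match.positive_mask
    if npos:
        targets[pos, gt_labels[states[pos]]] = 1.0
    keep = ~match.ignore_mask
    loss_el, grad_el = _focal_with_logits(np.asarray(cls_logits, dtype=np.float64), targets, params)
    cls_loss = float(loss_el[keep].sum()) / norm
    d_logits = np.where(keep[:, None], grad_el, 0.0) / norm

    # regression over positive anchors only
    d_deltas = np.zeros_like(np.asarray(reg_deltas, dtype=np.float64))
    if npos:
        t_star = encode(gt_boxes[states[pos]], a[pos])
        diff = np.asarray(reg_deltas, dtype=np.float64)[pos] - t_star
        reg_loss = float(smooth_l1(diff).sum()) / norm
        d_deltas[pos] = _smooth_l1_grad(diff) / norm
    else:
        reg_loss = 0.0

    return LossBundle(cls=cls_loss, reg=reg_loss), d_logits, d_deltas
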