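"""Axis-aligned box geometry: IoU, anchor grids, and delta encoding.

Boxes use continuous pixel coordinates ``(x_min, y_min, x_max, y_max)``,
origin top-left, with ``width = x_max - x_min`` (no +1 convention).
Functions accept single boxes of shape ``(4,)`` or stacks of shape
``(N, 4)``; anchors are stored in the same corner format.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Pyramid levels used by the detector; level L has stride 2**L.
DEFAULT_LEVELS = (3, 4, 5, 6, 7)
#: Octave scales per anchor position.
DEFAULT_SCALES = (1.0, 2.0 ** (1.0 / 3.0), 2.0 ** (2.0 / 3.0))
#: Aspect ratios h/w per anchor position.
DEFAULT_RATIOS = (0.5, 1.0, 2.0)


def validate_boxes(boxes: np.ndarray) -> np.ndarray:
    """Check the corner-order invariant and return a float64 (N, 4) view."""
    b = np.atleast_2d(np.asarray(boxes, dtype=np.float64))
    if b.shape[-1] != 4:
        raise ValueError(f"boxes must have 4 coordinates, got shape {b.shape}")
    if np.any(b[:, 2] < b[:, 0]) or np.any(b[:, 3] < b[:, 1]):
        raise ValueError("invalid box: max coordinate smaller than min coordinate")
    return b


def box_area(boxes: np.ndarray) -> np.ndarray:
    b = np.atleast_2d(np.asarray(boxes, dtype=np.float64))
    return (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])


def iou(a, b) -> float:
    """Intersection-over-union of two boxes; 0 when the union is degenerate."""
    a = validate_boxes(a)[0]
    b = validate_boxes(b)[0]
    ix = max(0.0, min(a[2], b[2]) - max(a[0], b[0]))
    iy = max(0.0, min(a[3], b[3]) - max(a[1], b[1]))
    inter = ix * iy
    union = box_area(a)[0] + box_area(b)[0] - inter
    return float(inter / union) if union > 0 else 0.0


def iou_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise IoU between box stacks; (len(a), len(b))."""
    a = validate_boxes(a)
    b = validate_boxes(b)
    ix = np.clip(
        np.minimum(a[:, None, 2], b[None, :, 2]) - np.maximum(a[:, None, 0], b[None, :, 0]),
        0.0,
        None,
    )
    iy = np.clip(
        np.minimum(a[:, None, 3], b[None, :, 3]) - np.maximum(a[:, None, 1], b[None, :, 1]),
        0.0,
        None,
    )
    inter = ix * iy
    union = box_area(a)[:, None] + box_area(b)[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(union > 0, inter / union, 0.0)
    return out


def _to_cxcywh(boxes: np.ndarray) -> np.ndarray:
    b = np.atleast_2d(np.asarray(boxes, dtype=np.float64))
    cx = 0.5 * (b[:, 0] + b[:, 2])
    cy = 0.5 * (b[:, 1] + b[:, 3])
    return np.stack([cx, cy, b[:, 2] - b[:, 0], b[:, 3] - b[:, 1]], axis=1)


def _to_xyxy(cxcywh: np.ndarray) -> np.ndarray:
    c = np.atleast_2d(cxcywh)
    half_w, half_h = 0.5 * c[:, 2], 0.5 * c[:, 3]
    return np.stack(
        [c[:, 0] - half_w, c[:, 1] - half_h, c[:, 0] + half_w, c[:, 1] + half_h], axis=1
    )


def encode(gt, anchors) -> np.ndarray:
    """Anchor-relative deltas ``(tx, ty, tw, th)`` in the R-CNN form.

    ``tx = (gx-ax)/aw``, ``tw = log(gw/aw)`` and analogously for y/h, where
    ``(gx, gy, gw, gh)`` is the ground-truth centre/size and
    ``(ax, ay, aw, ah)`` the anchor centre/size.
    """
    single = np.asarray(gt).ndim == 1
    g = _to_cxcywh(validate_boxes(gt))
    a = _to_cxcywh(validate_boxes(anchors))
    if np.any(a[:, 2] <= 0) or np.any(a[:, 3] <= 0):
        raise ValueError("anchors must have positive width and height")
    if np.any(g[:, 2] <= 0) or np.any(g[:, 3] <= 0):
        raise ValueError("ground-truth boxes must have positive area to be encoded")
    t = np.stack(
        [
            (g[:, 0] - a[:, 0]) / a[:, 2],
            (g[:, 1] - a[:, 1]) / a[:, 3],
            np.log(g[:, 2] / a[:, 2]),
            np.log(g[:, 3] / a[:, 3]),
        ],
        axis=1,
    )
    return t[0] if single else t


def decode(deltas, anchors, image_size: tuple[int, int] | None = None) -> np.ndarray:
    """Exact inverse of :func:`encode`; optionally clips to image bounds.

    ``image_size`` is ``(width, height)``.
    """
    single = np.asarray(deltas).ndim == 1
    t = np.atleast_2d(np.asarray(deltas, dtype=np.float64))
    if not np.all(np.isfinite(t)):
        raise ValueError("non-finite box deltas")
    a = _to_cxcywh(validate_boxes(anchors))
    cx = a[:, 0] + t[:, 0] * a[:, 2]
    cy = a[:, 1] + t[:, 1] * a[:, 3]
    w = a[:, 2] * np.exp(t[:, 2])
    h = a[:, 3] * np.exp(t[:, 3])
    out = _to_xyxy(np.stack([cx, cy, w, h], axis=1))
    if image_size is not None:
        iw, ih = image_size
        out[:, 0::2] = np.clip(out[:, 0::2], 0.0, iw)
        out[:, 1::2] = np.clip(out[:, 1::2], 0.0, ih)
    return out[0] if single else out


@dataclass(frozen=True)
class AnchorConfig:
    """Anchor layout: 3 octave scales x 3 aspect ratios, base size 4·stride."""

    levels: tuple[int, ...] = DEFAULT_LEVELS
    scales: tuple[float, ...] = DEFAULT_SCALES
    ratios: tuple[float, ...] = DEFAULT_RATIOS
    base_size_factor: float = 4.0

    @property
    def anchors_per_position(self) -> int:
        return len(self.scales) * len(self.ratios)


def feature_grid_size(image_size: tuple[int, int], level: int) -> tuple[int, int]:
    """(height, width) of the level-``level`` feature grid (ceil division)."""
    iw, ih = image_size
    stride = 2**level
    return -(-ih // stride), -(-iw // stride)


def generate_anchors(
    image_size: tuple[int, int], config: AnchorConfig = AnchorConfig()
) -> dict[int, np.ndarray]:
    """Per-level anchor sets for an image of size ``(width, height)``.

    Each level L carries ``len(scales) * len(ratios)`` anchors centred on
    every position of its stride-``2**L`` grid, with base size
    ``base_size_factor * stride``; cell shapes follow
    ``w = base*scale/sqrt(ratio)``, ``h = base*scale*sqrt(ratio)``.
    """
    iw, ih = image_size
    if iw <= 0 or ih <= 0:
        raise ValueError(f"image size must be positive, got {image_size}")
    out: dict[int, np.ndarray] = {}
    for level in config.levels:
        stride = 2**level
        gh, gw = feature_grid_size(image_size, level)
        base = config.base_size_factor * stride
        shapes = []
        for scale in config.scales:
            for ratio in config.ratios:
                w = base * scale / np.sqrt(ratio)
                h = base * scale * np.sqrt(ratio)
                shapes.append((w, h))
        shapes = np.asarray(shapes)  # (A, 2)
        cx = (np.arange(gw) + 0.5) * stride
        cy = (np.arange(gh) + 0.5) * stride
        cxg, cyg = np.meshgrid(cx, cy)  # (gh, gw)
        centers = np.stack([cxg, cyg], axis=-1).reshape(-1, 1, 2)  # (gh*gw, 1, 2)
        half = 0.5 * shapes.reshape(1, -1, 2)
        mins = centers - half
        maxs = centers + half
        out[level] = np.concatenate([mins, maxs], axis=-1).reshape(-1, 4)
    return out


def concat_anchors(per_level: dict[int, np.ndarray]) -> np.ndarray:
    """Stack per-level anchors in ascending level order into one (N, 4)."""
    return np.concatenate([per_level[lv] for lv in sorted(per_level)], axis=0)
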