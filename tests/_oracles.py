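"""Independent brute-force references shared by the test suite.

Everything here is deliberately written with plain loops over the scalar
:func:`weednet.boxes.iou`, sharing no code path with the vectorised
implementations it checks.
"""

import numpy as np

from weednet.boxes import box_area, iou
from weednet.postprocess import Detection


def brute_force_nms(dets, thresh):
    """O(n^2) greedy NMS with the same tie-breaks (score, area, order)."""
    order = sorted(
        range(len(dets)),
        key=lambda i: (-dets[i].score, -float(box_area(dets[i].box)[0]), i),
    )
    keep = []
    for i in order:
        if all(iou(dets[i].box, dets[k].box) <= thresh for k in keep):
            keep.append(i)
    return [dets[i] for i in keep]


def brute_force_crop_first(dets, thresh):
    crops = [d for d in dets if d.label == "sugarbeet"]
    out = []
    for d in dets:
        if d.label == "sugarbeet":
            out.append(d)
        elif all(iou(d.box, c.box) <= thresh for c in crops):
            out.append(d)
    return out


def random_detections(rng, n, labels=("weed",), size=100.0):
    dets = []
    for _ in range(n):
        x1, y1 = rng.uniform(0, size * 0.7, size=2)
        w, h = rng.uniform(3, size * 0.4, size=2)
        dets.append(
            Detection(
                box=np.array([x1, y1, x1 + w, y1 + h]),
                label=str(rng.choice(labels)),
                score=float(rng.uniform(0.01, 1.0)),
            )
        )
    return dets


def oracle_counts(dets, gts, iou_thresh):
    """Greedy matcher over (image_id, box, score) / (image_id, box) lists."""
    remaining = {}
    for img, box in gts:
        remaining.setdefault(img, []).append([box, False])
    tp = fp = 0
    for img, box, _ in sorted(dets, key=lambda d: -d[2]):
        best, best_iou = None, -1.0
        for entry in remaining.get(img, []):
            if entry[1]:
                continue
            v = iou(box, entry[0])
            if v > best_iou:
                best, best_iou = entry, v
        if best is not None and best_iou > iou_thresh:
            best[1] = True
            tp += 1
        else:
            fp += 1
    return tp, fp


def oracle_ap(dets, gts, iou_thresh, grid=20001):
    """Enumerate every score threshold; integrate the stepwise precision
    envelope numerically on a fine recall grid."""
    points = []
    for s in sorted({d[2] for d in dets}, reverse=True):
        sub = [d for d in dets if d[2] >= s]
        tp, fp = oracle_counts(sub, gts, iou_thresh)
        points.append((tp / len(gts), tp / (tp + fp)))
    rs = np.linspace(0.0, 1.0, grid)
    env = np.zeros(grid)
    for r, p in points:
        env[rs <= r] = np.maximum(env[rs <= r], p)
    return float(np.trapezoid(env, rs))


def random_eval_fixture(rng, n_dets=None, n_gts=None, n_images=2):
    """Detections/ground truths with a mix of near-hits and noise boxes."""
    gts, dets = [], []
    n_gts = int(rng.integers(1, 6)) if n_gts is None else n_gts
    n_dets = int(rng.integers(0, 11)) if n_dets is None else n_dets
    for _ in range(n_gts):
        img = f"im{rng.integers(n_images)}"
        x, y = rng.uniform(0, 60, 2)
        w, h = rng.uniform(8, 30, 2)
        gts.append((img, np.array([x, y, x + w, y + h])))
    for _ in range(n_dets):
        if len(gts) and rng.random() < 0.6:  # perturbed copy of some gt
            img, base = gts[rng.integers(len(gts))]
            box = base + rng.normal(0, 4, 4)
            box = np.array(
                [
                    min(box[0], box[2] - 1),
                    min(box[1], box[3] - 1),
                    max(box[0] + 1, box[2]),
                    max(box[1] + 1, box[3]),
                ]
            )
        else:
            img = f"im{rng.integers(n_images)}"
            x, y = rng.uniform(0, 60, 2)
            w, h = rng.uniform(8, 30, 2)
            box = np.array([x, y, x + w, y + h])
        dets.append((img, box, float(rng.uniform(0.05, 1.0))))
    return dets, gts
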