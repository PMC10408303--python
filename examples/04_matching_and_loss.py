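"""Anchor matching and the focal + smooth-L1 objective on one scene.

Shows how ground-truth plants claim positive anchors under the 0.5/0.4
IoU bands and what the Npos-normalised loss looks like for an untrained
predictor versus a perfect one.
"""

import numpy as np

from weednet.boxes import concat_anchors, encode, generate_anchors
from weednet.losses import FocalParams, detection_loss, focal_loss, match_anchors, smooth_l1
from weednet.model import CLASS_NAMES
from weednet.synthetic import SceneSpec, generate_scene

scene = generate_scene(SceneSpec(seed=7))
anchors = concat_anchors(generate_anchors((160, 160)))
gt_boxes = np.stack([a.box for a in scene.annotations])
gt_labels = np.array([CLASS_NAMES.index(a.label) for a in scene.annotations])

match = match_anchors(anchors, gt_boxes)
print(f"{len(anchors)} anchors, {len(gt_boxes)} objects")
print(f"positive {match.npos}, negative {int(match.negative_mask.sum())}, "
      f"ignored {int(match.ignore_mask.sum())}")
for j, ann in enumerate(scene.annotations):
    print(f"  {ann.label:<10} claims {int((match.states == j).sum()):3d} anchors")

print("\nfocal loss samples (alpha=0.25, gamma=2):")
for p in (0.1, 0.5, 0.9, 0.99):
    print(f"  p_t={p:4}: positive {focal_loss(p, 1):.5f}   negative {focal_loss(1-p, 0):.5f}")
print(f"smooth L1 at 0 / 1 / 3: {smooth_l1(0.0):.3f} / {smooth_l1(1.0):.3f} / {smooth_l1(3.0):.3f}")

# untrained predictor: logits at the background prior, zero deltas
prior = -np.log((1 - 0.01) / 0.01)
logits = np.full((len(anchors), 2), prior)
deltas = np.zeros((len(anchors), 4))
bundle, _, _ = detection_loss(logits, deltas, anchors, gt_boxes, gt_labels)
print(f"\nuntrained loss : cls {bundle.cls:.4f} + reg {bundle.reg:.4f} = {bundle.total:.4f}")

# perfect predictor: confident correct classes, exact box deltas
logits = np.full((len(anchors), 2), -40.0)
pos = np.nonzero(match.positive_mask)[0]
for i in pos:
    logits[i, gt_labels[match.states[i]]] = 40.0
    deltas[i] = encode(gt_boxes[match.states[i]], anchors[i])
bundle, _, _ = detection_loss(logits, deltas, anchors, gt_boxes, gt_labels)
print(f"perfect loss   : cls {bundle.cls:.4f} + reg {bundle.reg:.4f} = {bundle.total:.4f}")
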