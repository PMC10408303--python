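# Methods

## Problem setting

Detecting weeds among crop plants in nadir field imagery is a two-class
object-detection problem with an asymmetric cost structure: a weeding
actuator that destroys a crop plant does far more damage than one that
misses a weed. The package implements a one-stage anchor-based detector
specialised for this setting — context-enlarged receptive fields in the
neck, a warmup-annealed training schedule, and a cross-class suppression
rule biased toward the crop — together with the full evaluation stack
and a synthetic scene generator that makes every component testable at
desk scale.

## Architecture

**Backbone.** A residual network exposing the stride-8/16/32 stage
outputs C3–C5. The reference configuration is ResNet-50 (bottleneck
blocks 3/4/6/3); `resnet18` and a five-stage `tiny` backbone
(single basic blocks, widths 16–64) are config-selectable for CPU-scale
work. Only trainable tensors are counted in parameter audits: conv
kernels, conv biases where present, and batch-norm affine pairs —
batch-norm running statistics are buffers, not parameters.

**Feature pyramid.** 1x1 lateral projections of C3–C5 to 256 channels,
nearest-neighbour top-down summation, 3x3 smoothing on P3–P5. P6 is a
stride-2 3x3 conv on C5 (not on P5) and P7 a stride-2 3x3 conv on
ReLU(P6); with these choices the baseline audits at 36,350,582
parameters, printed 36.4M. Feature-grid sizes follow ceil division per
stride, so odd input sizes are handled without padding bookkeeping.

**Context modules.** Each module runs three branches over its input
P (C channels): `y1 = CB(P)`; `y2 = CB2(CBL1(P))`; `y3 =
CB3(CBL2(CBL1(P)))`, the stem CBL1 shared between y2 and y3. CB is a
3x3 conv (no bias) + batch norm; CBL adds a leaky ReLU (slope 0.01).
Branch depths 1/2/3 give receptive-field equivalents of 3x3/5x5/7x7
kernels — verified in the tests by impulse-response spread. The branch
outputs are concatenated, passed through a ReLU, and fused by a 3x3
conv (with bias) back to C channels, so the module preserves its input
shape exactly.

Branch widths are C/4 for y1 and C/8 for the stem and branches y2/y3,
giving a concatenation width of C/2. This split is a design choice
pinned by the parameter budget: at C=256 one module costs 544,384
trainable parameters, three modules 1,633,152, moving the detector from
36.4M to 38.0M — a 4.4% increase on the printed megaparameter values.
`context_levels` selects `none` (baseline), `p3-p5` (default; three
modules) or `p3-p7` (five modules, the wider ablation arm, +2 more
module counts).

**Heads.** Classification and regression towers of four 3x3 convs (256
channels, ReLU) shared across pyramid levels, with final convs to
`anchors x classes` and `anchors x 4`. "Shared" means each tower is
shared across levels, not that the two towers share weights with each
other — tower sharing between class and box branches would cut the
baseline to ~34M and contradict the 36.4M budget. Head convs initialise
with Gaussian sigma 0.01; the classification output bias starts at
`-log((1-pi)/pi)` with prior pi = 0.01 so an untrained detector
predicts background; backbone and pyramid convs use He initialisation
(the package trains from random weights; an ImageNet-pretrained start is
a config flag but no weights are bundled).

## Anchors, matching, loss

Nine anchors per position: octave scales {1, 2^(1/3), 2^(2/3)} x aspect
ratios {0.5, 1, 2}, base size 4x the level stride, centres at grid-cell
centres. Anchors match ground truth by max IoU: ≥ 0.5 positive (to the
argmax ground truth, ties to the lowest index), < 0.4 negative,
otherwise ignored. No best-anchor-per-ground-truth override is applied;
the synthetic generator's size ranges are chosen so every object
receives positive anchors under the plain rule (verified over hundreds
of scenes).

Classification is per-class sigmoid (background = all-negative) with
focal loss, alpha 0.25 and gamma 2; probabilities are clamped at 1e-6
before the log. Regression applies smooth L1 elementwise to the delta
residuals of positive anchors. Both sums are divided by the same
`max(Npos, 1)`; the clamp makes object-free images well defined (zero
regression loss, finite classification loss). The loss and its analytic
gradients w.r.t. logits and deltas are computed in closed form and
checked against finite differences; the trainer seeds reverse-mode
backpropagation with those gradients.

## Learning-rate schedule

`lr(t) = lr_init * omega(t) * 0.5 * (1 + cos(pi t / T))` with
`omega(t) = 1 - exp(-(1-beta2) t)`. The warmup factor is a function of
the optimiser's second-momentum coefficient alone — nominal period
`2/(1-beta2)` (2000 steps at beta2 = 0.999) — and is left active for
the whole run rather than switched off; it is within `1 - e^-2` of its
limit at the nominal period. The cosine factor is the standard
half-cosine annealed to zero over all T steps (no restart, no floor);
the annealing formula and the zero floor are design choices. Scheduling
is step-based with `T = epochs x ceil(N/batch)`. Reference defaults
mirror the training protocol the detector was designed under: Adam with
lr 1e-4, beta1 0.9, beta2 0.999, batch 8, 20 epochs, random horizontal
flipping, input resized to 640x640.

## Post-processing

Sigmoid scores are thresholded (per-level top-1000 pre-selection),
deltas decoded against anchors and clipped to the image, then per-class
greedy NMS at IoU 0.5 with deterministic tie-breaks (score, then larger
area, then input order) — the vectorised implementation is
property-tested against a plain O(n^2) reference.

**Crop-first NMS** then partitions detections into sugar-beet and weed
groups and deletes every weed box whose IoU with any sugar-beet box
strictly exceeds the threshold (default 0.5). Crop boxes are never
removed: an object claimed by both classes is resolved as crop, which
is the safe behaviour for a weeding robot. The rule is an
operating-point decision: it is applied in the deployment profile
(confidence ≥ 0.5, `NMSConfig.deployment()`) and off by default in the
dense evaluation profile (threshold 0.05), because over a dense
candidate set near-noise crop boxes would suppress confident correct
weed detections and the rule's published effect is measured at the 0.5
operating point. The evaluation API exposes the toggle for before/after
comparisons.

## Evaluation

Greedy confidence-ordered matching per image: each detection claims the
highest-IoU unmatched ground truth; a claim with IoU strictly above the
threshold (0.5 throughout) is a true positive, anything else a false
positive; unclaimed ground truths are false negatives. True negatives
have no box-level meaning in detection and are reported as
not-applicable. AP integrates the upper envelope of the
precision/recall curve over all detection scores (all-point
interpolation — the faithful discretisation of the continuous integral;
the 11-point variant would understate it, and AP values can shift ~1%
between flavours). mAP averages the per-class APs; a class with no
ground truth has undefined AP and is excluded rather than scored zero.
Tp/Fp/Fn operating-point counts use confidence ≥ 0.5. The AP
implementation is tested against an independent oracle that enumerates
every threshold and integrates the stepwise envelope numerically.

## Synthetic scenes

The generator renders what the detection task needs and nothing more: a
low-frequency brown soil texture with pixel grain; "sugarbeet" plants
as 5–8-lobed rosettes (footprint radius 22–31 px at the default 160 px
scene size, boxes ~45–62 px); "weed" plants as 3–5 thin blades crossing
a common centre (radius 15–20 px, boxes ~24–40 px). Both classes share
a green palette whose proximity is set by `color_similarity` (default
0.8), mirroring the colour/morphology resemblance that makes the real
task hard; the deliberate class separation is in shape and scale. Box
annotations are tight to the rendered mask (margin ≤ 1 px). Placement
resamples positions until pairwise tight-box IoU stays within the
overlap policy (default 0.10) and raises if the budget (60 tries per
plant) is exhausted. Scenes are byte-deterministic in the seed;
datasets derive per-scene seeds from a master seed.

What passing on this data shows: the assembled detector, loss,
schedule, decoding and scoring interoperate and can learn a two-class
localisation task from scratch. What it does not show: robustness to
real-field nuisance factors — occlusion, illumination, soil debris,
growth-stage variation, class imbalance — none of which the generator
models.

## Toy training benchmark

The CPU benchmark (`toy_run_config`) trains the `tiny` backbone with a
64-channel pyramid and 2-conv heads on 300 scenes of 160x160 for 5
epochs at batch 8 (~190 steps, about 90 s), holding out 30 validation
and 60 test scenes. Two schedule constants differ from the reference
defaults, for reasons intrinsic to the small run: lr_init 2e-3 (a small
network trained from random initialisation, no pretrained backbone) and
beta2 0.99, which sets the untuned warmup period to 200 steps —
commensurate with the run length, exactly the coupling the untuned rule
exists to provide. The benchmark asserts held-out mAP@0.5 ≥ 0.70; the
pinned seed reaches ~0.99, so the margin absorbs seed-to-seed
variation.

## Numerical choices and degenerate inputs

- float32 forward/backward; loss and geometry in float64.
- IoU of two zero-area boxes is 0 (degenerate union).
- Probability clamp 1e-6 in the focal loss; smooth L1 gradient is the
  clipped residual, continuous at the knee.
- `encode` rejects zero-area ground truth (log of zero); `decode`
  rejects non-finite deltas and clips to the image when a size is given.
- Empty ground truth: all anchors negative, Npos clamp keeps the loss
  finite; empty detection set: AP 0 (with ground truth present), AP
  undefined (without).
- VOC XML coordinates are 1-based integers on disk, 0-based continuous
  in memory; round trips are lossless up to coordinate rounding.
- Dataset split: floor(0.2 N) test (min 1), then floor(0.1 of the
  remainder) validation (min 1); the split is an exact partition and
  deterministic in the seed.

## Known limitations

- No pretrained backbone weights are shipped; reproducing field-data
  accuracy would additionally require the original imagery and far more
  compute than the CPU benchmark exercises.
- The numpy layer stack is single-threaded apart from BLAS matmuls;
  it is sized for the toy benchmark, not for 640x640 training.
- Letterboxed (aspect-preserving) resize is available behind a flag but
  the default pipeline distorts aspect, matching the square-resize
  convention the detector was designed under.
- Rotated boxes, masks, soft-NMS and COCO-style mAP@[.5:.95] are out of
  scope.
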