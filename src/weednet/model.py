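"""The crop/weed detector: backbone + feature pyramid + context modules +
shared prediction sub-nets, with an exact trainable-parameter audit.

Architecture summary
--------------------
A residual backbone supplies stage outputs C3-C5.  A feature pyramid builds
P3-P5 from them via 1x1 lateral connections, nearest-neighbour top-down
summation and 3x3 smoothing; P6 is a stride-2 3x3 convolution on C5 and P7
a stride-2 3x3 convolution on ReLU(P6).  Multi-branch context modules are
optionally inserted after the pyramid outputs (the three bottom levels
P3-P5 by default, all five levels for the wider ablation arm).  Shared
classification and regression towers (four 3x3 convolutions each, by
default) run over every level; the classification output uses per-class
sigmoid logits.

Context module
--------------
Three parallel branches over the input feature map P:

* ``y1 = CB(P)`` - one 3x3 conv + batch norm (3x3 receptive field);
* ``y2 = CB2(CBL1(P))`` - two stacked 3x3 convs (5x5-equivalent);
* ``y3 = CB3(CBL2(CBL1(P)))`` - three stacked convs (7x7-equivalent),
  where the first stem ``CBL1`` is shared with the ``y2`` branch.

``CB`` is conv + batch norm; ``CBL`` additionally applies a leaky ReLU.
The branches are concatenated channel-wise, passed through a ReLU, and a
final 3x3 fusion convolution maps back to the input channel count, so the
module preserves both the channel and the spatial shape of its input.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import nn
from .backbones import build_backbone
from .boxes import AnchorConfig
from .nn import Tensor

#: Class vocabulary; index 0 is the crop.
CLASS_NAMES = ("sugarbeet", "weed")

CONTEXT_LEVEL_CHOICES = {"none": (), "p3-p5": (3, 4, 5), "p3-p7": (3, 4, 5, 6, 7)}


@dataclass(frozen=True)
class ContextModuleConfig:
    """Channel widths of the context-module branches.

    Defaults follow the C/4 + C/8 + C/8 split, whose concatenation width
    C/2 keeps the per-module overhead at 544,384 parameters for C=256.
    """

    in_channels: int = 256
    branch1_out: int | None = None  # default C/4
    stem_out: int | None = None  # default C/8
    branch2_out: int | None = None  # default C/8
    branch3_out: int | None = None  # default C/8
    fusion_kernel: int = 3

    def resolved(self) -> "ContextModuleConfig":
        c = self.in_channels
        return replace(
            self,
            branch1_out=self.branch1_out if self.branch1_out is not None else c // 4,
            stem_out=self.stem_out if self.stem_out is not None else c // 8,
            branch2_out=self.branch2_out if self.branch2_out is not None else c // 8,
            branch3_out=self.branch3_out if self.branch3_out is not None else c // 8,
        )

    @property
    def concat_width(self) -> int:
        r = self.resolved()
        return r.branch1_out + r.branch2_out + r.branch3_out


@dataclass(frozen=True)
class ModelConfig:
    """Detector configuration.

    ``context_levels`` selects the variant: ``"none"`` is the plain
    one-stage baseline, ``"p3-p5"`` the context-augmented detector, and
    ``"p3-p7"`` the five-module ablation arm.
    """

    backbone: str = "resnet50"
    fpn_channels: int = 256
    num_classes: int = len(CLASS_NAMES)
    context_levels: str = "p3-p5"
    head_convs: int = 4
    anchors: AnchorConfig = field(default_factory=AnchorConfig)
    prior_prob: float = 0.01
    leaky_slope: float = 0.01

    def __post_init__(self):
        if self.context_levels not in CONTEXT_LEVEL_CHOICES:
            raise ValueError(
                f"context_levels must be one of {sorted(CONTEXT_LEVEL_CHOICES)}, "
                f"got {self.context_levels!r}"
            )


@dataclass(frozen=True)
class ParamCount:
    """Trainable-parameter audit with a per-component breakdown."""

    backbone: int
    pyramid: int
    heads: int
    context: int

    @property
    def total(self) -> int:
        return self.backbone + self.pyramid + self.heads + self.context

    def total_millions(self) -> float:
        """Total in megaparameters, rounded to one decimal (as printed)."""
        return round(self.total / 1e6, 1)

    def __str__(self) -> str:
        rows = [
            ("backbone", self.backbone),
            ("pyramid", self.pyramid),
            ("heads", self.heads),
            ("context", self.context),
            ("total", self.total),
        ]
        lines = [f"{name:<10}{count:>12,}" for name, count in rows]
        lines.append(f"{'':<10}{self.total_millions():>11.1f}M")
        return "\n".join(lines)


class ContextModule(nn.Module):
    def __init__(self, cfg: ContextModuleConfig, rng: np.random.Generator, leaky_slope=0.01):
        super().__init__()
        cfg = cfg.resolved()
        c = cfg.in_channels
        self.cb1_conv = nn.Conv2d(c, cfg.branch1_out, 3, bias=False, rng=rng)
        self.cb1_bn = nn.BatchNorm2d(cfg.branch1_out)
        self.cbl1_conv = nn.Conv2d(c, cfg.stem_out, 3, bias=False, rng=rng)
        self.cbl1_bn = nn.BatchNorm2d(cfg.stem_out)
        self.cb2_conv = nn.Conv2d(cfg.stem_out, cfg.branch2_out, 3, bias=False, rng=rng)
        self.cb2_bn = nn.BatchNorm2d(cfg.branch2_out)
        self.cbl2_conv = nn.Conv2d(cfg.stem_out, cfg.stem_out, 3, bias=False, rng=rng)
        self.cbl2_bn = nn.BatchNorm2d(cfg.stem_out)
        self.cb3_conv = nn.Conv2d(cfg.stem_out, cfg.branch3_out, 3, bias=False, rng=rng)
        self.cb3_bn = nn.BatchNorm2d(cfg.branch3_out)
        self.fusion = nn.Conv2d(cfg.concat_width, c, cfg.fusion_kernel, bias=True, rng=rng)
        self.leaky_slope = leaky_slope
        self.in_channels = c

    def forward(self, p: Tensor) -> Tensor:
        if p.shape[1] != self.in_channels:
            raise ValueError(
                f"context module expects {self.in_channels} channels, got {p.shape[1]}"
            )
        y1 = self.cb1_bn(self.cb1_conv(p))
        stem = nn.leaky_relu(self.cbl1_bn(self.cbl1_conv(p)), self.leaky_slope)
        y2 = self.cb2_bn(self.cb2_conv(stem))
        stem2 = nn.leaky_relu(self.cbl2_bn(self.cbl2_conv(stem)), self.leaky_slope)
        y3 = self.cb3_bn(self.cb3_conv(stem2))
        fused = nn.relu(nn.concat([y1, y2, y3], axis=1))
        return self.fusion(fused)


class FeaturePyramid(nn.Module):
    def __init__(self, in_channels: tuple[int, int, int], out_channels: int, rng):
        super().__init__()
        c3, c4, c5 = in_channels
        self.lateral3 = nn.Conv2d(c3, out_channels, 1, rng=rng)
        self.lateral4 = nn.Conv2d(c4, out_channels, 1, rng=rng)
        self.lateral5 = nn.Conv2d(c5, out_channels, 1, rng=rng)
        self.smooth3 = nn.Conv2d(out_channels, out_channels, 3, rng=rng)
        self.smooth4 = nn.Conv2d(out_channels, out_channels, 3, rng=rng)
        self.smooth5 = nn.Conv2d(out_channels, out_channels, 3, rng=rng)
        # P6 from the backbone's C5 (not P5), P7 from ReLU(P6)
        self.p6 = nn.Conv2d(c5, out_channels, 3, stride=2, rng=rng)
        self.p7 = nn.Conv2d(out_channels, out_channels, 3, stride=2, rng=rng)

    def forward(self, c3: Tensor, c4: Tensor, c5: Tensor) -> list[Tensor]:
        m5 = self.lateral5(c5)
        m4 = nn.add(self.lateral4(c4), nn.upsample_nearest(m5, c4.shape[2:]))
        m3 = nn.add(self.lateral3(c3), nn.upsample_nearest(m4, c3.shape[2:]))
        p3 = self.smooth3(m3)
        p4 = self.smooth4(m4)
        p5 = self.smooth5(m5)
        p6 = self.p6(c5)
        p7 = self.p7(nn.relu(p6))
        return [p3, p4, p5, p6, p7]


class PredictionHead(nn.Module):
    """Conv tower shared across pyramid levels; heads init with sigma=0.01."""

    def __init__(
        self,
        channels: int,
        out_per_anchor: int,
        anchors_per_pos: int,
        n_convs: int,
        rng,
        out_bias_init: float = 0.0,
    ):
        super().__init__()
        tower = []
        for _ in range(n_convs):
            tower.append(nn.Conv2d(channels, channels, 3, rng=rng, init_std=0.01))
            tower.append(nn.ReLU())
        self.tower = nn.Sequential(*tower)
        self.out_per_anchor = out_per_anchor
        self.anchors_per_pos = anchors_per_pos
        self.out_conv = nn.Conv2d(
            channels, anchors_per_pos * out_per_anchor, 3, rng=rng, init_std=0.01
        )
        self.out_conv.bias.data[:] = out_bias_init

    def forward(self, x: Tensor) -> Tensor:
        """Returns (N, H*W*A, out_per_anchor) with anchor index fastest."""
        out = self.out_conv(self.tower(x))
        n, _, h, w = out.shape
        out = nn.reshape(out, (n, self.anchors_per_pos, self.out_per_anchor, h, w))
        out = nn.transpose(out, (0, 3, 4, 1, 2))
        return nn.reshape(out, (n, h * w * self.anchors_per_pos, self.out_per_anchor))


class Detector(nn.Module):
    """Assembled one-stage detector; see the module docstring."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.config = config
        self.backbone = build_backbone(config.backbone, rng)
        self.fpn = FeaturePyramid(self.backbone.out_channels, config.fpn_channels, rng)
        ctx_levels = CONTEXT_LEVEL_CHOICES[config.context_levels]
        self.context_levels = ctx_levels
        self.context_modules = [
            ContextModule(
                ContextModuleConfig(in_channels=config.fpn_channels),
                rng,
                config.leaky_slope,
            )
            for _ in ctx_levels
        ]
        a = config.anchors.anchors_per_position
        pi = config.prior_prob
        cls_bias = -float(np.log((1.0 - pi) / pi))
        self.cls_head = PredictionHead(
            config.fpn_channels, config.num_classes, a, config.head_convs, rng, cls_bias
        )
        self.reg_head = PredictionHead(config.fpn_channels, 4, a, config.head_convs, rng)

    def forward(self, images) -> list[tuple[Tensor, Tensor]]:
        """Per-level raw outputs for a batch of images.

        ``images``: float array or Tensor of shape (N, 3, H, W).  Returns a
        list ordered P3..P7 of ``(class_logits, box_deltas)`` pairs shaped
        ``(N, H_l*W_l*A, num_classes)`` and ``(N, H_l*W_l*A, 4)``; logits
        are raw (the loss and the post-processing apply the sigmoid).
        """
        if not isinstance(images, Tensor):
            images = Tensor(images)
        if images.ndim != 4 or images.shape[1] != 3:
            raise ValueError(f"expected (N, 3, H, W) images, got shape {images.shape}")
        c3, c4, c5 = self.backbone(images)
        pyramid = self.fpn(c3, c4, c5)
        levels = list(self.config.anchors.levels)
        for module, level in zip(self.context_modules, self.context_levels):
            idx = levels.index(level)
            pyramid[idx] = module(pyramid[idx])
        return [(self.cls_head(p), self.reg_head(p)) for p in pyramid]


def build_model(config: ModelConfig, seed: int = 0) -> Detector:
    return Detector(config, seed=seed)


def count_parameters(model: Detector) -> ParamCount:
    """Exact trainable-parameter audit (conv kernels, biases, BN affine)."""

    def count(module_or_list) -> int:
        modules = module_or_list if isinstance(module_or_list, list) else [module_or_list]
        return int(sum(m.num_parameters() for m in modules))

    return ParamCount(
        backbone=count(model.backbone),
        pyramid=count(model.fpn),
        heads=count(model.cls_head) + count(model.reg_head),
        context=count(model.context_modules),
    )
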