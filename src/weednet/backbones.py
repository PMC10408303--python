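"""Feature-extraction backbones.

``resnet50`` (bottleneck blocks, stage widths 256/512/1024/2048) is the
reference backbone whose parameter budget the audit targets; ``resnet18``
and ``tiny`` are lighter config-selectable alternatives for CPU-scale
experiments.  Every backbone returns the stride-8/16/32 stage outputs
(C3, C4, C5) consumed by the feature pyramid.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .nn import Tensor


class BasicBlock(nn.Module):
    expansion = 1

    def __init__(self, in_ch: int, planes: int, stride: int, rng: np.random.Generator):
        super().__init__()
        out_ch = planes * self.expansion
        self.conv1 = nn.Conv2d(in_ch, planes, 3, stride=stride, bias=False, rng=rng)
        self.bn1 = nn.BatchNorm2d(planes)
        self.conv2 = nn.Conv2d(planes, planes, 3, bias=False, rng=rng)
        self.bn2 = nn.BatchNorm2d(planes)
        if stride != 1 or in_ch != out_ch:
            self.down_conv = nn.Conv2d(in_ch, out_ch, 1, stride=stride, bias=False, rng=rng)
            self.down_bn = nn.BatchNorm2d(out_ch)
        else:
            self.down_conv = None
            self.down_bn = None

    def forward(self, x: Tensor) -> Tensor:
        identity = x
        out = nn.relu(self.bn1(self.conv1(x)))
        out = self.bn2(self.conv2(out))
        if self.down_conv is not None:
            identity = self.down_bn(self.down_conv(x))
        return nn.relu(nn.add(out, identity))


class Bottleneck(nn.Module):
    expansion = 4

    def __init__(self, in_ch: int, planes: int, stride: int, rng: np.random.Generator):
        super().__init__()
        out_ch = planes * self.expansion
        self.conv1 = nn.Conv2d(in_ch, planes, 1, bias=False, rng=rng)
        self.bn1 = nn.BatchNorm2d(planes)
        self.conv2 = nn.Conv2d(planes, planes, 3, stride=stride, bias=False, rng=rng)
        self.bn2 = nn.BatchNorm2d(planes)
        self.conv3 = nn.Conv2d(planes, out_ch, 1, bias=False, rng=rng)
        self.bn3 = nn.BatchNorm2d(out_ch)
        if stride != 1 or in_ch != out_ch:
            self.down_conv = nn.Conv2d(in_ch, out_ch, 1, stride=stride, bias=False, rng=rng)
            self.down_bn = nn.BatchNorm2d(out_ch)
        else:
            self.down_conv = None
            self.down_bn = None

    def forward(self, x: Tensor) -> Tensor:
        identity = x
        out = nn.relu(self.bn1(self.conv1(x)))
        out = nn.relu(self.bn2(self.conv2(out)))
        out = self.bn3(self.conv3(out))
        if self.down_conv is not None:
            identity = self.down_bn(self.down_conv(x))
        return nn.relu(nn.add(out, identity))


class ResNetBackbone(nn.Module):
    """Residual backbone with the standard 7x7 stem and four stages."""

    def __init__(self, block, layers: tuple[int, int, int, int], rng: np.random.Generator):
        super().__init__()
        self.conv1 = nn.Conv2d(3, 64, 7, stride=2, padding=3, bias=False, rng=rng)
        self.bn1 = nn.BatchNorm2d(64)
        self.maxpool = nn.MaxPool2d(3, 2, 1)
        self._in_ch = 64
        self.layer1 = self._make_stage(block, 64, layers[0], 1, rng)
        self.layer2 = self._make_stage(block, 128, layers[1], 2, rng)
        self.layer3 = self._make_stage(block, 256, layers[2], 2, rng)
        self.layer4 = self._make_stage(block, 512, layers[3], 2, rng)
        self.out_channels = (
            128 * block.expansion,
            256 * block.expansion,
            512 * block.expansion,
        )

    def _make_stage(self, block, planes: int, n_blocks: int, stride: int, rng):
        blocks = [block(self._in_ch, planes, stride, rng)]
        self._in_ch = planes * block.expansion
        for _ in range(n_blocks - 1):
            blocks.append(block(self._in_ch, planes, 1, rng))
        return nn.Sequential(*blocks)

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor, Tensor]:
        x = self.maxpool(nn.relu(self.bn1(self.conv1(x))))
        c2 = self.layer1(x)
        c3 = self.layer2(c2)
        c4 = self.layer3(c3)
        c5 = self.layer4(c4)
        return c3, c4, c5


class TinyBackbone(nn.Module):
    """Five stride-2 stages of single residual blocks; for CPU-scale runs."""

    def __init__(self, rng: np.random.Generator, widths=(16, 24, 32, 48, 64)):
        super().__init__()
        w0, w1, w2, w3, w4 = widths
        self.stem = nn.Sequential(
            nn.Conv2d(3, w0, 3, stride=2, bias=False, rng=rng),
            nn.BatchNorm2d(w0),
            nn.ReLU(),
        )
        self.stage1 = BasicBlock(w0, w1, 2, rng)
        self.stage2 = BasicBlock(w1, w2, 2, rng)
        self.stage3 = BasicBlock(w2, w3, 2, rng)
        self.stage4 = BasicBlock(w3, w4, 2, rng)
        self.out_channels = (w2, w3, w4)

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor, Tensor]:
        x = self.stem(x)
        c2 = self.stage1(x)
        c3 = self.stage2(c2)
        c4 = self.stage3(c3)
        c5 = self.stage4(c4)
        return c3, c4, c5


_BACKBONES = {
    "resnet50": lambda rng: ResNetBackbone(Bottleneck, (3, 4, 6, 3), rng),
    "resnet18": lambda rng: ResNetBackbone(BasicBlock, (2, 2, 2, 2), rng),
    "tiny": lambda rng: TinyBackbone(rng),
}


def build_backbone(name: str, rng: np.random.Generator):
    try:
        factory = _BACKBONES[name]
    except KeyError:
        raise ValueError(f"unknown backbone {name!r}; choose from {sorted(_BACKBONES)}") from None
    return factory(rng)
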