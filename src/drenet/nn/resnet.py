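"""Residual feature extractor (ResNet-v1 bottleneck design).

The default configuration is the standard 50-layer network with its
classification layers removed: stem (7x7/2 conv, 3x3/2 max pool), four
bottleneck stages of (3, 4, 6, 3) blocks, and a global average pool that
yields a flat 2048-dimensional feature vector.  Stage outputs can be
captured for shape audits and activation maps.
"""

from __future__ import annotations

import numpy as np

from .layers import (BatchNorm2d, Conv2d, GlobalAvgPool, MaxPool2d, Module,
                     ReLU)

__all__ = ["Bottleneck", "ResNetFeatures", "resnet50_config"]


class Bottleneck(Module):
    """1x1 -> 3x3 -> 1x1 residual block with optional projection shortcut."""

    def __init__(self, in_ch: int, mid_ch: int, out_ch: int, stride: int, *,
                 rng: np.random.Generator, dtype=np.float32) -> None:
        self.conv1 = Conv2d(in_ch, mid_ch, 1, rng=rng, dtype=dtype)
        self.bn1 = BatchNorm2d(mid_ch, dtype=dtype)
        self.conv2 = Conv2d(mid_ch, mid_ch, 3, stride=stride, padding=1, rng=rng, dtype=dtype)
        self.bn2 = BatchNorm2d(mid_ch, dtype=dtype)
        self.conv3 = Conv2d(mid_ch, out_ch, 1, rng=rng, dtype=dtype)
        self.bn3 = BatchNorm2d(out_ch, dtype=dtype)
        self.relu1, self.relu2, self.relu3 = ReLU(), ReLU(), ReLU()
        if stride != 1 or in_ch != out_ch:
            self.down_conv = Conv2d(in_ch, out_ch, 1, stride=stride, rng=rng, dtype=dtype)
            self.down_bn = BatchNorm2d(out_ch, dtype=dtype)
        else:
            self.down_conv = None
            self.down_bn = None

    def forward(self, x, train=False):
        out = self.relu1(self.bn1(self.conv1(x, train), train), train)
        out = self.relu2(self.bn2(self.conv2(out, train), train), train)
        out = self.bn3(self.conv3(out, train), train)
        if self.down_conv is not None:
            shortcut = self.down_bn(self.down_conv(x, train), train)
        else:
            shortcut = x
        return self.relu3(out + shortcut, train)

    def backward(self, dy):
        d = self.relu3.backward(dy)
        dshort = d
        dx = self.conv3.backward(self.bn3.backward(d))
        dx = self.conv2.backward(self.bn2.backward(self.relu2.backward(dx)))
        dx = self.conv1.backward(self.bn1.backward(self.relu1.backward(dx)))
        if self.down_conv is not None:
            dx = dx + self.down_conv.backward(self.down_bn.backward(dshort))
        else:
            dx = dx + dshort
        return dx


def resnet50_config() -> dict:
    return {"blocks": (3, 4, 6, 3), "base_width": 64, "expansion": 4}


class ResNetFeatures(Module):
    """Truncated residual network: image -> flat feature vector."""

    def __init__(self, blocks=(3, 4, 6, 3), base_width: int = 64, expansion: int = 4,
                 in_ch: int = 3, *, rng: np.random.Generator, dtype=np.float32) -> None:
        self.conv1 = Conv2d(in_ch, base_width, 7, stride=2, padding=3, rng=rng, dtype=dtype)
        self.bn1 = BatchNorm2d(base_width, dtype=dtype)
        self.relu1 = ReLU()
        self.maxpool = MaxPool2d(3, 2, padding=1)
        self.stages: list[list[Bottleneck]] = []
        ch = base_width
        for i, n_blocks in enumerate(blocks):
            mid = base_width * (2 ** i)
            out_ch = mid * expansion
            stage = []
            for b in range(n_blocks):
                stride = 2 if (b == 0 and i > 0) else 1
                stage.append(Bottleneck(ch, mid, out_ch, stride, rng=rng, dtype=dtype))
                ch = out_ch
            self.stages.append(stage)
        self.gap = GlobalAvgPool()
        self.feature_dim = ch
        self.stage_names = ["Conv 1", "Max Pooling"] + \
            [f"Conv {i + 2}_x" for i in range(len(blocks))] + ["Average Pooling"]

    def forward(self, x, train=False, capture: dict | None = None):
        if capture is not None:
            capture["Image Input"] = x
        x = self.relu1(self.bn1(self.conv1(x, train), train), train)
        if capture is not None:
            capture["Conv 1"] = x
        x = self.maxpool(x, train)
        if capture is not None:
            capture["Max Pooling"] = x
        for i, stage in enumerate(self.stages):
            for block in stage:
                x = block(x, train)
            if capture is not None:
                capture[f"Conv {i + 2}_x"] = x
        x = self.gap(x, train)
        if capture is not None:
            capture["Average Pooling"] = x
        return x

    def backward(self, dy):
        dy = self.gap.backward(dy)
        for stage in reversed(self.stages):
            for block in reversed(stage):
                dy = block.backward(dy)
        dy = self.maxpool.backward(dy)
        return self.conv1.backward(self.bn1.backward(self.relu1.backward(dy)))
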