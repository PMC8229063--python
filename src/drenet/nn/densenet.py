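"""Densely connected feature extractor.

Default configuration is the 201-layer variant truncated before
classification: stem, four dense blocks of (6, 12, 48, 32) layers with
growth rate 32 and halving transitions, a final batch norm, and a global
average pool producing a flat 1920-dimensional feature vector.
"""

from __future__ import annotations

import numpy as np

from .layers import (AvgPool2d, BatchNorm2d, Conv2d, GlobalAvgPool, MaxPool2d,
                     Module, ReLU)

__all__ = ["DenseLayer", "DenseBlock", "Transition", "DenseNetFeatures",
           "densenet201_config"]


class DenseLayer(Module):
    """BN-ReLU-1x1(bn_size*g) -> BN-ReLU-3x3(g) composite producing g new channels."""

    def __init__(self, in_ch: int, growth: int, bn_size: int, *,
                 rng: np.random.Generator, dtype=np.float32) -> None:
        mid = bn_size * growth
        self.bn1 = BatchNorm2d(in_ch, dtype=dtype)
        self.relu1 = ReLU()
        self.conv1 = Conv2d(in_ch, mid, 1, rng=rng, dtype=dtype)
        self.bn2 = BatchNorm2d(mid, dtype=dtype)
        self.relu2 = ReLU()
        self.conv2 = Conv2d(mid, growth, 3, padding=1, rng=rng, dtype=dtype)

    def forward(self, x, train=False):
        out = self.conv1(self.relu1(self.bn1(x, train), train), train)
        out = self.conv2(self.relu2(self.bn2(out, train), train), train)
        return out

    def backward(self, dy):
        dx = self.bn2.backward(self.relu2.backward(self.conv2.backward(dy)))
        dx = self.bn1.backward(self.relu1.backward(self.conv1.backward(dx)))
        return dx


class DenseBlock(Module):
    def __init__(self, in_ch: int, n_layers: int, growth: int, bn_size: int, *,
                 rng: np.random.Generator, dtype=np.float32) -> None:
        self.growth = growth
        self.in_ch = in_ch
        self.dense_layers = [
            DenseLayer(in_ch + i * growth, growth, bn_size, rng=rng, dtype=dtype)
            for i in range(n_layers)
        ]
        self.out_ch = in_ch + n_layers * growth

    def forward(self, x, train=False):
        feats = x
        for layer in self.dense_layers:
            new = layer(feats, train)
            feats = np.concatenate([feats, new], axis=1)
        return feats

    def backward(self, dy):
        # dy covers the final concatenation [x | y1 | ... | yL]; walk the
        # layers in reverse, folding each layer's input gradient back into
        # the gradient of the growing prefix.
        g = dy.copy()
        for i in range(len(self.dense_layers) - 1, -1, -1):
            layer = self.dense_layers[i]
            lo = self.in_ch + i * self.growth
            dnew = g[:, lo:lo + self.growth]
            dprefix = layer.backward(np.ascontiguousarray(dnew))
            g[:, :lo] += dprefix
        return np.ascontiguousarray(g[:, :self.in_ch])


class Transition(Module):
    """BN-ReLU-1x1 compression followed by 2x2/2 average pooling."""

    def __init__(self, in_ch: int, out_ch: int, *, rng: np.random.Generator,
                 dtype=np.float32) -> None:
        self.bn = BatchNorm2d(in_ch, dtype=dtype)
        self.relu = ReLU()
        self.conv = Conv2d(in_ch, out_ch, 1, rng=rng, dtype=dtype)
        self.pool = AvgPool2d(2, 2)

    def forward(self, x, train=False):
        return self.pool(self.conv(self.relu(self.bn(x, train), train), train), train)

    def backward(self, dy):
        return self.bn.backward(self.relu.backward(self.conv.backward(self.pool.backward(dy))))


def densenet201_config() -> dict:
    return {"blocks": (6, 12, 48, 32), "growth": 32, "init_ch": 64, "bn_size": 4}


class DenseNetFeatures(Module):
    """Truncated densely connected network: image -> flat feature vector."""

    def __init__(self, blocks=(6, 12, 48, 32), growth: int = 32, init_ch: int = 64,
                 bn_size: int = 4, in_ch: int = 3, *, rng: np.random.Generator,
                 dtype=np.float32) -> None:
        self.conv1 = Conv2d(in_ch, init_ch, 7, stride=2, padding=3, rng=rng, dtype=dtype)
        self.bn1 = BatchNorm2d(init_ch, dtype=dtype)
        self.relu1 = ReLU()
        self.maxpool = MaxPool2d(3, 2, padding=1)
        self.blocks: list[DenseBlock] = []
        self.transitions: list[Transition] = []
        ch = init_ch
        for i, n_layers in enumerate(blocks):
            block = DenseBlock(ch, n_layers, growth, bn_size, rng=rng, dtype=dtype)
            self.blocks.append(block)
            ch = block.out_ch
            if i < len(blocks) - 1:
                tr = Transition(ch, ch // 2, rng=rng, dtype=dtype)
                self.transitions.append(tr)
                ch = ch // 2
        self.bn_final = BatchNorm2d(ch, dtype=dtype)
        self.relu_final = ReLU()
        self.gap = GlobalAvgPool()
        self.feature_dim = ch
        self.stage_names = ["Conv 1", "Max Pooling"]
        for i in range(len(blocks)):
            self.stage_names.append(f"DenseBlock_{i + 1}")
            if i < len(blocks) - 1:
                self.stage_names.append(f"Transition Layer {i + 1}")
        self.stage_names.append("Average Pooling")

    def forward(self, x, train=False, capture: dict | None = None):
        if capture is not None:
            capture["Image Input"] = x
        x = self.relu1(self.bn1(self.conv1(x, train), train), train)
        if capture is not None:
            capture["Conv 1"] = x
        x = self.maxpool(x, train)
        if capture is not None:
            capture["Max Pooling"] = x
        for i, block in enumerate(self.blocks):
            x = block(x, train)
            if capture is not None:
                capture[f"DenseBlock_{i + 1}"] = x
            if i < len(self.transitions):
                x = self.transitions[i](x, train)
                if capture is not None:
                    capture[f"Transition Layer {i + 1}"] = x
        x = self.relu_final(self.bn_final(x, train), train)
        x = self.gap(x, train)
        if capture is not None:
            capture["Average Pooling"] = x
        return x

    def backward(self, dy):
        dy = self.gap.backward(dy)
        dy = self.bn_final.backward(self.relu_final.backward(dy))
        for i in range(len(self.blocks) - 1, -1, -1):
            if i < len(self.transitions):
                dy = self.transitions[i].backward(dy)
            dy = self.blocks[i].backward(dy)
        dy = self.maxpool.backward(dy)
        return self.conv1.backward(self.bn1.backward(self.relu1.backward(dy)))
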