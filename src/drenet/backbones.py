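"""The two truncated feature extractors and their diagnostics.

``resnet50_modified`` and ``densenet201_modified`` are the standard
50-layer residual and 201-layer densely connected networks with their
classification layers (fully connected, softmax, output) removed, so each
maps a 224x224x3 image to a flat feature vector: 2048 dimensions for the
residual network (f1) and 1920 for the dense network (f2).

Extractors are deterministic in inference mode.  ``pretrained=False``
(the default) draws seeded random weights; ``pretrained=True`` requires a
caller-supplied ``.npz`` weight bundle, since no weight download is
performed by this package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .nn import DenseNetFeatures, Linear, Module, ResNetFeatures
from .nn.layers import BatchNorm2d

logger = logging.getLogger(__name__)

__all__ = [
    "ARCH_FEATURE_DIMS", "IMAGENET_MEAN", "IMAGENET_STD",
    "FeatureExtractorSpec", "FeatureExtractor", "build_extractor",
    "stage_shapes", "attach_temp_head", "TempClassifier",
    "block_activation_map", "activation_map_stages", "calibrate_batchnorm",
]

ARCH_FEATURE_DIMS = {"resnet50_modified": 2048, "densenet201_modified": 1920}
IMAGENET_MEAN = np.array([0.485, 0.456, 0.406], dtype=np.float32)
IMAGENET_STD = np.array([0.229, 0.224, 0.225], dtype=np.float32)


@dataclass
class FeatureExtractorSpec:
    """What to build: architecture, initialization, input geometry."""

    arch: str
    pretrained: bool = False
    expected_feature_dim: int | None = None
    seed: int = 0
    input_size: int = 224
    weights_path: str | None = None
    dtype: type = np.float32

    def __post_init__(self) -> None:
        if self.arch not in ARCH_FEATURE_DIMS:
            raise ValueError(
                f"unknown arch {self.arch!r}; expected one of {sorted(ARCH_FEATURE_DIMS)}")
        dim = ARCH_FEATURE_DIMS[self.arch]
        if self.expected_feature_dim is None:
            self.expected_feature_dim = dim
        elif self.expected_feature_dim != dim:
            raise ValueError(
                f"{self.arch} produces {dim}-d features, not {self.expected_feature_dim}")


class FeatureExtractor:
    """A built backbone plus its preprocessing conventions."""

    def __init__(self, spec: FeatureExtractorSpec, net: Module) -> None:
        self.spec = spec
        self.net = net
        self.feature_dim = net.feature_dim

    # --- preprocessing -------------------------------------------------
    def preprocess(self, images) -> np.ndarray:
        """uint8 images (H,W) or (H,W,3) -> (N,3,S,S) float32 network input."""
        if isinstance(images, np.ndarray) and images.ndim in (2, 3) \
                and (images.ndim == 2 or images.shape[2] in (1, 3)):
            images = [images]
        size = self.spec.input_size
        batch = np.empty((len(images), 3, size, size), dtype=np.float32)
        for i, img in enumerate(images):
            arr = np.asarray(img)
            if arr.ndim == 2:
                arr = np.repeat(arr[:, :, None], 3, axis=2)
            elif arr.shape[2] == 1:
                arr = np.repeat(arr, 3, axis=2)
            if arr.shape[0] != size or arr.shape[1] != size:
                arr = np.asarray(Image.fromarray(arr.astype(np.uint8)).resize(
                    (size, size), Image.Resampling.BILINEAR))
            x = arr.astype(np.float32) / 255.0
            if self.spec.pretrained:
                x = (x - IMAGENET_MEAN) / IMAGENET_STD
            batch[i] = x.transpose(2, 0, 1)
        return batch

    # --- feature extraction --------------------------------------------
    def features(self, images, batch_size: int = 16) -> np.ndarray:
        """Inference-mode feature matrix, (N, feature_dim)."""
        x = self.preprocess(images)
        out = np.empty((x.shape[0], self.feature_dim), dtype=np.float32)
        for i in range(0, x.shape[0], batch_size):
            out[i:i + batch_size] = self.net(x[i:i + batch_size], train=False)
        return out

    def __call__(self, images, batch_size: int = 16) -> np.ndarray:
        return self.features(images, batch_size=batch_size)

    # --- persistence ---------------------------------------------------
    def save_weights(self, path: str | Path) -> None:
        np.savez_compressed(path, **self.net.state_dict())

    def load_weights(self, path: str | Path) -> None:
        with np.load(path) as data:
            self.net.load_state_dict({k: data[k] for k in data.files})


def build_extractor(spec: FeatureExtractorSpec) -> FeatureExtractor:
    """Build a feature extractor; no classification layers are attached."""
    rng = np.random.default_rng(spec.seed)
    if spec.arch == "resnet50_modified":
        net = ResNetFeatures(rng=rng, dtype=spec.dtype)
    else:
        net = DenseNetFeatures(rng=rng, dtype=spec.dtype)
    extractor = FeatureExtractor(spec, net)
    if spec.pretrained:
        if spec.weights_path is None:
            raise ValueError(
                "pretrained=True needs a weights_path pointing at an .npz weight "
                "bundle; this package does not download weights")
        extractor.load_weights(spec.weights_path)
    return extractor


def stage_shapes(extractor: FeatureExtractor,
                 input_size: int | None = None) -> list[tuple[str, int, int, int]]:
    """Audit table of (stage name, height, width, channels) per stage."""
    size = input_size or extractor.spec.input_size
    x = np.zeros((1, 3, size, size), dtype=np.float32)
    capture: dict[str, np.ndarray] = {}
    extractor.net.forward(x, train=False, capture=capture)
    table = []
    for name, act in capture.items():
        if act.ndim == 4:
            _, c, h, w = act.shape
        else:
            c, h, w = act.shape[1], 1, 1
        table.append((name, h, w, c))
    return table


def activation_map_stages(extractor: FeatureExtractor) -> list[str]:
    """The five stages whose maps are reported (post max-pool + four blocks)."""
    names = extractor.net.stage_names
    return [n for n in names
            if n == "Max Pooling" or n.startswith(("Conv ", "DenseBlock_"))
            and n != "Conv 1"]


def block_activation_map(extractor: FeatureExtractor, image, stage: str) -> np.ndarray:
    """Channel-mean activation of ``stage``, min-max normalized, upsampled.

    Returns a (S, S) float map in [0, 1] at the extractor's input size.
    """
    x = extractor.preprocess([image])
    capture: dict[str, np.ndarray] = {}
    extractor.net.forward(x, train=False, capture=capture)
    valid = [n for n in capture if capture[n].ndim == 4 and n != "Image Input"]
    if stage not in valid:
        raise ValueError(f"unknown stage {stage!r}; valid stages: {valid}")
    act = capture[stage][0]                      # (C, h, w)
    heat = act.mean(axis=0)
    lo, hi = heat.min(), heat.max()
    heat = np.zeros_like(heat) if hi - lo == 0 else (heat - lo) / (hi - lo)
    size = extractor.spec.input_size
    up = Image.fromarray((heat * 255).astype(np.uint8)).resize(
        (size, size), Image.Resampling.BILINEAR)
    return np.asarray(up, dtype=np.float64) / 255.0


class TempClassifier:
    """Backbone + temporary fully-connected softmax head.

    Used to fine-tune a backbone standalone; ``detach`` discards the head
    without touching the extractor's parameters.
    """

    def __init__(self, extractor: FeatureExtractor, num_classes: int,
                 seed: int = 0) -> None:
        if num_classes < 2:
            raise ValueError("num_classes must be >= 2")
        rng = np.random.default_rng(seed)
        self.extractor = extractor
        self.head = Linear(extractor.feature_dim, num_classes,
                           rng=rng, dtype=extractor.spec.dtype)
        self.num_classes = num_classes

    def logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        feats = self.extractor.net(x, train=train)
        return self.head(feats, train=train)

    def predict_proba(self, images) -> np.ndarray:
        from .ensemble import softmax_probs
        z = self.logits(self.extractor.preprocess(images))
        return softmax_probs(z)

    def parameters(self):
        return self.extractor.net.parameters() + self.head.parameters()

    def detach(self) -> FeatureExtractor:
        return self.extractor


def attach_temp_head(extractor: FeatureExtractor, num_classes: int,
                     seed: int = 0) -> TempClassifier:
    return TempClassifier(extractor, num_classes, seed=seed)


def calibrate_batchnorm(extractor: FeatureExtractor, images,
                        batch_size: int = 32) -> None:
    """Set batch-norm running statistics from one pass over ``images``.

    Random-initialized batch norms carry (0, 1) running statistics that do
    not match the activation scale of a given dataset; one calibration
    pass replaces them with observed statistics.  Inference afterwards
    stays deterministic and batch-independent.
    """
    x = extractor.preprocess(images)[:batch_size]
    bns = [m for m in extractor.net.modules() if isinstance(m, BatchNorm2d)]
    saved = [bn.momentum for bn in bns]
    for bn in bns:
        bn.momentum = 1.0
    try:
        extractor.net.forward(x, train=True)
    finally:
        for bn, m in zip(bns, saved):
            bn.momentum = m
            bn._cache = None
    for m in extractor.net.modules():
        for attr in ("_cache", "_mask", "_x"):
            if hasattr(m, attr):
                setattr(m, attr, None)
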