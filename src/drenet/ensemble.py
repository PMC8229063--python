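"""The ensemble assembly: feature concatenation, the shallow concatenation
network (SCN) head, and end-to-end prediction.

The SCN takes the residual-network feature vector f1 (2048-d) and the
dense-network feature vector f2 (1920-d), concatenates them into
f = [f1 | f2] (3968-d, order fixed), applies a single fully connected
layer z_j = sum_l w_{j,l} f_l + b_j, and a softmax
p_i = exp(z_i) / sum_j exp(z_j) over the K = 4 manufacturer classes.
Softmax is computed with max-subtraction, which is mathematically
identical and numerically stable.  Argmax ties break toward the lowest
class index.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .backbones import FeatureExtractor, FeatureExtractorSpec, build_extractor
from .synthetic import CLASS_LABELS

logger = logging.getLogger(__name__)

RESNET_DIM, DENSENET_DIM = 2048, 1920
CONCAT_DIM = RESNET_DIM + DENSENET_DIM

__all__ = [
    "RESNET_DIM", "DENSENET_DIM", "CONCAT_DIM",
    "SCNHead", "ClassProbabilities", "DRENet",
    "concat_features", "fcl_forward", "softmax_probs", "softmax",
    "cross_entropy",
]


@dataclass
class SCNHead:
    """Weights (K x D) and bias (K) of the single fully connected layer."""

    weights: np.ndarray
    bias: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        self.bias = np.asarray(self.bias, dtype=np.float64)
        if self.weights.ndim != 2 or self.bias.ndim != 1 \
                or self.weights.shape[0] != self.bias.shape[0]:
            raise ValueError("head weights must be (K, D) with a K-vector bias")

    @property
    def num_classes(self) -> int:
        return self.weights.shape[0]

    @property
    def input_dim(self) -> int:
        return self.weights.shape[1]

    @classmethod
    def zeros(cls, num_classes: int = 4, input_dim: int = CONCAT_DIM) -> "SCNHead":
        return cls(np.zeros((num_classes, input_dim)), np.zeros(num_classes))

    @classmethod
    def random(cls, num_classes: int = 4, input_dim: int = CONCAT_DIM,
               seed: int = 0, scale: float = 0.01) -> "SCNHead":
        rng = np.random.default_rng(seed)
        return cls(rng.normal(0.0, scale, (num_classes, input_dim)),
                   np.zeros(num_classes))


@dataclass
class ClassProbabilities:
    """A probability vector on the class simplex plus its argmax label."""

    probabilities: np.ndarray
    labels: tuple[str, ...] = CLASS_LABELS

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=np.float64)
        if p.ndim != 1 or len(p) != len(self.labels):
            raise ValueError("need one probability per class label")
        if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("probabilities must be non-negative and sum to 1")
        self.probabilities = p

    @property
    def predicted_index(self) -> int:
        return int(np.argmax(self.probabilities))  # argmax takes the lowest tie

    @property
    def predicted_label(self) -> str:
        return self.labels[self.predicted_index]


def concat_features(f1: np.ndarray, f2: np.ndarray) -> np.ndarray:
    """f = [f1 | f2]: residual features first, dense features second.

    Accepts single vectors (2048,), (1920,) or batches (N, 2048), (N, 1920).
    """
    f1, f2 = np.asarray(f1), np.asarray(f2)
    if f1.shape[-1] != RESNET_DIM or f2.shape[-1] != DENSENET_DIM:
        raise ValueError(
            f"expected feature dims ({RESNET_DIM}, {DENSENET_DIM}), got "
            f"({f1.shape[-1]}, {f2.shape[-1]})")
    return np.concatenate([f1, f2], axis=-1)


def fcl_forward(f: np.ndarray, head: SCNHead) -> np.ndarray:
    """Fully connected layer: z_j = sum_l w_{j,l} f_l + b_j."""
    f = np.asarray(f, dtype=np.float64)
    if not np.isfinite(f).all():
        raise ValueError("non-finite feature input to the fully connected layer")
    if f.shape[-1] != head.input_dim:
        raise ValueError(
            f"feature dim {f.shape[-1]} does not match head input {head.input_dim}")
    return f @ head.weights.T + head.bias


def softmax_probs(z: np.ndarray) -> np.ndarray:
    """Stable softmax along the last axis (shift-invariant by construction)."""
    z = np.asarray(z, dtype=np.float64)
    if not np.isfinite(z).all():
        raise ValueError("softmax requires finite inputs")
    shifted = z - z.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


def softmax(z: np.ndarray, labels: tuple[str, ...] = CLASS_LABELS) -> ClassProbabilities:
    """Softmax of one K-vector of scores, packaged with its argmax label."""
    z = np.asarray(z, dtype=np.float64)
    if z.ndim != 1:
        raise ValueError("softmax() packages a single score vector; "
                         "use softmax_probs for batches")
    return ClassProbabilities(softmax_probs(z), labels)


def cross_entropy(probabilities, true_label) -> float:
    """CE = -log p(true class).  A zero probability yields +inf."""
    if isinstance(probabilities, ClassProbabilities):
        labels = probabilities.labels
        p = probabilities.probabilities
    else:
        labels = CLASS_LABELS
        p = np.asarray(probabilities, dtype=np.float64)
    if isinstance(true_label, str):
        if true_label not in labels:
            raise ValueError(f"unknown label {true_label!r}")
        idx = labels.index(true_label)
    else:
        idx = int(true_label)
        if not (0 <= idx < len(p)):
            raise ValueError(f"label index {idx} out of range")
    pt = p[idx]
    if pt == 0.0:
        return float("inf")
    return float(-np.log(pt))


def batch_cross_entropy(probs: np.ndarray, label_idx: np.ndarray) -> float:
    """Mean CE over a batch of probability rows."""
    probs = np.asarray(probs, dtype=np.float64)
    rows = np.arange(len(label_idx))
    p = probs[rows, label_idx]
    with np.errstate(divide="ignore"):
        return float(np.mean(-np.log(p)))


class DRENet:
    """The assembled ensemble: two extractors + SCN head."""

    def __init__(self, extractor_resnet: FeatureExtractor,
                 extractor_densenet: FeatureExtractor,
                 head: SCNHead | None = None,
                 labels: tuple[str, ...] = CLASS_LABELS) -> None:
        if extractor_resnet.feature_dim != RESNET_DIM \
                or extractor_densenet.feature_dim != DENSENET_DIM:
            raise ValueError("extractor feature dims must be (2048, 1920)")
        self.extractor_resnet = extractor_resnet
        self.extractor_densenet = extractor_densenet
        self.head = head
        self.labels = labels

    @classmethod
    def build(cls, seed: int = 0, input_size: int = 224,
              head: SCNHead | None = None) -> "DRENet":
        r = build_extractor(FeatureExtractorSpec(
            "resnet50_modified", seed=seed, input_size=input_size))
        d = build_extractor(FeatureExtractorSpec(
            "densenet201_modified", seed=seed + 1, input_size=input_size))
        return cls(r, d, head=head)

    def is_assembled(self) -> bool:
        return self.head is not None

    def concat_features_of(self, images, batch_size: int = 16) -> np.ndarray:
        """Concat-layer output [f1 | f2] for each image, (N, 3968)."""
        f1 = self.extractor_resnet.features(images, batch_size=batch_size)
        f2 = self.extractor_densenet.features(images, batch_size=batch_size)
        return concat_features(f1, f2)

    def predict_proba(self, images, batch_size: int = 16) -> np.ndarray:
        if not self.is_assembled():
            raise RuntimeError("model head is not assembled; train or set an SCNHead")
        f = self.concat_features_of(images, batch_size=batch_size)
        return softmax_probs(fcl_forward(f, self.head))

    def predict(self, image) -> ClassProbabilities:
        probs = self.predict_proba([image])[0]
        return ClassProbabilities(probs, self.labels)

    def predict_labels(self, images, batch_size: int = 16) -> list[str]:
        probs = self.predict_proba(images, batch_size=batch_size)
        return [self.labels[i] for i in probs.argmax(axis=1)]

    # --- persistence ---------------------------------------------------
    def save(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        if self.head is not None:
            np.savez_compressed(out_dir / "head.npz",
                                weights=self.head.weights, bias=self.head.bias)
        self.extractor_resnet.save_weights(out_dir / "resnet.npz")
        self.extractor_densenet.save_weights(out_dir / "densenet.npz")
        meta = {
            "labels": list(self.labels),
            "input_size": self.extractor_resnet.spec.input_size,
            "seeds": [self.extractor_resnet.spec.seed,
                      self.extractor_densenet.spec.seed],
            "pretrained": [self.extractor_resnet.spec.pretrained,
                           self.extractor_densenet.spec.pretrained],
        }
        (out_dir / "meta.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, out_dir: str | Path) -> "DRENet":
        out_dir = Path(out_dir)
        meta = json.loads((out_dir / "meta.json").read_text())
        model = cls.build(seed=meta["seeds"][0], input_size=meta["input_size"])
        model.extractor_resnet.load_weights(out_dir / "resnet.npz")
        model.extractor_densenet.load_weights(out_dir / "densenet.npz")
        model.labels = tuple(meta["labels"])
        head_path = out_dir / "head.npz"
        if head_path.exists():
            with np.load(head_path) as data:
                model.head = SCNHead(data["weights"], data["bias"])
        return model
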