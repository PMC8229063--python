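"""Momentum-SGD training in the two regimes: sequential and end-to-end.

Sequential training fine-tunes each backbone standalone under a temporary
softmax head (13 epochs each by default), freezes them, extracts the
concatenated features once, and trains the SCN head on those features
(9 epochs).  End-to-end training updates both backbones and the head
jointly under one cross-entropy loss (7 epochs).  The optimizer is
classical momentum SGD with L2 weight decay added to the gradient:

    v <- momentum * v - lr * (grad + l2 * param);   param <- param + v

Defaults follow the published training protocol: mini-batch 10, learning
rate 0.001, momentum 0.9, L2 term 0.0001.  A learning-rate drop factor of
0.1 is recorded but applied only when a drop period is configured; the
default schedule is constant.  A stratified validation split (25% by
default) is carved from the training samples for monitoring only — there
is no early stopping.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .backbones import FeatureExtractor, attach_temp_head
from .ensemble import DRENet, SCNHead, softmax_probs
from .nn import Linear, Parameter
from .synthetic import CLASS_LABELS

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig", "TrainingTrace", "split_train_validation", "sgd_step",
    "SGD", "train_scn_on_features", "train_sequential", "train_end_to_end",
]


@dataclass
class TrainConfig:
    """Hyper-parameters for both training regimes."""

    regime: str = "sequential"
    epochs_backbone: int = 13
    epochs_scn: int = 9
    epochs_end_to_end: int = 7
    minibatch: int = 10
    learning_rate: float = 0.001
    momentum: float = 0.9
    l2_regularization: float = 0.0001
    lr_drop_factor: float = 0.1
    lr_drop_period: int | None = None
    validation_fraction: float = 0.25
    seed: int = 0
    #: global gradient-norm cap applied by the batch trainers before each
    #: update; needed for stability when training deep stacks from random
    #: initialization (small-batch batch-norm statistics can produce very
    #: large gradients).  ``None`` disables it; the bare ``sgd_step`` rule
    #: never clips.
    grad_clip_norm: float | None = 10.0

    def __post_init__(self) -> None:
        if self.regime not in ("sequential", "end_to_end"):
            raise ValueError(f"unknown regime {self.regime!r}")
        if not (0.0 < self.validation_fraction < 1.0):
            raise ValueError("validation_fraction must lie in (0, 1)")
        if self.minibatch < 1:
            raise ValueError("minibatch must be >= 1")
        for name in ("epochs_scn", "epochs_end_to_end"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.epochs_backbone < 0:
            raise ValueError("epochs_backbone must be >= 0")

    def lr_at_epoch(self, epoch: int) -> float:
        if self.lr_drop_period is None:
            return self.learning_rate
        return self.learning_rate * self.lr_drop_factor ** (epoch // self.lr_drop_period)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        return cls(**d)


@dataclass
class TrainingTrace:
    """Per-iteration training curve plus per-epoch validation curve."""

    iteration_loss: list[float] = field(default_factory=list)
    iteration_accuracy: list[float] = field(default_factory=list)
    epoch_val_loss: list[float] = field(default_factory=list)
    epoch_val_accuracy: list[float] = field(default_factory=list)

    def log_iteration(self, loss: float, accuracy: float) -> None:
        self.iteration_loss.append(float(loss))
        self.iteration_accuracy.append(float(accuracy))

    def log_epoch_validation(self, loss: float, accuracy: float) -> None:
        self.epoch_val_loss.append(float(loss))
        self.epoch_val_accuracy.append(float(accuracy))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "iteration": np.arange(len(self.iteration_loss)),
            "loss": self.iteration_loss,
            "accuracy": self.iteration_accuracy,
        })

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def _stratified_counts(sizes: list[int], fraction: float) -> list[int]:
    """Validation counts per class by largest remainder, so the total is
    exactly round(fraction * N) while staying proportional per class.
    Classes with fewer than 2 samples contribute nothing."""
    eligible = [i for i, n in enumerate(sizes) if n >= 2]
    target = int(round(fraction * sum(sizes[i] for i in eligible)))
    ideal = {i: fraction * sizes[i] for i in eligible}
    take = {i: min(int(ideal[i]), sizes[i] - 1) for i in eligible}
    by_remainder = sorted(eligible, key=lambda i: ideal[i] - take[i],
                          reverse=True)
    for i in by_remainder:
        if sum(take.values()) >= target:
            break
        if take[i] < sizes[i] - 1:
            take[i] += 1
    out = [0] * len(sizes)
    for i, n in take.items():
        out[i] = n
    return out


def split_train_validation(manifest: pd.DataFrame, fraction: float,
                           seed: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Seeded stratified split of a manifest into (train, validation)."""
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    classes = sorted(manifest["label"].unique())
    groups = [manifest[manifest["label"] == c] for c in classes]
    for c, g in zip(classes, groups):
        if len(g) < 2:
            warnings.warn(f"class {c!r} has <2 samples; keeping all in train")
    n_val = _stratified_counts([len(g) for g in groups], fraction)
    train_parts, val_parts = [], []
    for g, nv in zip(groups, n_val):
        order = rng.permutation(len(g))
        val_parts.append(g.iloc[order[:nv]])
        train_parts.append(g.iloc[order[nv:]])
    train = pd.concat(train_parts).sort_index().reset_index(drop=True)
    val = pd.concat(val_parts).sort_index().reset_index(drop=True)
    return train, val


def sgd_step(parameters: list[np.ndarray], gradients: list[np.ndarray],
             state: list[np.ndarray] | None, config: TrainConfig,
             lr: float | None = None):
    """One functional momentum-SGD step over matching arrays.

    Returns (updated parameters, updated state).  ``state`` holds one
    velocity array per parameter (``None`` initializes zeros).
    """
    lr = config.learning_rate if lr is None else lr
    if state is None:
        state = [np.zeros_like(p) for p in parameters]
    new_params, new_state = [], []
    for i, (p, g, v) in enumerate(zip(parameters, gradients, state)):
        if not np.all(np.isfinite(g)):
            raise FloatingPointError(f"non-finite gradient in parameter block {i}")
        v_new = config.momentum * v - lr * (g + config.l2_regularization * p)
        new_params.append(p + v_new)
        new_state.append(v_new)
    return new_params, new_state


class SGD:
    """In-place momentum SGD over :class:`Parameter` objects."""

    def __init__(self, params: list[Parameter], config: TrainConfig) -> None:
        self.params = params
        self.config = config
        self.velocity = [np.zeros_like(p.data) for p in params]

    def step(self, lr: float | None = None) -> None:
        cfg = self.config
        lr = cfg.learning_rate if lr is None else lr
        scale = 1.0
        if cfg.grad_clip_norm is not None:
            total = np.sqrt(sum(float(np.sum(p.grad.astype(np.float64) ** 2))
                                for p in self.params))
            if total > cfg.grad_clip_norm:
                scale = cfg.grad_clip_norm / total
        for p, v in zip(self.params, self.velocity):
            g = p.grad
            if not np.all(np.isfinite(g)):
                raise FloatingPointError(f"non-finite gradient in parameter {p.name!r}")
            v *= cfg.momentum
            v -= lr * (scale * g + cfg.l2_regularization * p.data)
            p.data += v

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


def _label_indices(labels, label_order=CLASS_LABELS) -> np.ndarray:
    lookup = {lab: i for i, lab in enumerate(label_order)}
    return np.array([lookup[l] if isinstance(l, str) else int(l) for l in labels])


def _carve_validation(n: int, labels_idx: np.ndarray, fraction: float,
                      rng: np.random.Generator):
    """Stratified index split; validation may be empty for tiny classes."""
    classes = np.unique(labels_idx)
    groups = [np.flatnonzero(labels_idx == c) for c in classes]
    n_val = _stratified_counts([len(g) for g in groups], fraction)
    val_idx, train_idx = [], []
    for members, nv in zip(groups, n_val):
        members = members[rng.permutation(len(members))]
        val_idx.extend(members[:nv])
        train_idx.extend(members[nv:])
    return np.sort(np.array(train_idx, int)), np.sort(np.array(val_idx, int))


def train_scn_on_features(features: np.ndarray, labels, config: TrainConfig,
                          num_classes: int = 4, epochs: int | None = None,
                          label_order=CLASS_LABELS):
    """Train the SCN head (softmax regression) on fixed concat features.

    Returns (SCNHead, TrainingTrace).  The loss is mean cross entropy; the
    L2 term enters through the optimizer.
    """
    features = np.asarray(features, dtype=np.float64)
    y = _label_indices(labels, label_order)
    epochs = config.epochs_scn if epochs is None else epochs
    rng = np.random.default_rng(config.seed)
    trace = TrainingTrace()

    tr_idx, va_idx = _carve_validation(len(y), y, config.validation_fraction, rng)
    # condition the optimization: standardize per feature on the training
    # portion and fold the affine map back into the returned head, so the
    # fitted classifier is still a single linear layer on raw features.
    # Without this, momentum SGD at the published learning rate diverges
    # on unnormalized extractor features.
    mu = features[tr_idx].mean(axis=0)
    sigma = features[tr_idx].std(axis=0)
    sigma[sigma < 1e-8] = 1.0
    features = (features - mu) / sigma
    Xtr, ytr = features[tr_idx], y[tr_idx]
    Xva, yva = features[va_idx], y[va_idx]

    d = features.shape[1]
    w = rng.normal(0.0, 0.01, (num_classes, d))
    b = np.zeros(num_classes)
    vel = [np.zeros_like(w), np.zeros_like(b)]
    onehot = np.eye(num_classes)

    for epoch in range(epochs):
        lr = config.lr_at_epoch(epoch)
        order = rng.permutation(len(ytr))
        for start in range(0, len(ytr), config.minibatch):
            batch = order[start:start + config.minibatch]
            xb, yb = Xtr[batch], ytr[batch]
            z = xb @ w.T + b
            p = softmax_probs(z)
            loss = float(np.mean(-np.log(np.maximum(p[np.arange(len(yb)), yb], 1e-300))))
            acc = float(np.mean(p.argmax(axis=1) == yb))
            dz = (p - onehot[yb]) / len(yb)
            gw, gb = dz.T @ xb, dz.sum(axis=0)
            (w, b), vel = sgd_step([w, b], [gw, gb], vel, config, lr=lr)
            trace.log_iteration(loss, acc)
        if len(yva):
            pv = softmax_probs(Xva @ w.T + b)
            vl = float(np.mean(-np.log(np.maximum(pv[np.arange(len(yva)), yva], 1e-300))))
            trace.log_epoch_validation(vl, float(np.mean(pv.argmax(axis=1) == yva)))
    w_raw = w / sigma
    b_raw = b - w_raw @ mu
    return SCNHead(w_raw, b_raw), trace


def _finetune_backbone(extractor: FeatureExtractor, x: np.ndarray,
                       y: np.ndarray, config: TrainConfig, epochs: int,
                       num_classes: int, seed: int) -> TrainingTrace:
    """Fine-tune one backbone under a temporary softmax head (discarded)."""
    trace = TrainingTrace()
    if epochs == 0:
        return trace
    clf = attach_temp_head(extractor, num_classes, seed=seed)
    opt = SGD(clf.parameters(), config)
    rng = np.random.default_rng(seed)
    onehot = np.eye(num_classes)
    for epoch in range(epochs):
        lr = config.lr_at_epoch(epoch)
        order = rng.permutation(len(y))
        for start in range(0, len(y), config.minibatch):
            batch = order[start:start + config.minibatch]
            xb, yb = x[batch], y[batch]
            opt.zero_grad()
            z = clf.logits(xb, train=True)
            p = softmax_probs(z)
            loss = float(np.mean(-np.log(np.maximum(p[np.arange(len(yb)), yb], 1e-300))))
            dz = ((p - onehot[yb]) / len(yb)).astype(xb.dtype)
            dfeat = clf.head.backward(dz)
            extractor.net.backward(dfeat)
            opt.step(lr=lr)
            trace.log_iteration(loss, float(np.mean(p.argmax(axis=1) == yb)))
    return trace


def train_sequential(model: DRENet, images, labels, config: TrainConfig,
                     num_classes: int = 4):
    """Sequential regime: fine-tune backbones, freeze, then train the SCN.

    ``images`` are raw (already augmented) training images; ``labels``
    their class labels.  Returns (model, {component: TrainingTrace}).
    """
    y = _label_indices(labels, model.labels)
    traces: dict[str, TrainingTrace] = {}
    for name, extractor, seed_off in (
            ("resnet", model.extractor_resnet, 1),
            ("densenet", model.extractor_densenet, 2)):
        x = extractor.preprocess(images)
        traces[name] = _finetune_backbone(
            extractor, x, y, config, config.epochs_backbone, num_classes,
            seed=config.seed + seed_off)
    # backbones are frozen from here on: extract features exactly once
    feats = model.concat_features_of(images)
    head, scn_trace = train_scn_on_features(
        feats, y, config, num_classes=num_classes, label_order=model.labels)
    traces["scn"] = scn_trace
    model.head = head
    return model, traces


def train_end_to_end(model: DRENet, images, labels, config: TrainConfig,
                     num_classes: int = 4):
    """End-to-end regime: joint update of both backbones and the head."""
    y = _label_indices(labels, model.labels)
    rng = np.random.default_rng(config.seed)
    dtype = model.extractor_resnet.spec.dtype
    head = Linear(model.extractor_resnet.feature_dim
                  + model.extractor_densenet.feature_dim, num_classes,
                  rng=np.random.default_rng(config.seed + 3), dtype=dtype)
    params = (model.extractor_resnet.net.parameters()
              + model.extractor_densenet.net.parameters() + head.parameters())
    opt = SGD(params, config)
    xr = model.extractor_resnet.preprocess(images)
    xd = model.extractor_densenet.preprocess(images)
    onehot = np.eye(num_classes)
    trace = TrainingTrace()
    d1 = model.extractor_resnet.feature_dim

    tr_idx, va_idx = _carve_validation(len(y), y, config.validation_fraction, rng)
    for epoch in range(config.epochs_end_to_end):
        lr = config.lr_at_epoch(epoch)
        order = tr_idx[rng.permutation(len(tr_idx))]
        for start in range(0, len(order), config.minibatch):
            batch = order[start:start + config.minibatch]
            yb = y[batch]
            opt.zero_grad()
            f1 = model.extractor_resnet.net(xr[batch], train=True)
            f2 = model.extractor_densenet.net(xd[batch], train=True)
            f = np.concatenate([f1, f2], axis=1)
            p = softmax_probs(head(f, train=True))
            loss = float(np.mean(-np.log(np.maximum(p[np.arange(len(yb)), yb], 1e-300))))
            dz = ((p - onehot[yb]) / len(yb)).astype(dtype)
            df = head.backward(dz)
            model.extractor_resnet.net.backward(np.ascontiguousarray(df[:, :d1]))
            model.extractor_densenet.net.backward(np.ascontiguousarray(df[:, d1:]))
            opt.step(lr=lr)
            trace.log_iteration(loss, float(np.mean(p.argmax(axis=1) == yb)))
        if len(va_idx):
            f1 = model.extractor_resnet.net(xr[va_idx])
            f2 = model.extractor_densenet.net(xd[va_idx])
            pv = softmax_probs(head(np.concatenate([f1, f2], axis=1)))
            yv = y[va_idx]
            vl = float(np.mean(-np.log(np.maximum(pv[np.arange(len(yv)), yv], 1e-300))))
            trace.log_epoch_validation(vl, float(np.mean(pv.argmax(axis=1) == yv)))
    model.head = SCNHead(head.weight.data.astype(np.float64),
                         head.bias.data.astype(np.float64))
    return model, trace
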