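"""Closed-world protocol: stratified k-fold cross-validation, confusion
matrices, macro metrics, and the pooled paired t-test.

Metric conventions
------------------
The four reported metrics are computed from per-class one-vs-rest counts
TP_k, TN_k, FP_k, FN_k of a K x K confusion matrix:

* precision: macro mean of TP_k / (TP_k + FP_k)
* recall (default ``standard``): macro mean of TP_k / (TP_k + FN_k);
  an ``eq7_literal`` mode computes TP_k / (TP_k + TN_k) instead, kept for
  auditability of the printed formula it mirrors (that expression is not
  a recall and is off by construction)
* accuracy (default ``overall``): trace / total; an ``eq4_literal`` mode
  computes the macro mean of per-class one-vs-rest binary accuracies.
  For K classes the two are affinely related:
  literal = 100 - 2 * (100 - overall) / K, since each error contributes
  exactly one FP and one FN
* F1 = 2 * precision * recall / (precision + recall) from the macro means

Per-class terms with an empty denominator contribute 0 with a warning.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .augment import RotationPolicy, rotate_image
from .backbones import calibrate_batchnorm
from .ensemble import DRENet, fcl_forward, softmax_probs
from .synthetic import CLASS_LABELS
from .training import TrainConfig, train_scn_on_features, train_sequential, \
    train_end_to_end

logger = logging.getLogger(__name__)

__all__ = [
    "FoldPlan", "stratified_kfold", "ConfusionMatrix", "confusion",
    "MetricsReport", "metrics", "pooled_paired_ttest",
    "ClosedWorldResult", "run_closed_world", "CachedConcatFeatures",
    "prepare_frozen_model",
]


@dataclass
class FoldPlan:
    """Per-sample fold assignment for stratified k-fold cross-validation."""

    k: int
    fold_id: np.ndarray
    labels: np.ndarray

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_id == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_id != fold)

    def per_class_fold_counts(self) -> pd.DataFrame:
        """Rows: class, columns: fold, values: test-fold sizes."""
        df = pd.DataFrame({"label": self.labels, "fold": self.fold_id})
        return df.groupby(["label", "fold"]).size().unstack(fill_value=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"label": self.labels, "fold": self.fold_id})


def stratified_kfold(labels, k: int, seed: int) -> FoldPlan:
    """Assign folds within each class; remainders go to the earliest folds.

    Within each class, fold sizes differ by at most one.  A warning is
    issued when ``k`` exceeds the smallest class size (some folds then
    lack that class entirely).
    """
    labels = np.asarray(labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    fold_id = np.empty(len(labels), dtype=int)
    for label in sorted(np.unique(labels).tolist()):
        members = np.flatnonzero(labels == label)
        if len(members) < k:
            warnings.warn(
                f"class {label!r} has {len(members)} samples < k={k}; "
                "some folds will lack this class")
        members = members[rng.permutation(len(members))]
        base, extra = divmod(len(members), k)
        start = 0
        for fold in range(k):
            size = base + (1 if fold < extra else 0)
            fold_id[members[start:start + size]] = fold
            start += size
    return FoldPlan(k=k, fold_id=fold_id, labels=labels.copy())


@dataclass
class ConfusionMatrix:
    """K x K counts; rows are true classes, columns predicted classes."""

    counts: np.ndarray
    labels: tuple[str, ...] = CLASS_LABELS

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] != c.shape[1] or c.shape[0] != len(self.labels):
            raise ValueError("counts must be K x K matching the label list")
        if (c < 0).any():
            raise ValueError("confusion counts must be non-negative")
        self.counts = c

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def per_class(self) -> dict[str, dict[str, float]]:
        """One-vs-rest TP/FP/FN/TN per class."""
        out = {}
        total = self.counts.sum()
        for i, label in enumerate(self.labels):
            tp = self.counts[i, i]
            fp = self.counts[:, i].sum() - tp
            fn = self.counts[i, :].sum() - tp
            tn = total - tp - fp - fn
            out[label] = {"tp": float(tp), "fp": float(fp),
                          "fn": float(fn), "tn": float(tn)}
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.labels),
                            columns=list(self.labels))


def confusion(predictions, truths, labels: tuple[str, ...] = CLASS_LABELS) -> ConfusionMatrix:
    """Tally a confusion matrix from paired prediction/truth label lists."""
    if len(predictions) != len(truths):
        raise ValueError("predictions and truths must have equal length")
    index = {lab: i for i, lab in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=int)
    for pred, true in zip(predictions, truths):
        if pred not in index:
            raise ValueError(f"unknown predicted label {pred!r}")
        if true not in index:
            raise ValueError(f"unknown true label {true!r}")
        counts[index[true], index[pred]] += 1
    return ConfusionMatrix(counts, labels)


@dataclass
class MetricsReport:
    """Macro metrics in percent, plus the modes they were computed under."""

    accuracy: float
    f1: float
    precision: float
    recall: float
    accuracy_mode: str = "overall"
    recall_mode: str = "standard"

    def as_dict(self) -> dict[str, float]:
        return {"accuracy": self.accuracy, "f1": self.f1,
                "precision": self.precision, "recall": self.recall}

    def pooled_values(self) -> list[float]:
        return [self.accuracy, self.f1, self.precision, self.recall]


def _safe_ratio(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"undefined {what} (zero denominator); contributing 0")
        return 0.0
    return num / den


def metrics(cm: ConfusionMatrix, accuracy_mode: str = "overall",
            recall_mode: str = "standard") -> MetricsReport:
    """Macro metrics of a confusion matrix (percent)."""
    if accuracy_mode not in ("overall", "eq4_literal"):
        raise ValueError(f"unknown accuracy mode {accuracy_mode!r}")
    if recall_mode not in ("standard", "eq7_literal"):
        raise ValueError(f"unknown recall mode {recall_mode!r}")
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    per = cm.per_class()
    k = len(cm.labels)
    precision = np.mean([
        _safe_ratio(c["tp"], c["tp"] + c["fp"], f"precision[{lab}]")
        for lab, c in per.items()])
    if recall_mode == "standard":
        recall = np.mean([
            _safe_ratio(c["tp"], c["tp"] + c["fn"], f"recall[{lab}]")
            for lab, c in per.items()])
    else:
        recall = np.mean([
            _safe_ratio(c["tp"], c["tp"] + c["tn"], f"recall[{lab}]")
            for lab, c in per.items()])
    if accuracy_mode == "overall":
        accuracy = np.trace(cm.counts) / cm.total
    else:
        accuracy = np.mean([
            (c["tp"] + c["tn"]) / (c["tp"] + c["tn"] + c["fp"] + c["fn"])
            for c in per.values()])
    f1 = _safe_ratio(2 * precision * recall, precision + recall, "F1")
    return MetricsReport(accuracy=100 * accuracy, f1=100 * f1,
                         precision=100 * precision, recall=100 * recall,
                         accuracy_mode=accuracy_mode, recall_mode=recall_mode)


def pooled_paired_ttest(reports_a: list[MetricsReport],
                        reports_b: list[MetricsReport]) -> float:
    """Two-tailed paired t-test over the pooled fold-wise metric values.

    The four metrics of each fold are pooled into 4 * n_folds paired
    values per method.  Degenerate cases: all differences zero -> p = 1;
    constant nonzero differences (zero variance) -> p = 0, reported as
    smaller than machine epsilon.
    """
    if len(reports_a) != len(reports_b):
        raise ValueError("both methods need the same number of folds")
    a = np.array([v for r in reports_a for v in r.pooled_values()])
    b = np.array([v for r in reports_b for v in r.pooled_values()])
    d = a - b
    if np.allclose(d, 0.0):
        return 1.0
    sd = d.std(ddof=1)
    if sd == 0.0:
        return 0.0
    t = d.mean() / (sd / np.sqrt(len(d)))
    return float(2.0 * stats.t.sf(abs(t), df=len(d) - 1))


@dataclass
class ClosedWorldResult:
    fold_reports: list[MetricsReport]
    fold_confusions: list[ConfusionMatrix]
    mean_report: MetricsReport
    mean_confusion: np.ndarray

    def summary(self) -> dict:
        return {
            "mean": self.mean_report.as_dict(),
            "folds": [r.as_dict() for r in self.fold_reports],
        }


def _mean_report(reports: list[MetricsReport]) -> MetricsReport:
    return MetricsReport(
        accuracy=float(np.mean([r.accuracy for r in reports])),
        f1=float(np.mean([r.f1 for r in reports])),
        precision=float(np.mean([r.precision for r in reports])),
        recall=float(np.mean([r.recall for r in reports])),
        accuracy_mode=reports[0].accuracy_mode,
        recall_mode=reports[0].recall_mode,
    )


class CachedConcatFeatures:
    """Lazy (image index, angle) -> concat feature cache for one frozen model.

    Valid only while the backbones stay frozen; any fine-tuning of the
    extractors invalidates it (the runner simply does not use a cache in
    that case).
    """

    def __init__(self, model: DRENet, images, policy: RotationPolicy,
                 batch_size: int = 16) -> None:
        self.model = model
        self.images = images
        self.policy = policy
        self.batch_size = batch_size
        self._store: dict[tuple[int, float], np.ndarray] = {}

    def get(self, pairs: list[tuple[int, float]]) -> np.ndarray:
        missing = [p for p in dict.fromkeys(pairs) if p not in self._store]
        if missing:
            imgs = [rotate_image(self.images[i], angle, self.policy)
                    if angle != 0.0 else self.images[i]
                    for i, angle in missing]
            feats = self.model.concat_features_of(imgs, batch_size=self.batch_size)
            for p, f in zip(missing, feats):
                self._store[p] = f
        return np.stack([self._store[p] for p in pairs])


def prepare_frozen_model(images, seed: int, input_size: int,
                         bn_calibration: int,
                         policy: RotationPolicy) -> CachedConcatFeatures:
    """Build a frozen random-init ensemble with calibrated batch norms and
    wrap it in a concat-feature cache keyed by (image index, angle)."""
    model = DRENet.build(seed=seed, input_size=input_size)
    if bn_calibration:
        pick = np.linspace(0, len(images) - 1, bn_calibration).astype(int)
        calib = [images[i] for i in pick]
        calibrate_batchnorm(model.extractor_resnet, calib)
        calibrate_batchnorm(model.extractor_densenet, calib)
    return CachedConcatFeatures(model, images, policy)


def run_closed_world(images, labels, train_config: TrainConfig, k: int = 10,
                     seed: int = 0, policy: RotationPolicy | None = None,
                     model_seed: int | None = None, input_size: int = 224,
                     bn_calibration: int = 0,
                     cache: "CachedConcatFeatures | None" = None) -> ClosedWorldResult:
    """Full closed-world protocol on an in-memory labeled image set.

    Per fold: RIA expands the training portion only, the model is trained
    per ``train_config``, and the untouched test portion is scored.  When
    the sequential regime is run with ``epochs_backbone == 0`` the
    extractors stay frozen, so concat features are cached across folds.
    """
    policy = policy or RotationPolicy()
    labels = np.asarray(labels)
    plan = stratified_kfold(labels, k, seed)
    label_order = tuple(sorted(np.unique(labels).tolist()))
    model_seed = seed if model_seed is None else model_seed

    frozen = (train_config.regime == "sequential"
              and train_config.epochs_backbone == 0)
    if frozen:
        if cache is None:
            cache = prepare_frozen_model(images, model_seed, input_size,
                                         bn_calibration, policy)
        model = cache.model
        model.labels = label_order

    fold_reports, fold_cms = [], []
    for fold in range(k):
        tr_idx = plan.train_indices(fold)
        te_idx = plan.test_indices(fold)
        logger.info("closed-world fold %d/%d: %d train, %d test",
                    fold + 1, k, len(tr_idx), len(te_idx))
        if frozen:
            pairs = [(int(i), float(a)) for i in tr_idx for a in policy.angles_deg]
            feats = cache.get(pairs)
            y_aug = np.repeat(labels[tr_idx], policy.n_angles)
            head, _ = train_scn_on_features(
                feats, y_aug, train_config, num_classes=len(label_order),
                label_order=label_order)
            model.head = head
            test_feats = cache.get([(int(i), 0.0) for i in te_idx])
            probs = softmax_probs(fcl_forward(test_feats, head))
            preds = [label_order[j] for j in probs.argmax(axis=1)]
        else:
            model = DRENet.build(seed=model_seed, input_size=input_size)
            model.labels = label_order
            aug_images, aug_labels = [], []
            for i in tr_idx:
                for angle in policy.angles_deg:
                    aug_images.append(rotate_image(images[i], angle, policy))
                    aug_labels.append(labels[i])
            if train_config.regime == "sequential":
                model, _ = train_sequential(model, aug_images, aug_labels,
                                            train_config,
                                            num_classes=len(label_order))
            else:
                model, _ = train_end_to_end(model, aug_images, aug_labels,
                                            train_config,
                                            num_classes=len(label_order))
            preds = model.predict_labels([images[i] for i in te_idx])
        cm = confusion(preds, labels[te_idx].tolist(), label_order)
        fold_cms.append(cm)
        fold_reports.append(metrics(cm))
    mean_cm = np.mean([cm.counts for cm in fold_cms], axis=0)
    return ClosedWorldResult(fold_reports, fold_cms,
                             _mean_report(fold_reports), mean_cm)
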