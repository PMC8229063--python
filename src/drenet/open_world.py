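"""Open-world protocol: class-disjoint evaluation by nearest class mean.

Train and test class sets are disjoint.  The network is trained on the
training classes only; test images of the unseen classes are identified
by the L2 (Euclidean) distance between their concat-layer feature vector
(1 x 3968, head weights unused) and registered per-class mean feature
vectors.  New classes can be registered at inference time by storing a
mean vector and a label — no retraining.

During evaluation the reference mean of a query's own class is computed
leave-one-out (the query never contributes to its own reference), and
gallery features come from unaugmented images only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .augment import RotationPolicy, rotate_image
from .closed_world import ConfusionMatrix, MetricsReport, _mean_report, \
    confusion, metrics
from .ensemble import DRENet
from .training import TrainConfig, train_scn_on_features

logger = logging.getLogger(__name__)

__all__ = [
    "ReferenceGallery", "OpenWorldPlan", "DEFAULT_OPEN_WORLD_PLAN",
    "extract_concat_features", "build_gallery", "match", "register_class",
    "OpenWorldResult", "run_open_world",
]


@dataclass
class ReferenceGallery:
    """label -> (mean feature vector, number of enrolled vectors)."""

    means: dict[str, np.ndarray] = field(default_factory=dict)
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def labels(self) -> list[str]:
        return sorted(self.means)

    def __len__(self) -> int:
        return len(self.means)


@dataclass(frozen=True)
class OpenWorldPlan:
    """Named (train classes, test classes) runs; sets must be disjoint."""

    runs: tuple[tuple[str, tuple[str, ...], tuple[str, ...]], ...]

    def __post_init__(self) -> None:
        for name, train, test in self.runs:
            if set(train) & set(test):
                raise ValueError(
                    f"open-world run {name!r} has overlapping train/test "
                    f"classes: {sorted(set(train) & set(test))}")


#: the four class-disjoint two-fold runs used by default
DEFAULT_OPEN_WORLD_PLAN = OpenWorldPlan((
    ("1st fold-A", ("C1", "C2"), ("C3", "C4")),
    ("1st fold-B", ("C3", "C4"), ("C1", "C2")),
    ("2nd fold-A", ("C1", "C3"), ("C2", "C4")),
    ("2nd fold-B", ("C2", "C4"), ("C1", "C3")),
))


def extract_concat_features(model: DRENet, images, batch_size: int = 16) -> np.ndarray:
    """Concat-layer outputs (N x 3968); the SCN head weights are unused."""
    if model.extractor_resnet is None or model.extractor_densenet is None:
        raise RuntimeError("model extractors are not assembled")
    return model.concat_features_of(images, batch_size=batch_size)


def build_gallery(features_by_label: dict[str, np.ndarray]) -> ReferenceGallery:
    """Per-label arithmetic mean of enrolled feature vectors."""
    gallery = ReferenceGallery()
    for label, feats in features_by_label.items():
        feats = np.asarray(feats, dtype=np.float64)
        if feats.ndim == 1:
            feats = feats[None, :]
        if feats.shape[0] == 0:
            raise ValueError(f"empty enrollment group for label {label!r}")
        gallery.means[label] = feats.mean(axis=0)
        gallery.counts[label] = int(feats.shape[0])
    return gallery


def match(query: np.ndarray, gallery: ReferenceGallery) -> str:
    """Label of the nearest mean by L2 distance; ties -> lowest label."""
    if len(gallery) == 0:
        raise ValueError("cannot match against an empty gallery")
    query = np.asarray(query, dtype=np.float64)
    best_label, best_dist = None, np.inf
    for label in gallery.labels:  # sorted => lowest label wins ties
        mean = gallery.means[label]
        if mean.shape != query.shape:
            raise ValueError(
                f"query length {query.shape} does not match gallery mean "
                f"length {mean.shape} for label {label!r}")
        dist = float(np.linalg.norm(query - mean))
        if dist < best_dist:
            best_label, best_dist = label, dist
    return best_label


def register_class(gallery: ReferenceGallery, label: str,
                   enrollment: np.ndarray, overwrite: bool = False) -> ReferenceGallery:
    """Add a new class mean without retraining; existing means untouched."""
    if label in gallery.means and not overwrite:
        raise ValueError(f"label {label!r} already registered (use overwrite=True)")
    enrollment = np.asarray(enrollment, dtype=np.float64)
    if enrollment.ndim == 1:
        enrollment = enrollment[None, :]
    if enrollment.shape[0] == 0:
        raise ValueError(f"empty enrollment for label {label!r}")
    new = ReferenceGallery(means=dict(gallery.means), counts=dict(gallery.counts))
    new.means[label] = enrollment.mean(axis=0)
    new.counts[label] = int(enrollment.shape[0])
    return new


def _leave_one_out_predictions(features: np.ndarray, labels: np.ndarray) -> list[str]:
    """Match each query against leave-one-out class means."""
    classes = sorted(np.unique(labels).tolist())
    sums = {c: features[labels == c].sum(axis=0) for c in classes}
    counts = {c: int((labels == c).sum()) for c in classes}
    preds = []
    for i, query in enumerate(features):
        own = labels[i]
        best_label, best_dist = None, np.inf
        for c in classes:
            if c == own:
                if counts[c] < 2:
                    continue  # no reference left for a singleton class
                mean = (sums[c] - query) / (counts[c] - 1)
            else:
                mean = sums[c] / counts[c]
            dist = float(np.linalg.norm(query - mean))
            if dist < best_dist:
                best_label, best_dist = c, dist
        preds.append(best_label)
    return preds


@dataclass
class OpenWorldResult:
    run_names: list[str]
    run_reports: list[MetricsReport]
    run_confusions: list[ConfusionMatrix]
    mean_report: MetricsReport

    def summary(self) -> dict:
        return {
            "mean": self.mean_report.as_dict(),
            "runs": {n: r.as_dict()
                     for n, r in zip(self.run_names, self.run_reports)},
        }


def run_open_world(images, labels, train_config: TrainConfig,
                   plan: OpenWorldPlan = DEFAULT_OPEN_WORLD_PLAN,
                   seed: int = 0, policy: RotationPolicy | None = None,
                   model_seed: int | None = None, input_size: int = 224,
                   bn_calibration: int = 0,
                   cache=None) -> OpenWorldResult:
    """Run each class-disjoint plan entry and average the run metrics.

    Per run: the network is trained on the RIA-expanded training-class
    images, concat features of the unaugmented testing-class images are
    extracted, and each query is matched against leave-one-out class
    means of the testing classes.
    """
    policy = policy or RotationPolicy()
    labels = np.asarray(labels)
    model_seed = seed if model_seed is None else model_seed
    frozen = (train_config.regime == "sequential"
              and train_config.epochs_backbone == 0)

    shared_model = None
    if frozen:
        if cache is None:
            from .closed_world import prepare_frozen_model
            cache = prepare_frozen_model(images, model_seed, input_size,
                                         bn_calibration, policy)
        shared_model = cache.model

    names, reports, cms = [], [], []
    for name, train_classes, test_classes in plan.runs:
        for c in train_classes + test_classes:
            if c not in labels:
                raise ValueError(f"plan class {c!r} absent from the dataset")
        tr_idx = np.flatnonzero(np.isin(labels, train_classes))
        te_idx = np.flatnonzero(np.isin(labels, test_classes))
        logger.info("open-world run %s: train %s (%d), test %s (%d)",
                    name, train_classes, len(tr_idx), test_classes, len(te_idx))
        model = shared_model or DRENet.build(seed=model_seed, input_size=input_size)
        model.labels = tuple(sorted(train_classes))

        # train on the training classes (RIA-expanded)
        if frozen:
            pairs = [(int(i), float(a)) for i in tr_idx
                     for a in policy.angles_deg]
            feats = cache.get(pairs)
            aug_labels = np.repeat(labels[tr_idx], policy.n_angles)
            head, _ = train_scn_on_features(
                feats, aug_labels, train_config,
                num_classes=len(train_classes), label_order=model.labels)
            model.head = head
        else:
            from .training import train_sequential, train_end_to_end
            aug_imgs, aug_labels = [], []
            for i in tr_idx:
                for a in policy.angles_deg:
                    aug_imgs.append(rotate_image(images[i], a, policy))
                    aug_labels.append(labels[i])
            trainer = (train_sequential if train_config.regime == "sequential"
                       else train_end_to_end)
            model, _ = trainer(model, aug_imgs, aug_labels, train_config,
                               num_classes=len(train_classes))

        # identify unseen-class queries by nearest leave-one-out class mean
        if frozen:
            test_feats = cache.get([(int(i), 0.0) for i in te_idx])
        else:
            test_feats = extract_concat_features(model, [images[i] for i in te_idx])
        preds = _leave_one_out_predictions(test_feats, labels[te_idx])
        order = tuple(sorted(test_classes))
        cm = confusion(preds, labels[te_idx].tolist(), order)
        names.append(name)
        cms.append(cm)
        reports.append(metrics(cm))
    return OpenWorldResult(names, reports, cms, _mean_report(reports))
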