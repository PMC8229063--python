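"""PCA + K-nearest-neighbour baseline over concat-layer features.

The concatenated 3968-d features are projected into the eigenspace of
their training covariance; a sweep over the number of retained
eigenvectors (lambda) scores each candidate by seeded cross-validated
accuracy on the training features, and the selected projection feeds a
KNN classifier (K = 1 by default; the neighbourhood size is
configurable).  Eigenvector signs are fixed by forcing the first nonzero
coordinate positive so fits are reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .closed_world import stratified_kfold

logger = logging.getLogger(__name__)

__all__ = ["PCAModel", "KNNConfig", "pca_fit", "pca_project", "knn_classify",
           "lambda_sweep"]


@dataclass
class PCAModel:
    """Training mean, orthonormal components (sorted), and eigenvalues."""

    mean: np.ndarray
    components: np.ndarray      # (r, D), rows are eigenvectors
    eigenvalues: np.ndarray     # (r,), non-increasing, >= 0

    @property
    def n_components(self) -> int:
        return self.components.shape[0]


@dataclass(frozen=True)
class KNNConfig:
    k: int = 1

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("K must be >= 1")


def _fix_signs(components: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    out = components.copy()
    for i, vec in enumerate(out):
        nz = np.flatnonzero(np.abs(vec) > tol)
        if len(nz) and vec[nz[0]] < 0:
            out[i] = -vec
    return out


def pca_fit(features: np.ndarray) -> PCAModel:
    """Eigendecomposition of the training covariance via SVD.

    Components are sorted by non-increasing eigenvalue; eigenvalues are
    the centered singular values squared over (N - 1), so their sum
    equals the total variance.  Constant features simply yield zero
    eigenvalues.
    """
    x = np.asarray(features, dtype=np.float64)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("pca_fit needs an (N >= 2) x D feature matrix")
    mean = x.mean(axis=0)
    centered = x - mean
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    eigenvalues = s ** 2 / (x.shape[0] - 1)
    components = _fix_signs(vt)
    return PCAModel(mean=mean, components=components, eigenvalues=eigenvalues)


def pca_project(model: PCAModel, features: np.ndarray, lam: int) -> np.ndarray:
    """Center by the training mean and project onto the top-lam components."""
    if not (1 <= lam <= model.n_components):
        raise ValueError(
            f"lambda={lam} out of range [1, {model.n_components}]")
    x = np.asarray(features, dtype=np.float64)
    single = x.ndim == 1
    if single:
        x = x[None, :]
    proj = (x - model.mean) @ model.components[:lam].T
    return proj[0] if single else proj


def knn_classify(train_proj: np.ndarray, train_labels, queries: np.ndarray,
                 config: KNNConfig = KNNConfig()) -> list:
    """Majority vote over the K nearest training points (Euclidean).

    Neighbour selection breaks distance ties toward the lowest label;
    vote ties also resolve to the lowest label.
    """
    train_proj = np.asarray(train_proj, dtype=np.float64)
    queries = np.asarray(queries, dtype=np.float64)
    if queries.ndim == 1:
        queries = queries[None, :]
    if train_proj.shape[0] == 0:
        raise ValueError("empty training set")
    if config.k > train_proj.shape[0]:
        raise ValueError(f"K={config.k} exceeds training size {train_proj.shape[0]}")
    labels = np.asarray(train_labels)
    classes, label_rank = np.unique(labels, return_inverse=True)
    out = []
    d2 = ((queries[:, None, :] - train_proj[None, :, :]) ** 2).sum(axis=2)
    for row in d2:
        order = np.lexsort((label_rank, row))[:config.k]
        votes = np.bincount(label_rank[order], minlength=len(classes))
        out.append(classes[int(votes.argmax())])  # argmax -> lowest label on ties
    return out


def lambda_sweep(features: np.ndarray, labels, lam_values, folds: int = 5,
                 seed: int = 0, config: KNNConfig = KNNConfig()):
    """Cross-validated accuracy per lambda on the training features.

    Returns (per-lambda mean accuracy dict, best lambda).  Ties resolve
    to the smallest lambda.  The sweep never touches held-out test data.
    """
    features = np.asarray(features, dtype=np.float64)
    labels = np.asarray(labels)
    lam_values = sorted(int(l) for l in lam_values)
    plan = stratified_kfold(labels, folds, seed)
    max_rank = min(features.shape[0] - max(
        len(plan.test_indices(f)) for f in range(folds)) - 1, features.shape[1])
    if lam_values[-1] > max_rank:
        raise ValueError(
            f"lambda up to {lam_values[-1]} exceeds the {max_rank} components "
            "available from the training folds")
    accs = {lam: [] for lam in lam_values}
    for fold in range(folds):
        tr, te = plan.train_indices(fold), plan.test_indices(fold)
        model = pca_fit(features[tr])
        for lam in lam_values:
            ptr = pca_project(model, features[tr], lam)
            pte = pca_project(model, features[te], lam)
            preds = knn_classify(ptr, labels[tr], pte, config)
            accs[lam].append(float(np.mean(np.asarray(preds) == labels[te])))
    curve = {lam: float(np.mean(v)) for lam, v in accs.items()}
    best = max(curve, key=lambda lam: (curve[lam], -lam))
    return curve, best
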