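"""PCA + KNN baseline: eigendecomposition against a brute-force covariance
oracle, projection geometry, neighbour voting, and the eigenvector sweep."""

import numpy as np
import pytest
from sklearn.decomposition import PCA as SkPCA
from sklearn.neighbors import KNeighborsClassifier

from drenet.pca_knn import (KNNConfig, knn_classify, lambda_sweep, pca_fit,
                            pca_project)


class TestPCAFit:
    def test_rank_one_line(self):
        x = np.linspace(-2, 2, 11)
        feats = np.stack([x, 2 * x], axis=1)
        model = pca_fit(feats)
        assert np.isclose(model.eigenvalues[1], 0.0, atol=1e-12)
        total_var = feats.var(axis=0, ddof=1).sum()
        assert np.isclose(model.eigenvalues[0], total_var)

    def test_matches_explicit_covariance_eigendecomposition(self):
        rng = np.random.default_rng(0)
        feats = rng.normal(size=(5, 3))
        model = pca_fit(feats)
        cov = np.cov(feats.T, ddof=1)
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        assert np.allclose(model.eigenvalues[:3], evals[order], atol=1e-8)
        for i in range(3):
            v = evecs[:, order[i]]
            assert np.allclose(np.abs(model.components[i] @ v), 1.0, atol=1e-8)

    def test_deterministic_with_sign_convention(self):
        rng = np.random.default_rng(1)
        feats = rng.normal(size=(20, 6))
        m1, m2 = pca_fit(feats), pca_fit(feats)
        assert np.array_equal(m1.components, m2.components)
        for vec in m1.components:
            nz = vec[np.abs(vec) > 1e-12]
            assert nz[0] > 0

    def test_eigenvalues_sorted_and_sum_to_total_variance(self):
        rng = np.random.default_rng(2)
        feats = rng.normal(size=(30, 8)) * np.arange(1, 9)
        model = pca_fit(feats)
        assert (np.diff(model.eigenvalues) <= 1e-9).all()
        assert np.isclose(model.eigenvalues.sum(),
                          feats.var(axis=0, ddof=1).sum(), rtol=1e-6)

    def test_agrees_with_sklearn(self):
        rng = np.random.default_rng(3)
        feats = rng.normal(size=(25, 10))
        model = pca_fit(feats)
        sk = SkPCA().fit(feats)
        assert np.allclose(model.eigenvalues[:10], sk.explained_variance_,
                           atol=1e-8)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError, match="N >= 2"):
            pca_fit(np.ones((1, 4)))


class TestProjection:
    def test_full_rank_projection_is_isometric(self):
        rng = np.random.default_rng(4)
        feats = rng.normal(size=(40, 6))
        model = pca_fit(feats)
        proj = pca_project(model, feats, 6)
        d_orig = np.linalg.norm(feats[:, None] - feats[None, :], axis=2)
        d_proj = np.linalg.norm(proj[:, None] - proj[None, :], axis=2)
        assert np.allclose(d_orig, d_proj, atol=1e-8)

    def test_lambda_10_reduces_3968_to_10(self):
        rng = np.random.default_rng(5)
        feats = rng.normal(size=(20, 3968))
        model = pca_fit(feats)
        assert pca_project(model, feats[0], 10).shape == (10,)
        assert pca_project(model, feats, 10).shape == (20, 10)

    def test_training_mean_projects_to_zero(self):
        rng = np.random.default_rng(6)
        feats = rng.normal(size=(15, 5)) + 7.0
        model = pca_fit(feats)
        assert np.allclose(pca_project(model, model.mean, 3), 0.0, atol=1e-9)

    def test_lambda_out_of_range_rejected(self):
        model = pca_fit(np.random.default_rng(7).normal(size=(6, 4)))
        with pytest.raises(ValueError, match="out of range"):
            pca_project(model, np.zeros(4), 0)
        with pytest.raises(ValueError, match="out of range"):
            pca_project(model, np.zeros(4), 99)

    def test_reconstruction_error_nonincreasing_in_lambda(self):
        rng = np.random.default_rng(8)
        feats = rng.normal(size=(30, 8)) * np.arange(1, 9)
        model = pca_fit(feats)
        errs = []
        for lam in range(1, 9):
            proj = pca_project(model, feats, lam)
            recon = proj @ model.components[:lam] + model.mean
            errs.append(np.linalg.norm(feats - recon))
        assert (np.diff(errs) <= 1e-9).all()


class TestKNN:
    def test_query_on_training_point(self):
        train = np.array([[0.0, 0.0], [5.0, 5.0]])
        assert knn_classify(train, ["A", "B"], train[1:])[0] == "B"

    def test_majority_vote(self):
        train = np.array([[0.0], [0.1], [3.0]])
        labels = ["A", "A", "B"]
        assert knn_classify(train, labels, np.array([[0.5]]),
                            KNNConfig(k=3))[0] == "A"

    def test_matches_exhaustive_oracle_and_sklearn(self):
        rng = np.random.default_rng(9)
        train = rng.normal(size=(50, 4))
        labels = rng.choice(["C1", "C2", "C3"], size=50)
        queries = rng.normal(size=(20, 4))
        preds = knn_classify(train, labels, queries, KNNConfig(k=1))
        for q, p in zip(queries, preds):
            d = np.linalg.norm(train - q, axis=1)
            assert p == labels[int(np.argmin(d))]
        sk = KNeighborsClassifier(n_neighbors=1).fit(train, labels)
        assert list(sk.predict(queries)) == list(preds)

    def test_k1_perfect_on_distinct_training_points(self):
        rng = np.random.default_rng(10)
        train = rng.normal(size=(30, 3))
        labels = rng.choice(["A", "B"], size=30)
        assert list(knn_classify(train, labels, train)) == list(labels)

    def test_vote_tie_breaks_to_lowest_label(self):
        train = np.array([[0.0], [1.0]])
        assert knn_classify(train, ["B", "A"], np.array([[0.5]]),
                            KNNConfig(k=2))[0] == "A"

    def test_k_exceeding_training_size_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            knn_classify(np.zeros((2, 2)), ["A", "B"], np.zeros((1, 2)),
                         KNNConfig(k=3))

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError, match=">= 1"):
            KNNConfig(k=0)


class TestLambdaSweep:
    def test_low_rank_class_structure_prefers_small_lambda(self):
        """Class information confined to a 4-d subspace: the sweep's best
        lambda stays small and accuracy plateaus beyond it."""
        rng = np.random.default_rng(11)
        basis = rng.normal(size=(4, 64))
        centers = rng.normal(size=(4, 4)) * 6
        feats, labels = [], []
        for i in range(4):
            z = centers[i] + rng.normal(0, 0.4, (25, 4))
            feats.append(z @ basis + rng.normal(0, 0.2, (25, 64)))
            labels += [f"C{i+1}"] * 25
        feats = np.vstack(feats)
        curve, best = lambda_sweep(feats, labels, range(1, 21), folds=5,
                                   seed=0)
        assert best <= 10
        assert curve[best] >= 0.95
        plateau = [curve[l] for l in range(10, 21)]
        assert max(plateau) - min(plateau) <= 0.05

    def test_singleton_range(self):
        rng = np.random.default_rng(12)
        feats = rng.normal(size=(40, 8))
        labels = ["A", "B"] * 20
        _, best = lambda_sweep(feats, labels, [5], folds=4, seed=0)
        assert best == 5

    def test_sweep_deterministic(self):
        rng = np.random.default_rng(13)
        feats = rng.normal(size=(40, 8))
        labels = list(rng.choice(["A", "B"], size=40))
        c1, b1 = lambda_sweep(feats, labels, range(1, 6), folds=4, seed=3)
        c2, b2 = lambda_sweep(feats, labels, range(1, 6), folds=4, seed=3)
        assert c1 == c2 and b1 == b2

    def test_lambda_beyond_fold_rank_rejected(self):
        rng = np.random.default_rng(14)
        feats = rng.normal(size=(10, 50))
        labels = ["A", "B"] * 5
        with pytest.raises(ValueError, match="exceeds"):
            lambda_sweep(feats, labels, [30], folds=2, seed=0)
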