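"""Closed-world protocol: fold balance, confusion tallies, macro metrics
against brute-force oracles, and the pooled paired t-test."""

import numpy as np
import pytest
from scipy import stats as sstats
from sklearn.metrics import precision_score, recall_score

from drenet.augment import RotationPolicy
from drenet.closed_world import (ConfusionMatrix, MetricsReport, confusion,
                                 metrics, pooled_paired_ttest,
                                 run_closed_world, stratified_kfold)
from drenet.training import TrainConfig


class TestFoldPlan:
    def test_real_dataset_balance_pattern(self):
        """Class sizes 83/294/71/149 at k=10: per-class test-fold sizes fall
        in {8,9}/{29,30}/{7,8}/{14,15}, and a fold testing 59 samples trains
        on the remaining 538 of 597."""
        labels = np.repeat(["C1", "C2", "C3", "C4"], [83, 294, 71, 149])
        plan = stratified_kfold(labels, 10, seed=0)
        counts = plan.per_class_fold_counts()
        bands = {"C1": {8, 9}, "C2": {29, 30}, "C3": {7, 8}, "C4": {14, 15}}
        for label, allowed in bands.items():
            assert set(counts.loc[label]) <= allowed
        for fold in range(10):
            n_test = len(plan.test_indices(fold))
            n_train = len(plan.train_indices(fold))
            assert n_train + n_test == 597
            if n_test == 59:
                assert n_train == 538

    def test_even_split(self):
        plan = stratified_kfold(["C2"] * 20, 10, seed=3)
        assert all(len(plan.test_indices(f)) == 2 for f in range(10))

    def test_partition_and_determinism(self):
        rng = np.random.default_rng(0)
        labels = rng.choice(["C1", "C2", "C3", "C4"], size=57)
        p1 = stratified_kfold(labels, 5, seed=9)
        p2 = stratified_kfold(labels, 5, seed=9)
        assert np.array_equal(p1.fold_id, p2.fold_id)
        all_test = np.concatenate([p1.test_indices(f) for f in range(5)])
        assert sorted(all_test) == list(range(57))
        # within-class fold sizes differ by at most 1
        counts = p1.per_class_fold_counts()
        assert (counts.max(axis=1) - counts.min(axis=1)).max() <= 1

    def test_small_class_warns(self):
        labels = ["C1"] * 3 + ["C2"] * 30
        with pytest.warns(UserWarning, match="C1"):
            stratified_kfold(labels, 10, seed=0)


class TestConfusion:
    def test_all_correct_is_diagonal(self):
        cm = confusion(["C1", "C2", "C3", "C4"], ["C1", "C2", "C3", "C4"])
        assert np.array_equal(cm.counts, np.eye(4, dtype=int))

    def test_two_class_tally(self):
        true = ["A"] * 10 + ["B"] * 10
        pred = ["A"] * 8 + ["B"] * 2 + ["A"] * 1 + ["B"] * 9
        cm = confusion(pred, true, labels=("A", "B"))
        assert cm.counts.tolist() == [[8, 2], [1, 9]]

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="Cx"):
            confusion(["Cx"], ["C1"])

    def test_per_class_counts_match_brute_force(self):
        rng = np.random.default_rng(11)
        labels = ("C1", "C2", "C3", "C4")
        true = rng.choice(labels, size=200)
        pred = rng.choice(labels, size=200)
        cm = confusion(pred, true)
        per = cm.per_class()
        for k in labels:
            tp = sum(1 for t, p in zip(true, pred) if t == k and p == k)
            fp = sum(1 for t, p in zip(true, pred) if t != k and p == k)
            fn = sum(1 for t, p in zip(true, pred) if t == k and p != k)
            tn = sum(1 for t, p in zip(true, pred) if t != k and p != k)
            assert per[k] == {"tp": tp, "fp": fp, "fn": fn, "tn": tn}
            assert tp + fp + fn + tn == 200


def _random_cm(rng, k=4, scale=30):
    return ConfusionMatrix(rng.integers(0, scale, size=(k, k)),
                           labels=tuple(f"C{i+1}" for i in range(k)))


class TestMetrics:
    def test_perfect_matrix_scores_100_in_all_modes(self):
        cm = ConfusionMatrix(np.diag([5, 6, 7, 8]))
        for am in ("overall", "eq4_literal"):
            r = metrics(cm, accuracy_mode=am)
            assert r.accuracy == r.precision == r.recall == r.f1 == 100.0

    def test_two_class_worked_example(self):
        cm = ConfusionMatrix(np.array([[8, 2], [1, 9]]), labels=("A", "B"))
        r = metrics(cm)
        assert np.isclose(r.recall, 85.0)       # (0.8 + 0.9) / 2
        assert np.isclose(r.accuracy, 85.0)     # 17 / 20
        # K = 2 makes the one-vs-rest literal accuracy equal the overall one
        assert np.isclose(metrics(cm, accuracy_mode="eq4_literal").accuracy, 85.0)

    def test_f1_identity_holds_for_every_report(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            r = metrics(_random_cm(rng))
            if r.precision + r.recall > 0:
                expected = 2 * r.precision * r.recall / (r.precision + r.recall)
                assert np.isclose(r.f1, expected, atol=1e-9)

    def test_k4_literal_accuracy_affine_identity(self):
        """For K=4 each error adds one FP and one FN, so the macro
        one-vs-rest accuracy is 100 - (100 - overall)/2."""
        rng = np.random.default_rng(1)
        for _ in range(100):
            cm = _random_cm(rng)
            if cm.total == 0:
                continue
            overall = metrics(cm).accuracy
            literal = metrics(cm, accuracy_mode="eq4_literal").accuracy
            assert np.isclose(literal, 100 - (100 - overall) / 2, atol=1e-9)

    def test_macro_metrics_agree_with_sklearn(self):
        rng = np.random.default_rng(2)
        labels = ("C1", "C2", "C3", "C4")
        true = rng.choice(labels, size=300)
        pred = rng.choice(labels, size=300)
        r = metrics(confusion(pred, true))
        assert np.isclose(r.precision / 100,
                          precision_score(true, pred, average="macro"))
        assert np.isclose(r.recall / 100,
                          recall_score(true, pred, average="macro"))
        assert np.isclose(r.accuracy / 100, np.mean(true == pred))

    def test_literal_recall_mode_uses_tn_denominator(self):
        cm = ConfusionMatrix(np.array([[8, 2], [1, 9]]), labels=("A", "B"))
        r = metrics(cm, recall_mode="eq7_literal")
        # TP/(TP+TN): (8/(8+9) + 9/(9+8)) / 2
        assert np.isclose(r.recall, 100 * 0.5 * (8 / 17 + 9 / 17))

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            metrics(ConfusionMatrix(np.zeros((4, 4), dtype=int)))

    def test_undefined_terms_contribute_zero_with_warning(self):
        cm = ConfusionMatrix(np.array([[5, 0], [3, 0]]), labels=("A", "B"))
        with pytest.warns(UserWarning, match="precision"):
            r = metrics(cm)
        assert r.precision == 100 * 0.5 * (5 / 8)


def _reports(values):
    return [MetricsReport(accuracy=a, f1=f, precision=p, recall=r)
            for a, f, p, r in values]


class TestPooledTTest:
    def test_identical_methods_give_p_one(self):
        a = _reports([(80, 79, 81, 78)] * 10)
        assert pooled_paired_ttest(a, a) == 1.0

    def test_constant_shift_gives_p_zero(self):
        rng = np.random.default_rng(3)
        vals = [tuple(rng.uniform(60, 90, 4)) for _ in range(10)]
        a = _reports(vals)
        b = _reports([tuple(v + 5 for v in row) for row in vals])
        assert pooled_paired_ttest(a, b) == 0.0

    def test_matches_textbook_formula_and_scipy(self):
        rng = np.random.default_rng(4)
        va = [tuple(rng.uniform(60, 90, 4)) for _ in range(10)]
        vb = [tuple(rng.uniform(60, 90, 4)) for _ in range(10)]
        p = pooled_paired_ttest(_reports(va), _reports(vb))
        a = np.array(va).ravel()
        b = np.array(vb).ravel()
        d = a - b
        t = d.mean() / (d.std(ddof=1) / np.sqrt(40))
        p_formula = 2 * sstats.t.sf(abs(t), 39)
        assert np.isclose(p, p_formula, atol=1e-10)
        assert np.isclose(p, sstats.ttest_rel(a, b).pvalue, atol=1e-10)

    def test_unequal_fold_counts_rejected(self):
        with pytest.raises(ValueError, match="same number"):
            pooled_paired_ttest(_reports([(1, 1, 1, 1)]), _reports([]))


class TestRunClosedWorld:
    def test_protocol_accounting_on_synthetic_data(self, small_dataset):
        manifest, images = small_dataset
        cfg = TrainConfig(seed=0, epochs_backbone=0)
        policy = RotationPolicy(angles_deg=(0.0, 90.0, 180.0, 270.0))
        result = run_closed_world(images, manifest["label"].tolist(), cfg,
                                  k=2, seed=0, policy=policy, input_size=56,
                                  bn_calibration=8)
        assert len(result.fold_reports) == 2
        # every sample is tested exactly once across folds
        total_tested = sum(cm.total for cm in result.fold_confusions)
        assert total_tested == len(images)
        assert result.mean_confusion.sum() * 2 == len(images)
        mean_acc = np.mean([r.accuracy for r in result.fold_reports])
        assert np.isclose(result.mean_report.accuracy, mean_acc)
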