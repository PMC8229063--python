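"""Training contracts: stratified splitting, the momentum-SGD update rule,
sequential freezing, and end-to-end gradient flow."""

import numpy as np
import pandas as pd
import pytest

from drenet.ensemble import DRENet
from drenet.training import (TrainConfig, sgd_step, split_train_validation,
                             train_end_to_end, train_scn_on_features,
                             train_sequential)


def _manifest(per_class):
    rows = []
    for label, n in per_class.items():
        rows += [{"path": f"{label}_{i}.png", "label": label, "split": "train"}
                 for i in range(n)]
    return pd.DataFrame(rows)


class TestSplit:
    def test_75_25_split(self):
        m = _manifest({"C1": 25, "C2": 25, "C3": 25, "C4": 25})
        train, val = split_train_validation(m, 0.25, seed=0)
        assert len(train) == 75 and len(val) == 25

    def test_stratification_exact_per_class(self):
        m = _manifest({c: 40 for c in ("C1", "C2", "C3", "C4")})
        train, val = split_train_validation(m, 0.25, seed=1)
        assert train["label"].value_counts().to_dict() == {c: 30 for c in
                                                           train["label"].unique()}
        assert val["label"].value_counts().to_dict() == {c: 10 for c in
                                                         val["label"].unique()}

    def test_deterministic_and_partition(self):
        m = _manifest({"C1": 13, "C2": 7})
        t1, v1 = split_train_validation(m, 0.3, seed=5)
        t2, v2 = split_train_validation(m, 0.3, seed=5)
        assert t1.equals(t2) and v1.equals(v2)
        merged = pd.concat([t1, v1]).sort_values("path").reset_index(drop=True)
        assert merged.equals(m.sort_values("path").reset_index(drop=True))

    def test_tiny_class_goes_entirely_to_train(self):
        m = _manifest({"C1": 1, "C2": 10})
        with pytest.warns(UserWarning, match="C1"):
            train, val = split_train_validation(m, 0.5, seed=0)
        assert (train["label"] == "C1").sum() == 1
        assert (val["label"] == "C1").sum() == 0


class TestSGDStep:
    def test_quadratic_closed_form(self):
        # loss w^2 at w=1 has gradient 2; lr 0.1 => w - 0.1*2 = 0.8
        cfg = TrainConfig(momentum=0.0, l2_regularization=0.0, learning_rate=0.1)
        (w,), _ = sgd_step([np.array(1.0)], [np.array(2.0)], None, cfg)
        assert np.isclose(w, 0.8)

    def test_zero_gradient_fixed_point(self):
        cfg = TrainConfig(l2_regularization=0.0)
        p = np.array([3.0, -1.0])
        (w,), (v,) = sgd_step([p], [np.zeros(2)], None, cfg)
        assert np.array_equal(w, p) and not v.any()

    def test_two_steps_match_explicit_recurrence(self):
        # quadratic loss 0.5*w'Aw with A = diag(2, 5)
        A = np.array([2.0, 5.0])
        cfg = TrainConfig(momentum=0.9, l2_regularization=0.0,
                          learning_rate=0.01)
        w = np.array([1.0, -2.0])
        state = None
        for _ in range(2):
            (w,), state = sgd_step([w], [A * w], state, cfg)
        # oracle: v_{t+1} = m v_t - lr g_t; w_{t+1} = w_t + v_{t+1}
        wo, vo = np.array([1.0, -2.0]), np.zeros(2)
        for _ in range(2):
            vo = 0.9 * vo - 0.01 * (A * wo)
            wo = wo + vo
        assert np.allclose(w, wo, atol=1e-12)

    def test_l2_term_enters_gradient(self):
        cfg = TrainConfig(momentum=0.0, l2_regularization=0.5,
                          learning_rate=1.0)
        (w,), _ = sgd_step([np.array(2.0)], [np.array(0.0)], None, cfg)
        assert np.isclose(w, 2.0 - 0.5 * 2.0)

    def test_nonfinite_gradient_names_block(self):
        cfg = TrainConfig()
        with pytest.raises(FloatingPointError, match="block 1"):
            sgd_step([np.zeros(2), np.zeros(2)],
                     [np.zeros(2), np.array([np.nan, 0.0])], None, cfg)

    def test_zero_lr_never_moves(self):
        cfg = TrainConfig(learning_rate=0.0)
        rng = np.random.default_rng(0)
        w = rng.normal(size=4)
        state = None
        cur = w.copy()
        for _ in range(5):
            (cur,), state = sgd_step([cur], [rng.normal(size=4)], state, cfg,
                                     lr=0.0)
        assert np.array_equal(cur, w)


class TestSCN:
    def test_separable_clusters_reach_full_accuracy_within_budget(self):
        rng = np.random.default_rng(0)
        centers = rng.normal(0, 1, (4, 3968)) * 3
        feats = np.vstack([c + rng.normal(0, 0.3, (30, 3968)) for c in centers])
        y = np.repeat(["C1", "C2", "C3", "C4"], 30)
        head, trace = train_scn_on_features(feats, y, TrainConfig(seed=0))
        steps_per_epoch = int(np.ceil(90 / 10))
        assert np.mean(trace.iteration_accuracy[-steps_per_epoch:]) == 1.0
        assert trace.epoch_val_accuracy[-1] == 1.0

    def test_trace_lengths_consistent(self):
        rng = np.random.default_rng(1)
        feats = rng.normal(size=(40, 8))
        y = np.repeat(["C1", "C2", "C3", "C4"], 10)
        _, trace = train_scn_on_features(feats, y, TrainConfig(seed=0),
                                         epochs=3)
        assert len(trace.epoch_val_loss) == 3
        assert len(trace.iteration_loss) == 3 * int(np.ceil(30 / 10))


@pytest.fixture(scope="module")
def tiny_model():
    return DRENet.build(seed=0, input_size=32)


@pytest.fixture(scope="module")
def tiny_data(tiny_model):
    rng = np.random.default_rng(2)
    images = [(rng.random((32, 32)) * 255).astype(np.uint8) for _ in range(8)]
    labels = ["C1", "C2", "C3", "C4"] * 2
    return images, labels


def _param_bytes(model):
    return [p.data.tobytes() for p in
            model.extractor_resnet.net.parameters()
            + model.extractor_densenet.net.parameters()]


class TestSequential:
    def test_frozen_backbones_untouched_by_scn_stage(self, tiny_model, tiny_data):
        images, labels = tiny_data
        cfg = TrainConfig(seed=0, epochs_backbone=0, epochs_scn=1,
                          validation_fraction=0.25)
        before = _param_bytes(tiny_model)
        model, traces = train_sequential(tiny_model, images, labels, cfg)
        assert _param_bytes(model) == before
        assert model.head is not None
        assert set(traces) == {"resnet", "densenet", "scn"}

    def test_backbone_finetuning_changes_backbone_parameters(self, tiny_data):
        images, labels = tiny_data
        model = DRENet.build(seed=3, input_size=32)
        cfg = TrainConfig(seed=0, epochs_backbone=1, epochs_scn=1,
                          minibatch=4)
        before = _param_bytes(model)
        model, _ = train_sequential(model, images, labels, cfg)
        assert _param_bytes(model) != before


class TestEndToEnd:
    def test_gradient_reaches_both_extractors_and_is_reproducible(self, tiny_data):
        images, labels = tiny_data
        cfg = TrainConfig(regime="end_to_end", seed=4, epochs_end_to_end=1,
                          minibatch=4)
        model1 = DRENet.build(seed=5, input_size=32)
        r_before = model1.extractor_resnet.net.state_dict()["conv1.weight"].copy()
        d_before = model1.extractor_densenet.net.state_dict()["conv1.weight"].copy()
        model1, trace = train_end_to_end(model1, images, labels, cfg)
        assert not np.array_equal(
            model1.extractor_resnet.net.state_dict()["conv1.weight"], r_before)
        assert not np.array_equal(
            model1.extractor_densenet.net.state_dict()["conv1.weight"], d_before)
        assert len(trace.iteration_loss) >= 1

        model2 = DRENet.build(seed=5, input_size=32)
        model2, _ = train_end_to_end(model2, images, labels, cfg)
        assert np.array_equal(model1.head.weights, model2.head.weights)
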