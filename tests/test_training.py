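import numpy as np
import pandas as pd
import pytest

from fundusgcn.backbone import BackboneConfig
from fundusgcn.label_graph import build_adjacency
from fundusgcn.nn import SGD, Param
from fundusgcn.training import (LesionGCNModel, OptimConfig, SplitSpec, fit,
                                loss_gradient, multilabel_softmargin_loss,
                                predict_labels, split_dataset)


def naive_loss(y_pred, y):
    """Direct, unvectorized evaluation of the one-versus-all logistic loss."""
    total = 0.0
    b, n = y_pred.shape
    for s in range(b):
        acc = 0.0
        for i in range(n):
            sig = 1.0 / (1.0 + np.exp(-y_pred[s, i]))
            acc += y[s, i] * np.log(sig) + (1 - y[s, i]) * np.log(1 - sig)
        total += -acc / n
    return total / b


class TestLoss:
    def test_zero_scores_give_ln2(self):
        y = np.array([[1, 0, 1, 0]])
        loss = multilabel_softmargin_loss(np.zeros((1, 4)), y)
        assert loss == pytest.approx(np.log(2), abs=1e-12)

    def test_ln3_closed_form(self):
        loss = multilabel_softmargin_loss(np.array([[np.log(3)]]),
                                          np.array([[1]]))
        assert loss == pytest.approx(np.log(4 / 3), abs=1e-9)

    def test_matches_naive_reference_on_random_batches(self):
        rng = np.random.default_rng(77)
        for _ in range(20):
            y_pred = rng.normal(scale=3.0, size=(5, 8))
            y = rng.integers(0, 2, size=(5, 8))
            got = multilabel_softmargin_loss(y_pred, y)
            assert got == pytest.approx(naive_loss(y_pred, y), abs=1e-9)

    def test_stable_at_extreme_scores(self):
        y_pred = np.array([[800.0, -800.0]])
        loss = multilabel_softmargin_loss(y_pred, np.array([[1, 0]]))
        assert np.isfinite(loss) and loss == pytest.approx(0.0, abs=1e-12)

    def test_non_binary_labels_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            multilabel_softmargin_loss(np.zeros((1, 2)),
                                       np.array([[0.5, 1.0]]))

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(3, 4))
        y = rng.integers(0, 2, size=(3, 4))
        g = loss_gradient(x, y)
        eps = 1e-6
        for idx in [(0, 0), (1, 3), (2, 2)]:
            xp, xm = x.copy(), x.copy()
            xp[idx] += eps
            xm[idx] -= eps
            num = (multilabel_softmargin_loss(xp, y)
                   - multilabel_softmargin_loss(xm, y)) / (2 * eps)
            assert g[idx] == pytest.approx(num, abs=1e-8)


class TestPredictLabels:
    def test_strict_threshold_at_zero_score(self):
        np.testing.assert_array_equal(
            predict_labels(np.array([0.1, -0.1, 0.0])), [1, 0, 0])

    def test_large_scores_all_positive(self):
        np.testing.assert_array_equal(predict_labels(np.full(3, 1e6)),
                                      [1, 1, 1])

    def test_threshold_logit_algebra(self):
        cut = np.log(9)
        scores = np.array([cut - 1e-9, cut + 1e-9])
        np.testing.assert_array_equal(predict_labels(scores, threshold=0.9),
                                      [0, 1])

    def test_monotone_threshold_consistency(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=50)
        for t in (0.2, 0.5, 0.8):
            cut = np.log(t / (1 - t))
            np.testing.assert_array_equal(predict_labels(scores, t),
                                          (scores > cut).astype(int))


class TestSplitDataset:
    @pytest.fixture
    def manifest(self):
        return pd.DataFrame({"image_path": [f"i{j}.png" for j in range(100)],
                             "a": np.arange(100) % 2})

    def test_sizes_70_15_15(self, manifest):
        tr, va, te = split_dataset(manifest, SplitSpec(seed=3))
        assert (len(tr), len(va), len(te)) == (70, 15, 15)

    def test_same_seed_identical_partition(self, manifest):
        p1 = split_dataset(manifest, SplitSpec(seed=9))
        p2 = split_dataset(manifest, SplitSpec(seed=9))
        for a, b in zip(p1, p2):
            pd.testing.assert_frame_equal(a, b)

    def test_exact_disjoint_partition(self, manifest):
        tr, va, te = split_dataset(manifest, SplitSpec(seed=1))
        idx = [set(p.index) for p in (tr, va, te)]
        assert idx[0] | idx[1] | idx[2] == set(manifest.index)
        assert not (idx[0] & idx[1] or idx[0] & idx[2] or idx[1] & idx[2])
        assert all(p["split"].iloc[0] == name
                   for p, name in zip((tr, va, te), ("train", "val", "test")))

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SplitSpec(train=0.8, val=0.15, test=0.15)


def _tiny_model(seed=0):
    cfg = BackboneConfig(name="t", input_size=16, stages=((4, 3, 2), (6, 3, 2)))
    Y = np.array([[1, 1, 0], [1, 0, 1], [0, 1, 1], [1, 1, 1]])
    A_hat = build_adjacency(Y)["A_normalized"]
    X = np.random.default_rng(seed).normal(size=(3, 5))
    return LesionGCNModel(cfg, [5, 4, 6], X, A_hat, ["a", "b", "c"],
                          seed=seed)


class TestFit:
    @pytest.fixture
    def batch(self):
        rng = np.random.default_rng(0)
        return (rng.random((8, 3, 16, 16)), rng.integers(0, 2, size=(8, 3)))

    def test_one_epoch_descends_on_training_batch(self, batch):
        images, labels = batch
        model = _tiny_model()
        before = multilabel_softmargin_loss(model.forward(images), labels)
        cfg = OptimConfig(epochs=1, batch_size=8, lr_backbone=0.001,
                          lr_head=0.01, seed=0)
        fit(model, images, labels, None, None, cfg)
        after = multilabel_softmargin_loss(model.forward(images), labels)
        assert after < before

    def test_identical_seeds_identical_weights(self, batch):
        images, labels = batch
        states = []
        for _ in range(2):
            model = _tiny_model(seed=5)
            fit(model, images, labels, None, None,
                OptimConfig(epochs=2, batch_size=4, seed=7))
            states.append(model.get_state())
        for key in states[0]:
            np.testing.assert_array_equal(states[0][key], states[1][key])

    def test_empty_split_rejected(self):
        model = _tiny_model()
        with pytest.raises(ValueError, match="empty"):
            fit(model, np.zeros((0, 3, 16, 16)), np.zeros((0, 3)),
                None, None, OptimConfig())

    def test_parameter_groups_receive_configured_rates(self):
        model = _tiny_model()
        groups = {p.group for p in model.params}
        assert groups == {"backbone", "head"}
        backbone_names = {p.name for p in model.params
                          if p.group == "backbone"}
        assert all(n.startswith("backbone.") for n in backbone_names)
        head_names = {p.name for p in model.params if p.group == "head"}
        assert any(n.startswith("gcn.") for n in head_names)
        assert any(n.startswith("downsample.") for n in head_names)
        # a single step moves each param by -lr * (grad + wd * value)
        opt = SGD(model.params, {"backbone": 0.01, "head": 0.1},
                  momentum=0.0, weight_decay=0.0)
        opt.zero_grad()
        for p in model.params:
            p.grad[...] = 1.0
        before = {p.name: p.value.copy() for p in model.params}
        opt.step()
        for p in model.params:
            lr = 0.01 if p.group == "backbone" else 0.1
            np.testing.assert_allclose(before[p.name] - p.value, lr,
                                       atol=1e-15)

    def test_checkpoint_roundtrip(self, tmp_path, batch):
        images, _ = batch
        model = _tiny_model(seed=2)
        scores_before = model.predict_scores(images)
        path = tmp_path / "ckpt.npz"
        model.save(path)
        # same fixed inputs (X, A_hat), scrambled weights, then restore
        other = _tiny_model(seed=2)
        for p in other.params:
            p.value += 1.0
        other.load(path)
        np.testing.assert_array_equal(other.predict_scores(images),
                                      scores_before)


class TestSGDUpdateRule:
    def test_momentum_and_weight_decay_arithmetic(self):
        p = Param(np.array([1.0]), group="head", name="w")
        opt = SGD([p], {"head": 0.1}, momentum=0.9, weight_decay=0.5)
        p.grad[...] = 2.0
        opt.step()  # v = 2 + 0.5*1 = 2.5; w = 1 - 0.25 = 0.75
        assert p.value[0] == pytest.approx(0.75)
        p.zero_grad()
        p.grad[...] = 1.0
        opt.step()  # v = 0.9*2.5 + (1 + 0.5*0.75) = 3.625
        assert p.value[0] == pytest.approx(0.75 - 0.3625)
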