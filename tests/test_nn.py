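"""1D-CNN: architecture contracts, losses vs enumeration, gradient check."""

import math

import numpy as np
import pytest

from emoselect.nn import (
    Cnn1DClassifier,
    ModelConfig,
    _Conv1D,
    _Dense,
    activation,
    batch_element_count,
    binary_cross_entropy,
    build_model,
    categorical_cross_entropy,
    grid_search,
    input_vector_length,
    train,
)

TINY = ModelConfig(filters=(3, 3, 2, 2), kernels=(3, 3, 3, 1),
                   hidden_units=4, dropout_conv=0.0, dropout_fc=0.0,
                   batch_size=8, epochs=3, dtype="float64",
                   early_stop_patience=None)


class TestActivation:
    def test_standard_relu_clamps_negatives(self):
        assert activation(-3.0) == 0.0
        assert activation(2.5) == 2.5

    def test_softplus_at_zero_is_ln2(self):
        assert activation(0.0, "softplus") == pytest.approx(math.log(2))

    def test_softplus_large_input_stable(self):
        out = activation(50.0, "softplus")
        assert np.isfinite(out)
        assert out == pytest.approx(50.0, abs=1e-12)

    def test_softplus_large_negative(self):
        assert activation(-100.0, "softplus") == pytest.approx(0.0,
                                                                   abs=1e-12)


class TestLosses:
    def test_perfect_binary_prediction_near_zero(self):
        assert binary_cross_entropy([1, 0], [1.0, 0.0]) < 1e-5

    def test_binary_half_confidence_ln2(self):
        assert binary_cross_entropy([1.0], [0.5]) == pytest.approx(math.log(2))

    def test_binary_matches_enumeration(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 4).astype(float)
        p = rng.uniform(0.05, 0.95, 4)
        manual = -np.mean([yi * math.log(pi) + (1 - yi) * math.log(1 - pi)
                           for yi, pi in zip(y, p)])
        assert binary_cross_entropy(y, p) == pytest.approx(manual, abs=1e-6)

    def test_categorical_perfect_near_zero(self):
        y = np.eye(3)
        assert categorical_cross_entropy(y, y) < 1e-5

    def test_categorical_uniform_ln3(self):
        y = np.eye(3)
        p = np.full((3, 3), 1 / 3)
        assert categorical_cross_entropy(y, p) == pytest.approx(math.log(3))

    def test_categorical_matches_enumeration(self):
        rng = np.random.default_rng(1)
        p = rng.dirichlet(np.ones(3), size=3)
        y = np.eye(3)[rng.integers(0, 3, 3)]
        manual = -np.mean([sum(y[i, k] * math.log(p[i, k]) for k in range(3))
                           for i in range(3)])
        assert categorical_cross_entropy(y, p) == pytest.approx(manual,
                                                                abs=1e-6)


class TestBuildModel:
    def test_default_architecture(self):
        m = build_model(ModelConfig(), 2560, 2)
        convs = [l for l in m.layers if isinstance(l, _Conv1D)]
        assert len(convs) == 4
        assert [c.params["W"].shape[0] for c in convs] == [64, 32, 32, 16]
        assert [c.k for c in convs] == [5, 5, 3, 1]

    def test_binary_head_single_sigmoid_unit(self):
        m = build_model(ModelConfig(), 512, 2)
        last = [l for l in m.layers if isinstance(l, _Dense)][-1]
        assert last.params["W"].shape[1] == 1
        assert m.head == "sigmoid_binary"

    def test_three_class_head_softmax(self):
        m = build_model(ModelConfig(), 512, 3)
        last = [l for l in m.layers if isinstance(l, _Dense)][-1]
        assert last.params["W"].shape[1] == 3
        assert m.head == "softmax_3class"

    def test_param_count_deterministic(self):
        a = build_model(ModelConfig(), 512, 2, seed=1)
        b = build_model(ModelConfig(), 512, 2, seed=2)
        assert a.count_params() == b.count_params()

    def test_input_too_small_raises(self):
        with pytest.raises(ValueError):
            build_model(ModelConfig(), 6, 2)

    def test_head_optimizer_pairing(self):
        assert ModelConfig().resolve_head(2) == ("sigmoid_binary", "adadelta")
        assert ModelConfig().resolve_head(3) == ("softmax_3class", "adam")


class TestGradients:
    @pytest.mark.parametrize("n_classes", [2, 3])
    def test_numeric_vs_analytic(self, n_classes):
        """Backprop gradients agree with central finite differences on a
        tiny float64 model (dropout off; BN in batch mode). The smooth
        softplus activation is used because the rectifier is genuinely
        non-differentiable at 0 (upstream rectifiers park exact zeros on
        the kink, where finite differences and subgradients must differ)."""
        rng = np.random.default_rng(0)
        x = rng.standard_normal((6, 32))
        y_idx = rng.integers(0, n_classes, 6)
        model = build_model(TINY.replace(activation="softplus"), 32,
                            n_classes, seed=0)
        if n_classes == 2:
            y_enc = y_idx.astype(float)
        else:
            y_enc = np.zeros((6, n_classes))
            y_enc[np.arange(6), y_idx] = 1.0

        model.loss_and_grad(x, y_enc, training=True)
        analytic = {(i, name): layer.grads[name].copy()
                    for (i, name), layer, _ in model.parameters()}

        def loss_only():
            z = model._forward(x, training=True)
            if n_classes == 2:
                from emoselect.nn import _sigmoid
                return binary_cross_entropy(y_enc, _sigmoid(z).ravel())
            from emoselect.nn import _softmax
            return categorical_cross_entropy(y_enc, _softmax(z))

        h = 1e-6
        rng2 = np.random.default_rng(1)
        checked = 0
        for (i, name), layer, p in model.parameters():
            flat = p.ravel()
            for idx in rng2.choice(flat.size, size=min(4, flat.size),
                                   replace=False):
                orig = flat[idx]
                flat[idx] = orig + h
                lp = loss_only()
                flat[idx] = orig - h
                lm = loss_only()
                flat[idx] = orig
                num = (lp - lm) / (2 * h)
                ana = analytic[(i, name)].ravel()[idx]
                assert num == pytest.approx(ana, rel=1e-4, abs=1e-7), \
                    f"layer {i} param {name}[{idx}]"
                checked += 1
        assert checked > 20


class TestTraining:
    @staticmethod
    def separable(n=48, n_in=64, seed=0):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal((n, n_in))
        y = np.array(["neg", "pos"] * (n // 2))
        x[y == "pos"] += 1.5
        return x, y

    def test_loss_decreases_on_separable_data(self):
        x, y = self.separable()
        wins = 0
        for seed in range(5):
            model = build_model(TINY.replace(epochs=8), 64, 2, seed=seed)
            train(model, x, y, seed=seed)
            hist = model.history["loss"]
            wins += hist[-1] < hist[0]
        assert wins >= 4  # majority of seeds

    def test_zero_learning_rate_freezes_weights(self):
        x, y = self.separable()
        cfg = TINY.replace(optimizer="sgd", learning_rate=0.0, momentum=0.0,
                           epochs=3, batch_size=64)  # one batch -> flat loss
        model = build_model(cfg, 64, 2, seed=0)
        before = [p.copy() for _, _, p in model.parameters()]
        train(model, x, y, cfg, seed=0)
        after = [p for _, _, p in model.parameters()]
        for b, a in zip(before, after):
            assert np.array_equal(b, a)
        assert np.ptp(model.history["loss"]) < 1e-6

    def test_training_deterministic_under_seed(self):
        x, y = self.separable()
        hists = []
        for _ in range(2):
            model = build_model(TINY, 64, 2, seed=3)
            train(model, x, y, seed=3)
            hists.append(model.history["loss"])
        assert hists[0] == hists[1]

    def test_early_stop_records_short_history(self):
        x, y = self.separable()
        cfg = TINY.replace(epochs=200, early_stop_patience=2)
        model = build_model(cfg, 64, 2, seed=0)
        train(model, x, y, cfg, seed=0)
        assert len(model.history["loss"]) < 200


class TestClassifierEstimator:
    def test_fit_predict_binary(self):
        x, y = TestTraining.separable()
        clf = Cnn1DClassifier(filters=(3, 3, 2, 2), kernels=(3, 3, 3, 1),
                              hidden_units=4, dropout_conv=0.0,
                              dropout_fc=0.0, epochs=40, batch_size=8,
                              random_state=0).fit(x, y)
        assert set(clf.predict(x)) <= {"neg", "pos"}
        assert clf.predict_proba(x).shape == (len(y), 2)
        assert clf.score(x, y) > 0.9

    def test_three_class_proba_simplex(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((30, 64))
        y = np.array(["a", "b", "c"] * 10)
        x[y == "b"] += 2; x[y == "c"] -= 2
        clf = Cnn1DClassifier(filters=(3, 3, 2, 2), kernels=(3, 3, 3, 1),
                              hidden_units=4, epochs=3, batch_size=8,
                              random_state=0).fit(x, y)
        p = clf.predict_proba(x)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-5)

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            Cnn1DClassifier().fit(np.zeros((4, 64)), np.zeros(4))

    def test_sklearn_clone(self):
        from sklearn.base import clone

        clf = Cnn1DClassifier(epochs=5, hidden_units=16)
        assert clone(clf).get_params() == clf.get_params()


class TestGridSearch:
    def test_single_point_grid(self):
        x, y = TestTraining.separable(n=24)
        best, results = grid_search({"hidden_units": [4]}, x, y, x, y,
                                    base=TINY.replace(epochs=2))
        assert best.hidden_units == 4
        assert len(results) == 1

    def test_ties_prefer_fewer_parameters(self):
        # all-zero inputs force a constant prediction, so both grid points
        # score exactly 0.5 on balanced labels: a guaranteed tie
        x = np.zeros((16, 64))
        y = np.array(["neg", "pos"] * 8)
        cfg = TINY.replace(epochs=1, learning_rate=0.0, optimizer="sgd",
                           momentum=0.0, batch_size=64)
        best, results = grid_search({"hidden_units": [8, 4]}, x, y, x, y,
                                    base=cfg)
        accs = [r[1] for r in results]
        assert accs[0] == accs[1] == 0.5
        assert best.hidden_units == 4

    def test_reproducible_ranking(self):
        x, y = TestTraining.separable(n=24)
        space = {"hidden_units": [4, 8]}
        base = TINY.replace(epochs=2)
        r1 = grid_search(space, x, y, x, y, seed=5, base=base)[1]
        r2 = grid_search(space, x, y, x, y, seed=5, base=base)[1]
        assert [a for _, a, _ in r1] == [a for _, a, _ in r2]

    def test_empty_grid_raises(self):
        with pytest.raises(ValueError):
            grid_search({}, None, None, None, None)

    def test_selected_values_are_a_grid_point(self):
        """The production defaults lie inside the documented search ranges."""
        from sklearn.model_selection import ParameterGrid

        space = {"conv_layers": [3, 4, 8], "batch_size": [32, 64, 128],
                 "learning_rate": [0.0005, 0.005, 0.01],
                 "momentum": [0.1, 0.9], "epochs": [50, 100, 200]}
        defaults = ModelConfig()
        assert any(all(getattr(defaults, k) == v for k, v in point.items())
                   for point in ParameterGrid(space))


class TestGeometryHelpers:
    def test_input_vector_lengths(self):
        assert input_vector_length(10, 2, 128) == 2560
        assert input_vector_length(10, 2, 256) == 5120

    def test_batch_element_counts(self):
        assert batch_element_count(2560, 64) == 163840
        assert batch_element_count(5120, 64) == 327680
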