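import numpy as np
import pytest

from mutclass import (
    NetworkConfig,
    TrainConfig,
    TrainingDivergedError,
    backward,
    forward,
    log_loss,
    predict,
    softmax,
    train,
)
from mutclass.dnn import (
    NetworkParams,
    init_params,
    one_hot,
    predict_batch,
    save_checkpoint,
    load_checkpoint,
)
from _oracles import mlp_forward_reference, numeric_gradients


def small_net(dims, seed=0):
    rng = np.random.default_rng(seed)
    return NetworkParams(
        weights=[rng.standard_normal((o, i)) for i, o in zip(dims[:-1], dims[1:])],
        biases=[rng.standard_normal(o) for o in dims[1:]],
    )


class TestForward:
    def test_zero_params_give_zero_logits(self):
        params = NetworkParams(
            weights=[np.zeros((3, 2)), np.zeros((2, 3))],
            biases=[np.zeros(3), np.zeros(2)],
        )
        _, logits = forward(np.array([1.0, -1.0]), params)
        assert np.array_equal(logits, np.zeros((1, 2)))

    def test_hand_arithmetic_single_unit(self):
        params = NetworkParams(weights=[np.array([[2.0]])], biases=[np.array([1.0])])
        _, logits = forward(np.array([3.0]), params)
        assert logits.item() == 7.0  # z = 2*3 + 1; output layer has no ReLU

    def test_matches_loop_reference_on_random_net(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            dims = rng.integers(1, 6, size=rng.integers(2, 5)).tolist()
            params = small_net(dims, seed=int(rng.integers(1000)))
            x = rng.standard_normal(dims[0])
            _, logits = forward(x, params)
            expected = mlp_forward_reference(x, params.weights, params.biases)
            np.testing.assert_allclose(logits[0], expected, rtol=1e-12)

    def test_shape_mismatch_is_an_error(self):
        params = small_net([3, 2])
        with pytest.raises(ValueError, match="width"):
            forward(np.ones(4), params)


class TestSoftmaxAndLoss:
    def test_equal_logits_give_uniform_probabilities(self):
        p = softmax(np.zeros(12))
        np.testing.assert_allclose(p, np.full(12, 1 / 12), rtol=1e-12)

    def test_shift_invariance(self):
        logits = np.array([0.3, -1.2, 5.0])
        np.testing.assert_allclose(softmax(logits), softmax(logits + 100.0), rtol=1e-12)

    def test_closed_form_two_classes(self):
        np.testing.assert_allclose(
            softmax(np.array([0.0, np.log(3)])), [0.25, 0.75], rtol=1e-12
        )

    def test_simplex_invariant(self):
        rng = np.random.default_rng(3)
        p = softmax(rng.standard_normal((50, 7)) * 50)
        assert (p >= 0).all()
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-12)

    @pytest.mark.parametrize(
        "p_true, expected",
        [(1.0, 0.0), (1 / 12, np.log(12)), (0.5, np.log(2))],
    )
    def test_log_loss_closed_forms(self, p_true, expected):
        probs = np.full(12, (1 - p_true) / 11)
        probs[4] = p_true
        y = np.zeros(12)
        y[4] = 1.0
        assert log_loss(probs, y) == pytest.approx(expected, rel=1e-12)

    def test_zero_probability_is_clamped(self):
        probs = np.array([0.0, 1.0])
        assert np.isfinite(log_loss(probs, np.array([1.0, 0.0])))


class TestBackward:
    def test_single_linear_layer_gradient_is_p_minus_y(self):
        params = NetworkParams(weights=[np.zeros((3, 3))], biases=[np.zeros(3)])
        x = np.eye(3)[0]
        y = np.array([0.0, 1.0, 0.0])
        grads_w, grads_b = backward(x, y, params)
        p = softmax(np.zeros(3))
        np.testing.assert_allclose(grads_b[0], p - y, rtol=1e-12)

    def test_perfect_prediction_gives_zero_logit_gradient(self):
        # drive one logit to near-certainty: gradient magnitude ~ (1 - P_true)
        params = NetworkParams(weights=[np.array([[100.0], [-100.0]])],
                               biases=[np.zeros(2)])
        grads_w, grads_b = backward(np.array([1.0]), np.array([1.0, 0.0]), params)
        np.testing.assert_allclose(grads_b[0], 0.0, atol=1e-12)

    def test_finite_difference_check_all_layers(self):
        """Backprop gradients agree with central differences on a 5-3-2 net."""
        rng = np.random.default_rng(99)
        params = small_net([5, 3, 2], seed=1)
        x = rng.standard_normal((4, 5))
        y = one_hot(rng.integers(1, 3, size=4), 2)
        wd = 5e-4

        def pack(params):
            return np.concatenate([a.ravel() for a in params.weights + params.biases])

        def unpack(flat):
            out = small_net([5, 3, 2], seed=1)
            pos = 0
            for arr in out.weights + out.biases:
                arr[...] = flat[pos: pos + arr.size].reshape(arr.shape)
                pos += arr.size
            return out

        def loss_fn(flat):
            p = unpack(flat)
            _, logits = forward(x, p)
            penalty = 0.5 * wd * sum((w ** 2).sum() for w in p.weights)
            return log_loss(softmax(logits), y) + penalty

        grads_w, grads_b = backward(x, y, params, weight_decay=wd)
        analytic = np.concatenate([g.ravel() for g in grads_w + grads_b])
        numeric = numeric_gradients(loss_fn, pack(params), step=1e-6)
        denom = np.maximum(np.abs(numeric), 1e-8)
        assert np.max(np.abs(analytic - numeric) / denom) < 1e-5

    def test_decay_touches_weights_not_biases(self):
        params = small_net([2, 2])
        x, y = np.array([1.0, 2.0]), np.array([1.0, 0.0])
        gw0, gb0 = backward(x, y, params, weight_decay=0.0)
        gw1, gb1 = backward(x, y, params, weight_decay=0.1)
        np.testing.assert_allclose(gw1[0] - gw0[0], 0.1 * params.weights[0], rtol=1e-12)
        np.testing.assert_allclose(gb1[0], gb0[0], rtol=1e-12)


class TestTraining:
    @staticmethod
    def blobs(seed=0, n=60):
        rng = np.random.default_rng(seed)
        x = np.vstack([
            rng.normal([-2, 0], 0.5, size=(n // 2, 2)),
            rng.normal([2, 0], 0.5, size=(n // 2, 2)),
        ])
        y = np.repeat([1, 2], n // 2)
        return x, y

    def test_separable_blobs_reach_perfect_training_accuracy(self):
        x, y = self.blobs()
        cfg = NetworkConfig(input_dim=2, output_dim=2, hidden_layers=1, units_per_layer=8)
        params, history = train(x, y, cfg, TrainConfig(max_epochs=50, batch_size=16, seed=0))
        assert (predict_batch(x, params) == y).all()
        assert history[-1] < history[0]

    def test_zero_epochs_returns_initial_params(self):
        x, y = self.blobs()
        cfg = NetworkConfig(input_dim=2, output_dim=2, hidden_layers=1, units_per_layer=4)
        tcfg = TrainConfig(max_epochs=0, lr_schedule=np.array([]), seed=5)
        params, history = train(x, y, cfg, tcfg)
        expected = init_params(cfg, np.random.default_rng(5))
        for a, b in zip(params.weights, expected.weights):
            np.testing.assert_array_equal(a, b)
        assert history == []

    def test_identical_seed_gives_identical_parameters(self):
        x, y = self.blobs()
        cfg = NetworkConfig(input_dim=2, output_dim=2, hidden_layers=2, units_per_layer=8)
        tcfg = TrainConfig(max_epochs=10, batch_size=16, seed=3)
        p1, h1 = train(x, y, cfg, tcfg)
        p2, h2 = train(x, y, cfg, tcfg)
        assert h1 == h2
        for a, b in zip(p1.weights, p2.weights):
            assert np.array_equal(a, b)

    def test_divergence_raises(self):
        x, y = self.blobs()
        cfg = NetworkConfig(input_dim=2, output_dim=2, hidden_layers=1, units_per_layer=8)
        tcfg = TrainConfig(max_epochs=30, lr_schedule=np.full(30, 1e12), seed=0)
        with pytest.raises((TrainingDivergedError, FloatingPointError)):
            with np.errstate(over="raise", invalid="raise"):
                train(x, y, cfg, tcfg)

    def test_weight_decay_shrinks_norms_on_null_labels(self):
        # single class: loss gradient vanishes, decay dominates
        rng = np.random.default_rng(0)
        x = rng.standard_normal((32, 4))
        y = np.ones(32, dtype=int)
        cfg = NetworkConfig(input_dim=4, output_dim=1, hidden_layers=1, units_per_layer=4)
        tcfg = TrainConfig(max_epochs=8, lr_schedule=np.full(8, 0.05),
                           weight_decay=0.01, batch_size=32, seed=1)
        params, _ = train(x, y, cfg, tcfg)
        initial = init_params(cfg, np.random.default_rng(1))
        assert sum((w ** 2).sum() for w in params.weights) < sum(
            (w ** 2).sum() for w in initial.weights
        )


class TestPredict:
    def test_argmax_and_tie_rule(self):
        params = NetworkParams(weights=[np.zeros((3, 2))], biases=[np.array([0.0, 1.0, 0.0])])
        res = predict(np.ones(2), params)
        assert res.predicted_class == 2
        tie = predict(np.ones(2), NetworkParams([np.zeros((2, 2))], [np.zeros(2)]))
        assert tie.predicted_class == 1  # exact tie -> lowest class index
        assert tie.probabilities == pytest.approx([0.5, 0.5])

    def test_batch_equals_per_sample(self):
        rng = np.random.default_rng(8)
        params = small_net([4, 5, 3], seed=2)
        x = rng.standard_normal((6, 4))
        batch = predict_batch(x, params)
        singles = [predict(row, params).predicted_class for row in x]
        assert batch.tolist() == singles


class TestCheckpoint:
    def test_roundtrip(self, tmp_path):
        params = small_net([3, 4, 2], seed=7)
        meta = {"class_names": ["a", "b"], "n_isr": 5}
        save_checkpoint(tmp_path / "m.npz", params, meta)
        back, meta2 = load_checkpoint(tmp_path / "m.npz")
        assert meta2 == meta
        for a, b in zip(params.weights, back.weights):
            np.testing.assert_array_equal(a, b)
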