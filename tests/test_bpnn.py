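"""Network forward pass, analytic gradients, trainer, and accuracy."""

import numpy as np
import pytest

from qrsnet import bpnn
from qrsnet.bpnn import (
    DivergenceError,
    NetworkParams,
    TrainConfig,
    accuracy,
    forward,
    gradients,
    init_network,
    pack,
    param_count,
    predict_class,
    train,
    unpack,
)
from qrsnet.types import InvalidArgumentError


def fd_gradient(params, x, t, h=1e-6):
    """Central finite differences of E = ½ Σ (t - z)², the standard check."""
    vec = pack(params)
    out = np.empty_like(vec)
    for i in range(vec.size):
        vp, vm = vec.copy(), vec.copy()
        vp[i] += h
        vm[i] -= h
        ep = bpnn.sample_error(unpack(params.layer_sizes, vp, params.transfers), x, t)
        em = bpnn.sample_error(unpack(params.layer_sizes, vm, params.transfers), x, t)
        out[i] = (ep - em) / (2 * h)
    return out


def flat_gradient(params, x, t):
    dW, dTh = gradients(params, x, t)
    return np.concatenate([w.ravel() for w in dW] + [th.ravel() for th in dTh])


class TestInit:
    def test_16_5_1_shapes_and_91_parameters(self):
        p = init_network((16, 5, 1), seed=0)
        assert p.weights[0].shape == (5, 16)
        assert p.weights[1].shape == (1, 5)
        assert p.thresholds[0].shape == (5,)
        assert p.thresholds[1].shape == (1,)
        assert p.n_params == 91
        assert param_count((16, 5, 1)) == 16 * 5 + 5 + 5 * 1 + 1

    def test_seed_reproducibility(self):
        a, b = init_network((4, 3, 2), seed=7), init_network((4, 3, 2), seed=7)
        assert all(np.array_equal(x, y) for x, y in zip(a.weights, b.weights))
        c = init_network((4, 3, 2), seed=8)
        assert any(not np.array_equal(x, y) for x, y in zip(a.weights, c.weights))

    def test_invalid_sizes(self):
        with pytest.raises(InvalidArgumentError):
            init_network((16, 0, 1), seed=0)
        with pytest.raises(InvalidArgumentError):
            init_network((16,), seed=0)


class TestForward:
    def test_zero_network_outputs_zero(self):
        p = init_network((3, 4, 2), seed=0)
        for w in p.weights:
            w[:] = 0
        for th in p.thresholds:
            th[:] = 0
        assert np.allclose(forward(p, np.ones(3)), 0.0)

    def test_binary_sigmoid_value_and_derivative_at_zero(self):
        assert bpnn._f("logsig", 0.0) == pytest.approx(0.5)
        assert bpnn._fprime_from_output("logsig", 0.5) == pytest.approx(0.25)

    def test_matches_two_loop_evaluation(self):
        rng = np.random.default_rng(3)
        p = init_network((4, 3, 2), seed=3)
        x = rng.uniform(-1, 1, 4)
        # hand-rolled evaluation with explicit loops
        y = np.empty(3)
        for j in range(3):
            y[j] = np.tanh(sum(p.weights[0][j, i] * x[i] for i in range(4))
                           - p.thresholds[0][j])
        z = np.empty(2)
        for l in range(2):
            z[l] = sum(p.weights[1][l, j] * y[j] for j in range(3)) - p.thresholds[1][l]
        assert np.allclose(forward(p, x), z, atol=1e-12)

    def test_dimension_mismatch(self):
        with pytest.raises(InvalidArgumentError):
            forward(init_network((4, 2), seed=0), np.ones(3))


class TestGradients:
    def test_zero_at_exact_fit(self):
        # single linear unit reproducing its target exactly
        p = unpack((1, 1), np.array([2.0, 0.0]), transfers=("purelin",))
        g = flat_gradient(p, np.array([1.5]), np.array([3.0]))
        assert np.allclose(g, 0.0, atol=1e-12)

    def test_linear_output_closed_form(self):
        # dE/dnu = -(t - z) * y for a linear output unit
        p = init_network((2, 3, 1), seed=1)
        x = np.array([0.3, -0.7])
        t = np.array([2.0])
        z = forward(p, x)
        a_hidden = np.tanh(p.weights[0] @ x - p.thresholds[0])
        dW, _ = gradients(p, x, t)
        assert np.allclose(dW[1], -(t - z)[:, None] * a_hidden[None, :], atol=1e-12)

    @pytest.mark.parametrize("transfers", [("tansig", "purelin"), ("logsig", "logsig")])
    def test_finite_difference_agreement(self, transfers):
        rng = np.random.default_rng(0)
        for draw in range(20):
            p = init_network((6, 4, 2), seed=draw, transfers=transfers)
            x = rng.uniform(-1, 1, 6)
            t = rng.uniform(-1, 1, 2)
            a = flat_gradient(p, x, t)
            f = fd_gradient(p, x, t)
            assert np.all(np.abs(a - f) <= 1e-6 * np.maximum(1.0, np.abs(a)))


class TestTrain:
    def test_returns_immediately_when_goal_met(self):
        p = unpack((1, 1), np.array([2.0, 0.0]), transfers=("purelin",))
        X = np.array([[1.0], [2.0]])
        T = 2.0 * X
        out, history = train(p, X, T, TrainConfig(epochs=100, goal=1e-9))
        assert len(history) == 1
        assert history[0][0] == pytest.approx(0.0, abs=1e-15)

    def test_linear_regression_recovers_slope(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(-1, 1, size=(50, 1))
        T = 2.0 * X
        p0 = init_network((1, 1), seed=1, transfers=("purelin",))
        cfg = TrainConfig(epochs=20000, goal=1e-10, lr=0.05, momentum=0.0)
        p, history = train(p0, X, T, cfg)
        assert p.weights[0][0, 0] == pytest.approx(2.0, abs=1e-3)
        assert abs(p.thresholds[0][0]) < 1e-3

    def test_descent_never_accepts_large_increase(self):
        rng = np.random.default_rng(4)
        X = rng.uniform(-1, 1, size=(30, 3))
        T = rng.uniform(-1, 1, size=(30, 1))
        p0 = init_network((3, 4, 1), seed=2)
        _, history = train(p0, X, T, TrainConfig(epochs=300, goal=1e-12, lr=0.01))
        mses = [m for m, _ in history]
        for prev, cur in zip(mses, mses[1:]):
            assert cur <= prev * 1.04 + 1e-12

    def test_adaptive_lr_moves(self):
        rng = np.random.default_rng(5)
        X = rng.uniform(-1, 1, size=(20, 2))
        T = (X[:, :1] + X[:, 1:]) / 2
        _, history = train(init_network((2, 3, 1), seed=0), X, T,
                           TrainConfig(epochs=100, goal=1e-12, lr=0.01))
        lrs = {lr for _, lr in history}
        assert len(lrs) > 1

    def test_bit_reproducible(self):
        rng = np.random.default_rng(6)
        X = rng.uniform(-1, 1, size=(20, 2))
        T = X[:, :1]
        cfg = TrainConfig(epochs=200, goal=1e-12, lr=0.01)
        p1, h1 = train(init_network((2, 3, 1), seed=9), X, T, cfg)
        p2, h2 = train(init_network((2, 3, 1), seed=9), X, T, cfg)
        assert h1 == h2
        assert all(np.array_equal(a, b) for a, b in zip(p1.weights, p2.weights))

    def test_divergence_detected(self):
        p0 = init_network((1, 1), seed=0, transfers=("purelin",))
        X = np.array([[1e3], [-1e3]])
        T = np.array([[1e3], [-1e3]])
        with pytest.raises(DivergenceError):
            train(p0, X, T, TrainConfig(epochs=5000, goal=1e-12, lr=1e6,
                                        max_perf_inc=np.inf))

    def test_empty_training_set_rejected(self):
        with pytest.raises(InvalidArgumentError):
            train(init_network((2, 1), seed=0), np.empty((0, 2)), np.empty((0, 1)),
                  TrainConfig())


class TestPrediction:
    @pytest.mark.parametrize("output,expected", [
        (2.4, 2), (7.3, 5), (0.2, 1), (2.5, 3), (4.49, 4),
    ])
    def test_round_and_clip(self, output, expected):
        p = unpack((1, 1), np.array([0.0, -output]), transfers=("purelin",))
        assert predict_class(p, np.array([0.0])) == expected

    def test_accuracy_arithmetic(self):
        assert accuracy([1, 2, 3], [1, 2, 3]) == 100.0
        pred = np.ones(75)
        actual = np.ones(75)
        actual[:3] = 2
        assert accuracy(pred, actual) == pytest.approx(96.0)
        assert accuracy([1, 1], [2, 2]) == 0.0

    def test_accuracy_empty_rejected(self):
        with pytest.raises(InvalidArgumentError):
            accuracy([], [])


class TestPackUnpack:
    def test_round_trip(self):
        p = init_network((5, 4, 2), seed=0)
        q = unpack(p.layer_sizes, pack(p), p.transfers)
        assert all(np.array_equal(a, b) for a, b in zip(p.weights, q.weights))
        assert all(np.array_equal(a, b) for a, b in zip(p.thresholds, q.thresholds))

    def test_json_round_trip(self):
        p = init_network((3, 2), seed=1)
        q = bpnn.from_json(bpnn.to_json(p))
        assert q.layer_sizes == p.layer_sizes
        assert np.array_equal(q.weights[0], p.weights[0])

    def test_length_mismatch(self):
        with pytest.raises(InvalidArgumentError):
            unpack((16, 5, 1), np.zeros(90))
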