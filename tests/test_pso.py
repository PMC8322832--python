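"""Constriction factor, swarm updates, fitness, and PSO-BPNN composition."""

import dataclasses

import numpy as np
import pytest

from qrsnet import bpnn
from qrsnet.bpnn import TrainConfig, forward_batch, init_network, pack, param_count, unpack
from qrsnet.pso import (
    Swarm,
    SwarmConfig,
    constriction,
    fitness,
    init_swarm,
    optimize_fn,
    step,
    train_pso_bpnn,
)
from qrsnet.types import InvalidArgumentError


def sphere(x):
    return float(np.sum(np.asarray(x) ** 2))


class TestConstriction:
    def test_boundary_phi_4(self):
        assert constriction(2.0, 2.0) == pytest.approx(1.0)

    def test_standard_parameters(self):
        # phi = 4.1: k = 2 / |2 - 4.1 - sqrt(4.1^2 - 4*4.1)|
        assert constriction(2.05, 2.05) == pytest.approx(0.7298, abs=2e-4)

    def test_study_parameters(self):
        # c1=2.5, c2=2.7: the formula gives ~0.351, not the printed 0.37
        assert constriction(2.5, 2.7) == pytest.approx(0.3510, abs=2e-4)

    def test_phi_below_4_rejected(self):
        with pytest.raises(InvalidArgumentError):
            constriction(1.0, 2.0)


class TestSwarmConfig:
    def test_validation(self):
        with pytest.raises(InvalidArgumentError):
            SwarmConfig(n_particles=1)
        with pytest.raises(InvalidArgumentError):
            SwarmConfig(c1=1.0, c2=1.0)
        with pytest.raises(InvalidArgumentError):
            SwarmConfig(vmax=0.0)
        with pytest.raises(InvalidArgumentError):
            SwarmConfig(wmax=0.1, wmin=0.9)

    def test_explicit_k_lifts_phi_constraint(self):
        cfg = SwarmConfig(c1=0.0, c2=0.0, k=1.0)
        assert cfg.constriction_factor == 1.0

    def test_k_defaults_to_formula(self):
        assert SwarmConfig().constriction_factor == pytest.approx(
            constriction(2.5, 2.7))


class TestStep:
    def _swarm_at(self, X, V):
        fit = np.array([sphere(x) for x in X])
        g = int(np.argmin(fit))
        return Swarm(X=X.copy(), V=V.copy(), pbest=X.copy(), pbest_fit=fit.copy(),
                     gbest=X[g].copy(), gbest_fit=float(fit[g]))

    def test_converged_particle_stays_fixed(self):
        X = np.tile([0.5, -0.5], (2, 1))
        swarm = self._swarm_at(X, np.zeros_like(X))
        cfg = SwarmConfig(n_particles=2, c1=2.5, c2=2.7)
        out = step(swarm, w=0.9, k=0.5, cfg=cfg, rng=np.random.default_rng(0),
                   fitness_fn=sphere)
        assert np.allclose(out.X, X)
        assert np.allclose(out.V, 0.0)

    def test_pure_inertia_advances_by_velocity(self):
        X = np.array([[0.1, 0.2], [0.3, -0.4]])
        V = np.array([[0.05, -0.05], [0.01, 0.02]])
        swarm = self._swarm_at(X, V)
        cfg = SwarmConfig(n_particles=2, c1=0.0, c2=0.0, k=1.0)
        out = step(swarm, w=1.0, k=1.0, cfg=cfg, rng=np.random.default_rng(0),
                   fitness_fn=sphere)
        assert np.allclose(out.X, X + V)
        assert np.allclose(out.V, V)

    def test_matches_scripted_rng_update(self):
        rng_a = np.random.default_rng(123)
        X = np.array([[0.5, -1.0], [-0.2, 0.8]])
        V = np.array([[0.1, 0.0], [0.0, -0.1]])
        swarm = self._swarm_at(X, V)
        cfg = SwarmConfig(n_particles=2, c1=2.5, c2=2.7, vmax=1.0)
        k, w = 0.37, 0.9
        out = step(swarm, w=w, k=k, cfg=cfg, rng=rng_a, fitness_fn=sphere)
        # replay the same draws by hand
        rng_b = np.random.default_rng(123)
        r1 = rng_b.random((2, 2))
        r2 = rng_b.random((2, 2))
        V_exp = k * (w * V + 2.5 * r1 * (swarm.pbest - X) + 2.7 * r2 * (swarm.gbest - X))
        V_exp = np.clip(V_exp, -1.0, 1.0)
        assert np.allclose(out.V, V_exp)
        assert np.allclose(out.X, X + V_exp)

    def test_velocity_clamped(self):
        X = np.array([[5.0, -5.0], [-5.0, 5.0]])
        swarm = self._swarm_at(X, np.zeros_like(X))
        swarm.gbest = np.array([-5.0, 5.0])
        cfg = SwarmConfig(n_particles=2, c1=2.5, c2=2.7, vmax=0.5)
        out = step(swarm, w=0.9, k=1.0, cfg=cfg, rng=np.random.default_rng(1),
                   fitness_fn=sphere)
        assert np.max(np.abs(out.V)) <= 0.5 + 1e-12


class TestFitness:
    def test_exact_network_scores_zero(self):
        p = unpack((1, 1), np.array([2.0, 0.0]), transfers=("purelin",))
        X = np.array([[1.0], [2.0], [3.0]])
        T = 2.0 * X
        assert fitness(pack(p), (1, 1), X, T, ("purelin",)) == pytest.approx(0.0)

    def test_constant_output_closed_form(self):
        # z == 0 for zero weights; balanced targets 1..5
        p = init_network((16, 5, 1), seed=0)
        for w in p.weights:
            w[:] = 0
        for th in p.thresholds:
            th[:] = 0
        X = np.zeros((5, 16))
        T = np.arange(1.0, 6.0).reshape(-1, 1)
        expected = np.mean(T**2)
        assert fitness(pack(p), (16, 5, 1), X, T) == pytest.approx(expected)

    def test_matches_loop_computation(self):
        rng = np.random.default_rng(2)
        p = init_network((4, 3, 1), seed=5)
        X = rng.uniform(-1, 1, (10, 4))
        T = rng.uniform(1, 5, (10, 1))
        Z = forward_batch(p, X)
        expected = sum((t[0] - z[0]) ** 2 for t, z in zip(T, Z)) / 10
        assert fitness(pack(p), (4, 3, 1), X, T) == pytest.approx(expected)

    def test_length_mismatch(self):
        with pytest.raises(InvalidArgumentError):
            fitness(np.zeros(10), (16, 5, 1), np.zeros((2, 16)), np.zeros((2, 1)))


class TestOptimize:
    def test_huge_minerr_stops_after_initialization(self):
        cfg = SwarmConfig(n_particles=5, itermax=100, minerr=1e12, seed=0)
        _, history = optimize_fn(sphere, dim=3, cfg=cfg)
        assert len(history) == 1

    def test_sphere_minimized_median_of_10_seeds(self):
        finals = []
        for seed in range(10):
            cfg = SwarmConfig(n_particles=20, itermax=100, minerr=0.0, seed=seed)
            best, history = optimize_fn(sphere, dim=5, cfg=cfg)
            finals.append(history[-1])
        assert np.median(finals) < 1e-3

    def test_gbest_history_non_increasing_and_positions_bounded(self):
        cfg = SwarmConfig(n_particles=10, itermax=100, minerr=0.0, seed=3)
        best, history = optimize_fn(sphere, dim=5, cfg=cfg)
        assert all(a >= b for a, b in zip(history, history[1:]))
        assert np.all(np.isfinite(best))
        assert np.max(np.abs(best)) < 100.0


class TestTrainPsoBpnn:
    def _dataset(self, seed=0):
        rng = np.random.default_rng(seed)
        centers = rng.uniform(-1, 1, (5, 8))
        X = np.vstack([c + 0.05 * rng.normal(size=(15, 8)) for c in centers])
        y = np.repeat(np.arange(1.0, 6.0), 15).reshape(-1, 1)
        order = rng.permutation(75)
        return X[order], y[order]

    def test_zero_iterations_reduces_to_bpnn_from_gbest(self):
        X, T = self._dataset()
        swarm_cfg = SwarmConfig(n_particles=5, itermax=0, seed=1)
        train_cfg = TrainConfig(epochs=50, goal=1e-9, lr=0.01, seed=1)
        params, info = train_pso_bpnn(X, T, swarm_cfg, train_cfg, layer_sizes=(8, 5, 1))
        assert len(info["swarm_history"]) == 1
        start = pack(info["initial_params"])
        assert start.size == param_count((8, 5, 1))

    def test_end_to_end_bit_reproducible(self):
        X, T = self._dataset(3)
        swarm_cfg = SwarmConfig(n_particles=8, itermax=10, seed=5)
        train_cfg = TrainConfig(epochs=100, goal=1e-9, lr=0.001, seed=5)
        p1, _ = train_pso_bpnn(X, T, swarm_cfg, train_cfg, layer_sizes=(8, 5, 1))
        p2, _ = train_pso_bpnn(X, T, swarm_cfg, train_cfg, layer_sizes=(8, 5, 1))
        assert all(np.array_equal(a, b) for a, b in zip(p1.weights, p2.weights))

    def test_swarm_seeding_beats_plain_bpnn_at_median(self):
        """Paired-seed comparison on separable 5-class features."""
        diffs = []
        for seed in range(10):
            X, T = self._dataset(seed)
            train_cfg = TrainConfig(epochs=3000, goal=0.0002, lr=0.0003, seed=seed)
            p_plain, _ = bpnn.train(init_network((8, 5, 1), seed=seed), X, T, train_cfg)
            swarm_cfg = SwarmConfig(n_particles=20, itermax=30, seed=seed)
            p_pso, _ = train_pso_bpnn(X, T, swarm_cfg, train_cfg, layer_sizes=(8, 5, 1))
            acc = lambda p: bpnn.accuracy(bpnn.predict_classes(p, X), T[:, 0].astype(int))
            diffs.append(acc(p_pso) - acc(p_plain))
        assert np.median(diffs) >= 0.0
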