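"""Constriction-factor particle swarm over flattened network parameters.

Velocity update (per particle i, dimension d):

    V <- k * [ w V + c1 r1 (P_i - X) + c2 r2 (P_g - X) ],   X <- X + V

with one uniform draw per term per dimension, elementwise velocity clamping
to [-vmax, vmax], a linearly decreasing inertia weight w, and the
constriction factor

    k = 2 / |2 - phi - sqrt(phi^2 - 4 phi)|,   phi = c1 + c2 >= 4.

Fitness of a position is the mean squared error of the unflattened
network's raw outputs on a held-out evaluation set; the swarm's best
position then seeds backpropagation fine-tuning.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import bpnn
from .types import InvalidArgumentError


@dataclass
class SwarmConfig:
    """Swarm hyperparameters (defaults follow the study protocol)."""

    n_particles: int = 75
    itermax: int = 100
    c1: float = 2.5  # local (cognitive) learning factor
    c2: float = 2.7  # global (social) learning factor
    wmax: float = 0.95
    wmin: float = 0.10
    vmax: float = 1.0
    minerr: float = 0.0001
    seed: int = 0
    k: float | None = None  # computed from c1, c2 unless overridden

    def __post_init__(self) -> None:
        if self.n_particles < 2:
            raise InvalidArgumentError("need at least 2 particles")
        if self.k is None and self.c1 + self.c2 < 4:
            # the constriction formula needs phi >= 4; an explicit k override
            # (e.g. for degenerate-parameter studies) lifts the constraint
            raise InvalidArgumentError("constriction requires c1 + c2 >= 4")
        if self.wmin > self.wmax:
            raise InvalidArgumentError("wmin must not exceed wmax")
        if self.vmax <= 0:
            raise InvalidArgumentError("vmax must be positive")

    @property
    def constriction_factor(self) -> float:
        return self.k if self.k is not None else constriction(self.c1, self.c2)


@dataclass
class Swarm:
    """Positions, velocities, and personal/global bests."""

    X: np.ndarray  # (N, D) positions
    V: np.ndarray  # (N, D) velocities
    pbest: np.ndarray  # (N, D)
    pbest_fit: np.ndarray  # (N,)
    gbest: np.ndarray  # (D,)
    gbest_fit: float


def constriction(c1: float, c2: float) -> float:
    """k = 2 / |2 - phi - sqrt(phi² - 4 phi)| with phi = c1 + c2 >= 4."""
    phi = c1 + c2
    if phi < 4:
        raise InvalidArgumentError(f"c1 + c2 must be >= 4, got {phi}")
    return 2.0 / abs(2.0 - phi - math.sqrt(phi**2 - 4.0 * phi))


def init_swarm(fitness_fn, dim: int, cfg: SwarmConfig, rng: np.random.Generator) -> Swarm:
    X = rng.uniform(-1.0, 1.0, size=(cfg.n_particles, dim))
    V = np.zeros_like(X)
    fit = np.asarray([fitness_fn(x) for x in X], dtype=float)
    g = int(np.argmin(fit))
    return Swarm(X=X, V=V, pbest=X.copy(), pbest_fit=fit.copy(),
                 gbest=X[g].copy(), gbest_fit=float(fit[g]))


def step(swarm: Swarm, w: float, k: float, cfg: SwarmConfig,
         rng: np.random.Generator, fitness_fn) -> Swarm:
    """One velocity/position update followed by a pbest/gbest refresh."""
    N, D = swarm.X.shape
    r1 = rng.random((N, D))
    r2 = rng.random((N, D))
    V = k * (w * swarm.V
             + cfg.c1 * r1 * (swarm.pbest - swarm.X)
             + cfg.c2 * r2 * (swarm.gbest - swarm.X))
    np.clip(V, -cfg.vmax, cfg.vmax, out=V)
    X = swarm.X + V
    fit = np.asarray([fitness_fn(x) for x in X], dtype=float)
    improved = fit < swarm.pbest_fit
    pbest = np.where(improved[:, None], X, swarm.pbest)
    pbest_fit = np.where(improved, fit, swarm.pbest_fit)
    g = int(np.argmin(pbest_fit))
    gbest, gbest_fit = pbest[g].copy(), float(pbest_fit[g])
    if gbest_fit > swarm.gbest_fit:  # guard: global best never worsens
        gbest, gbest_fit = swarm.gbest, swarm.gbest_fit
    return Swarm(X=X, V=V, pbest=pbest, pbest_fit=pbest_fit,
                 gbest=gbest, gbest_fit=gbest_fit)


def fitness(position, layer_sizes, eval_X, eval_T, transfers=None) -> float:
    """MSE of the unflattened network's raw outputs on the evaluation set."""
    params = bpnn.unpack(layer_sizes, position, transfers)
    T = np.asarray(eval_T, dtype=float)
    if T.ndim == 1:
        T = T.reshape(-1, 1)
    Z = bpnn.forward_batch(params, eval_X)
    return float(np.mean((T - Z) ** 2))


def optimize_fn(fitness_fn, dim: int, cfg: SwarmConfig):
    """Minimize an arbitrary fitness function; returns (best_position, history).

    ``history`` is the per-iteration global-best fitness, starting with the
    value after initialization; it is non-increasing by construction.
    """
    rng = np.random.default_rng(cfg.seed)
    k = cfg.constriction_factor
    swarm = init_swarm(fitness_fn, dim, cfg, rng)
    history = [swarm.gbest_fit]
    if swarm.gbest_fit < cfg.minerr or cfg.itermax == 0:
        return swarm.gbest, history
    denom = max(cfg.itermax - 1, 1)
    for it in range(cfg.itermax):
        w = cfg.wmax - (cfg.wmax - cfg.wmin) * (it / denom)
        swarm = step(swarm, w, k, cfg, rng, fitness_fn)
        history.append(swarm.gbest_fit)
        if swarm.gbest_fit < cfg.minerr:
            break
    return swarm.gbest, history


def optimize(layer_sizes, eval_X, eval_T, cfg: SwarmConfig, transfers=None):
    """PSO over network parameters; fitness = held-out MSE."""
    dim = bpnn.param_count(layer_sizes)

    def fn(pos):
        return fitness(pos, layer_sizes, eval_X, eval_T, transfers)

    return optimize_fn(fn, dim, cfg)


def train_pso_bpnn(train_X, train_T, swarm_cfg: SwarmConfig, train_cfg: bpnn.TrainConfig,
                   layer_sizes=(16, 5, 1), transfers=None,
                   eval_X=None, eval_T=None, val_fraction: float = 0.2):
    """PSO-optimized initial weights, then backpropagation fine-tuning.

    By default the swarm's fitness is evaluated on a validation split carved
    from the last ``val_fraction`` of the training rows (pass ``eval_X`` /
    ``eval_T`` explicitly to evaluate elsewhere, e.g. on the test set for a
    fidelity run).  Returns ``(trained params, info)`` with the swarm and
    training histories.
    """
    train_X = np.asarray(train_X, dtype=float)
    train_T = np.asarray(train_T, dtype=float)
    if train_T.ndim == 1:
        train_T = train_T.reshape(-1, 1)
    if eval_X is None:
        n_val = max(1, int(round(val_fraction * train_X.shape[0])))
        eval_X, eval_T = train_X[-n_val:], train_T[-n_val:]
    best, swarm_history = optimize(layer_sizes, eval_X, eval_T, swarm_cfg, transfers)
    params0 = bpnn.unpack(layer_sizes, best, transfers)
    params, train_history = bpnn.train(params0, train_X, train_T, train_cfg)
    return params, {"swarm_history": swarm_history, "train_history": train_history,
                    "initial_params": params0}
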