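"""Feed-forward network and backpropagation trainer, from first principles.

The network computes, layer by layer,

    y_j = f(net_j),   net_j = sum_i w_ji x_i - theta_j

with a tanh sigmoid ('tansig') in hidden layers and a linear output
('purelin') by default; the binary sigmoid ('logsig', f = 1/(1+e^-x),
f' = f(1-f)) is available as an option.  Training is batch gradient
descent on the mean squared error with momentum and an adaptive learning
rate: the rate grows by ``lr_up`` after an epoch that lowers the error and
shrinks by ``lr_down`` — with the step rejected — after an epoch that
raises it by more than 4%.

The single linear output regresses the class id; predictions are obtained
by rounding and clipping into [1, 5].
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .types import InvalidArgumentError

N_CLASSES = 5


class DivergenceError(FloatingPointError):
    """Training loss became non-finite."""


def _f(name: str, x):
    if name == "tansig":
        return np.tanh(x)
    if name == "logsig":
        return 1.0 / (1.0 + np.exp(-x))
    if name == "purelin":
        return x
    raise InvalidArgumentError(f"unknown transfer {name!r}")


def _fprime_from_output(name: str, y):
    # derivatives expressed through the activation value itself
    if name == "tansig":
        return 1.0 - y**2
    if name == "logsig":
        return y * (1.0 - y)
    if name == "purelin":
        return np.ones_like(y)
    raise InvalidArgumentError(f"unknown transfer {name!r}")


@dataclass
class NetworkParams:
    """Layer sizes, weight matrices, thresholds, and transfer names.

    ``weights[k]`` has shape (layer_sizes[k+1], layer_sizes[k]);
    ``thresholds[k]`` has shape (layer_sizes[k+1],).  A unit's net input is
    ``W a - theta``.
    """

    layer_sizes: tuple
    weights: list
    thresholds: list
    transfers: tuple

    def copy(self) -> "NetworkParams":
        return NetworkParams(self.layer_sizes, [w.copy() for w in self.weights],
                             [t.copy() for t in self.thresholds], self.transfers)

    @property
    def n_params(self) -> int:
        return sum(w.size for w in self.weights) + sum(t.size for t in self.thresholds)


@dataclass
class TrainConfig:
    """Batch-training hyperparameters (defaults follow the study protocol)."""

    epochs: int = 100_000
    goal: float = 0.0002
    lr: float = 0.0003
    momentum: float = 0.9
    lr_up: float = 1.05
    lr_down: float = 0.7
    max_perf_inc: float = 1.04  # reject steps raising MSE by more than 4%
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.goal <= 0 or self.lr <= 0 or not 0 <= self.momentum < 1:
            raise InvalidArgumentError("invalid training configuration")


def default_transfers(n_layers: int) -> tuple:
    return ("tansig",) * (n_layers - 2) + ("purelin",)


def init_network(layer_sizes, seed: int = 0, transfers=None) -> NetworkParams:
    """Uniform [-1, 1] weights and thresholds, reproducible from ``seed``."""
    layer_sizes = tuple(int(s) for s in layer_sizes)
    if len(layer_sizes) < 2 or any(s < 1 for s in layer_sizes):
        raise InvalidArgumentError(f"need >= 2 layers of size >= 1, got {layer_sizes}")
    if transfers is None:
        transfers = default_transfers(len(layer_sizes))
    transfers = tuple(transfers)
    if len(transfers) != len(layer_sizes) - 1:
        raise InvalidArgumentError("one transfer per connection layer required")
    rng = np.random.default_rng(seed)
    weights, thresholds = [], []
    for a, b in zip(layer_sizes, layer_sizes[1:]):
        weights.append(rng.uniform(-1.0, 1.0, size=(b, a)))
        thresholds.append(rng.uniform(-1.0, 1.0, size=b))
    return NetworkParams(layer_sizes, weights, thresholds, transfers)


def forward(params: NetworkParams, x) -> np.ndarray:
    """Output vector for one input vector."""
    a = np.asarray(x, dtype=float)
    if a.shape != (params.layer_sizes[0],):
        raise InvalidArgumentError(
            f"input length {a.shape} != {params.layer_sizes[0]}")
    for W, th, tf in zip(params.weights, params.thresholds, params.transfers):
        a = _f(tf, W @ a - th)
    return a


def forward_batch(params: NetworkParams, X) -> np.ndarray:
    """Outputs for a (n, in) matrix of inputs; returns (n, out)."""
    A = np.asarray(X, dtype=float)
    if A.ndim != 2 or A.shape[1] != params.layer_sizes[0]:
        raise InvalidArgumentError(f"X must be (n, {params.layer_sizes[0]})")
    for W, th, tf in zip(params.weights, params.thresholds, params.transfers):
        A = _f(tf, A @ W.T - th)
    return A


def _forward_trace(params: NetworkParams, A):
    activations = [A]
    for W, th, tf in zip(params.weights, params.thresholds, params.transfers):
        A = _f(tf, A @ W.T - th)
        activations.append(A)
    return activations


def _backprop(params: NetworkParams, X, T, scale: float):
    """Gradients of ``scale * sum over samples of ½||t - z||²``."""
    activations = _forward_trace(params, X)
    Z = activations[-1]
    delta = -(T - Z) * _fprime_from_output(params.transfers[-1], Z)  # dE/dnet
    dW = [None] * len(params.weights)
    dTh = [None] * len(params.thresholds)
    for k in range(len(params.weights) - 1, -1, -1):
        dW[k] = scale * (delta.T @ activations[k])
        dTh[k] = scale * (-delta.sum(axis=0))  # net = Wa - theta
        if k > 0:
            delta = (delta @ params.weights[k]) * _fprime_from_output(
                params.transfers[k - 1], activations[k])
    return dW, dTh, Z


def gradients(params: NetworkParams, x, t):
    """Analytic gradients of E = ½ Σ_l (t_l − z_l)² for one sample.

    Returns ``(dE_dW, dE_dtheta)`` lists matching the parameter layout;
    verified against central finite differences elsewhere.
    """
    x = np.asarray(x, dtype=float).reshape(1, -1)
    t = np.asarray(t, dtype=float).reshape(1, -1)
    if x.shape[1] != params.layer_sizes[0] or t.shape[1] != params.layer_sizes[-1]:
        raise InvalidArgumentError("dimension mismatch")
    dW, dTh, _ = _backprop(params, x, t, scale=1.0)
    return dW, dTh


def sample_error(params: NetworkParams, x, t) -> float:
    """E = ½ Σ_l (t_l − z_l)² for one sample."""
    z = forward(params, np.asarray(x, dtype=float))
    return 0.5 * float(np.sum((np.asarray(t, dtype=float) - z) ** 2))


def batch_mse(params: NetworkParams, X, T) -> float:
    Z = forward_batch(params, X)
    with np.errstate(over="ignore", invalid="ignore"):  # divergence handled by caller
        return float(np.mean((np.asarray(T, dtype=float) - Z) ** 2))


def train(params: NetworkParams, X, T, cfg: TrainConfig):
    """Batch gradient descent with momentum and adaptive learning rate.

    Returns ``(trained params, history)``; ``history`` is a list of
    ``(mse, lr)`` per epoch including the initial state.
    """
    X = np.asarray(X, dtype=float)
    T = np.asarray(T, dtype=float)
    if T.ndim == 1:
        T = T.reshape(-1, 1)
    if X.shape[0] == 0:
        raise InvalidArgumentError("training set must be non-empty")
    params = params.copy()
    lr = cfg.lr
    mse = batch_mse(params, X, T)
    history = [(mse, lr)]
    if mse <= cfg.goal:
        return params, history
    scale = 2.0 / T.size  # d(MSE)/d(sum of per-sample E)
    vW = [np.zeros_like(w) for w in params.weights]
    vTh = [np.zeros_like(t) for t in params.thresholds]
    for epoch in range(1, cfg.epochs + 1):
        dW, dTh, _ = _backprop(params, X, T, scale)
        for k in range(len(vW)):
            vW[k] = cfg.momentum * vW[k] - lr * dW[k]
            vTh[k] = cfg.momentum * vTh[k] - lr * dTh[k]
        cand = params.copy()
        for k in range(len(vW)):
            cand.weights[k] += vW[k]
            cand.thresholds[k] += vTh[k]
        new_mse = batch_mse(cand, X, T)
        if not np.isfinite(new_mse):
            raise DivergenceError(f"training loss non-finite at epoch {epoch}")
        if new_mse > mse * cfg.max_perf_inc:
            lr *= cfg.lr_down  # reject the step, damp the rate, reset momentum
            for k in range(len(vW)):
                vW[k][:] = 0.0
                vTh[k][:] = 0.0
        else:
            params = cand
            if new_mse < mse:
                lr *= cfg.lr_up
            mse = new_mse
        history.append((mse, lr))
        if mse <= cfg.goal:
            break
    return params, history


def predict_class(params: NetworkParams, x) -> int:
    """Round the (single) output to the nearest class id, clipped to [1, 5]."""
    z = forward(params, x)
    return int(np.clip(np.floor(z[0] + 0.5), 1, N_CLASSES))


def predict_classes(params: NetworkParams, X) -> np.ndarray:
    Z = forward_batch(params, X)
    return np.clip(np.floor(Z[:, 0] + 0.5), 1, N_CLASSES).astype(np.int64)


def accuracy(predicted, actual) -> float:
    """Percent of predictions equal to the actual class ids."""
    p = np.asarray(predicted)
    a = np.asarray(actual)
    if p.shape != a.shape or p.size == 0:
        raise InvalidArgumentError("predicted and actual must be equal-length and non-empty")
    return 100.0 * float(np.mean(p == a))


# --- flat parameter vector <-> structured network --------------------------

def param_count(layer_sizes) -> int:
    return sum(b * a + b for a, b in zip(layer_sizes, tuple(layer_sizes)[1:]))


def pack(params: NetworkParams) -> np.ndarray:
    parts = [w.ravel() for w in params.weights] + [t.ravel() for t in params.thresholds]
    return np.concatenate(parts)


def unpack(layer_sizes, vector, transfers=None) -> NetworkParams:
    layer_sizes = tuple(int(s) for s in layer_sizes)
    vector = np.asarray(vector, dtype=float)
    if vector.size != param_count(layer_sizes):
        raise InvalidArgumentError(
            f"vector length {vector.size} != parameter count {param_count(layer_sizes)}")
    if transfers is None:
        transfers = default_transfers(len(layer_sizes))
    weights, thresholds = [], []
    pos = 0
    for a, b in zip(layer_sizes, layer_sizes[1:]):
        weights.append(vector[pos : pos + b * a].reshape(b, a).copy())
        pos += b * a
    for a, b in zip(layer_sizes, layer_sizes[1:]):
        thresholds.append(vector[pos : pos + b].copy())
        pos += b
    return NetworkParams(layer_sizes, weights, thresholds, tuple(transfers))


def to_json(params: NetworkParams) -> str:
    import json

    return json.dumps({
        "layer_sizes": list(params.layer_sizes),
        "transfers": list(params.transfers),
        "weights": [w.tolist() for w in params.weights],
        "thresholds": [t.tolist() for t in params.thresholds],
    })


def from_json(text: str) -> NetworkParams:
    import json

    d = json.loads(text)
    return NetworkParams(
        tuple(d["layer_sizes"]),
        [np.asarray(w, dtype=float) for w in d["weights"]],
        [np.asarray(t, dtype=float) for t in d["thresholds"]],
        tuple(d["transfers"]),
    )
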