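"""A classical 3-layer feed-forward network trained by plain SGD.

Architecture I-H-2 (default 29-14-2): a sigmoid (or tanh) hidden layer
and a two-unit normalized-exponential output layer, so the two class
scores (o1, o2) always satisfy o1 + o2 = 1 — o1 is the positive
(minority) score. The loss is the sum of squared errors against the
one-hot label, which is also the early-stopping criterion upstream.
Gradients are exact (hand-derived backpropagation); there is no
momentum, weight decay, or autodiff dependency.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = [
    "NetworkConfig",
    "NetworkWeights",
    "Gradients",
    "ForwardResult",
    "init_weights",
    "forward",
    "forward_batch",
    "loss_sse",
    "backprop",
    "backprop_batch",
    "sgd_step",
    "labels_to_onehot",
]


def _sigmoid(z: np.ndarray) -> np.ndarray:
    # numerically safe logistic
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _sigmoid_deriv(a: np.ndarray) -> np.ndarray:
    return a * (1.0 - a)


def _tanh_deriv(a: np.ndarray) -> np.ndarray:
    return 1.0 - a * a


_ACTIVATIONS: dict[str, tuple[Callable, Callable]] = {
    "sigmoid": (_sigmoid, _sigmoid_deriv),
    "tanh": (np.tanh, _tanh_deriv),
}


@dataclass(frozen=True)
class NetworkConfig:
    """Shape and initialization of the I-H-2 network."""

    n_inputs: int = 29
    n_hidden: int = 14
    n_outputs: int = 2
    hidden_activation: str = "sigmoid"
    init_scale: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_inputs < 1 or self.n_hidden < 1:
            raise ValueError("n_inputs and n_hidden must be >= 1")
        if self.n_outputs != 2:
            raise ValueError("the output layer is fixed at 2 units")
        if self.hidden_activation not in _ACTIVATIONS:
            raise ValueError(
                f"unknown activation {self.hidden_activation!r}; "
                f"choose from {sorted(_ACTIVATIONS)}"
            )


@dataclass
class NetworkWeights:
    """All parameters: input->hidden (w1, b1) and hidden->output (w2, b2)."""

    w1: np.ndarray  # (n_inputs, n_hidden)
    b1: np.ndarray  # (n_hidden,)
    w2: np.ndarray  # (n_hidden, 2)
    b2: np.ndarray  # (2,)
    config: NetworkConfig = field(default_factory=NetworkConfig)

    def copy(self) -> "NetworkWeights":
        return NetworkWeights(
            self.w1.copy(), self.b1.copy(), self.w2.copy(), self.b2.copy(), self.config
        )

    def is_finite(self) -> bool:
        return all(
            np.all(np.isfinite(a)) for a in (self.w1, self.b1, self.w2, self.b2)
        )

    # -- portable JSON round trip ----------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "config": vars(self.config),
                "w1": self.w1.tolist(),
                "b1": self.b1.tolist(),
                "w2": self.w2.tolist(),
                "b2": self.b2.tolist(),
            }
        )

    @classmethod
    def from_json(cls, s: str) -> "NetworkWeights":
        d = json.loads(s)
        cfg = NetworkConfig(**d["config"])
        return cls(
            np.asarray(d["w1"], dtype=float),
            np.asarray(d["b1"], dtype=float),
            np.asarray(d["w2"], dtype=float),
            np.asarray(d["b2"], dtype=float),
            cfg,
        )


# Gradients share the weight structure exactly.
Gradients = NetworkWeights


@dataclass
class ForwardResult:
    o1: float
    o2: float
    hidden_activations: np.ndarray


def init_weights(config: NetworkConfig) -> NetworkWeights:
    """Draw all weights and biases uniformly on [-init_scale, init_scale]."""
    rng = np.random.default_rng(config.seed)
    s = config.init_scale
    return NetworkWeights(
        w1=rng.uniform(-s, s, size=(config.n_inputs, config.n_hidden)),
        b1=rng.uniform(-s, s, size=config.n_hidden),
        w2=rng.uniform(-s, s, size=(config.n_hidden, 2)),
        b2=rng.uniform(-s, s, size=2),
        config=config,
    )


def forward_batch(weights: NetworkWeights, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized forward pass.

    Returns ``(O, H)`` where ``O`` is (n, 2) normalized class scores with
    rows summing to 1 and ``H`` is (n, n_hidden) hidden activations.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != weights.config.n_inputs:
        raise ValueError(
            f"input has {X.shape[1]} features, network expects "
            f"{weights.config.n_inputs}"
        )
    act, _ = _ACTIVATIONS[weights.config.hidden_activation]
    H = act(X @ weights.w1 + weights.b1)
    Z = H @ weights.w2 + weights.b2
    # normalized exponential, shift-invariant for stability
    Z = Z - Z.max(axis=1, keepdims=True)
    E = np.exp(Z)
    O = E / E.sum(axis=1, keepdims=True)
    return O, H


def forward(weights: NetworkWeights, x: np.ndarray) -> ForwardResult:
    """Forward pass for a single feature vector."""
    O, H = forward_batch(weights, np.asarray(x, dtype=float).reshape(1, -1))
    return ForwardResult(o1=float(O[0, 0]), o2=float(O[0, 1]), hidden_activations=H[0])


def labels_to_onehot(y: np.ndarray) -> np.ndarray:
    """Map 0/1 labels to (y1, y2) targets; positive -> (1, 0)."""
    y = np.asarray(y, dtype=int)
    Y = np.zeros((y.shape[0], 2))
    Y[y == 1, 0] = 1.0
    Y[y == 0, 1] = 1.0
    return Y


def loss_sse(O: np.ndarray, Y: np.ndarray) -> float:
    """Sum of squared errors sum_i (o1-y1)^2 + (o2-y2)^2."""
    O = np.atleast_2d(O)
    Y = np.atleast_2d(Y)
    if O.shape != Y.shape:
        raise ValueError(f"shape mismatch {O.shape} vs {Y.shape}")
    if O.shape[0] == 0:
        raise ValueError("empty prediction list")
    return float(np.sum((O - Y) ** 2))


def backprop_batch(weights: NetworkWeights, X: np.ndarray, Y: np.ndarray) -> Gradients:
    """Exact gradient of the summed SSE loss over a batch.

    The gradient of a batch is the sum of per-sample gradients; the
    output-layer delta accounts for the normalization coupling between
    the two output units.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    O, H = forward_batch(weights, X)
    dL_dO = 2.0 * (O - Y)  # (n, 2)
    # Jacobian of the normalized exponential: dO_j/dZ_k = O_j (δ_jk − O_k)
    s = np.sum(dL_dO * O, axis=1, keepdims=True)
    dZ = O * (dL_dO - s)  # (n, 2)
    gw2 = H.T @ dZ
    gb2 = dZ.sum(axis=0)
    _, deriv = _ACTIVATIONS[weights.config.hidden_activation]
    dH = (dZ @ weights.w2.T) * deriv(H)
    gw1 = X.T @ dH
    gb1 = dH.sum(axis=0)
    return Gradients(gw1, gb1, gw2, gb2, weights.config)


def backprop(weights: NetworkWeights, x: np.ndarray, label: int) -> Gradients:
    """Per-sample gradient of the SSE loss."""
    Y = labels_to_onehot(np.asarray([label]))
    return backprop_batch(weights, np.asarray(x, dtype=float).reshape(1, -1), Y)


def sgd_step(weights: NetworkWeights, grad: Gradients, lr: float) -> NetworkWeights:
    """One plain gradient-descent update w <- w - lr * g (returns new weights)."""
    if lr < 0:
        raise ValueError("learning rate must be non-negative")
    return NetworkWeights(
        weights.w1 - lr * grad.w1,
        weights.b1 - lr * grad.b1,
        weights.w2 - lr * grad.w2,
        weights.b2 - lr * grad.b2,
        weights.config,
    )


def sgd_step_(weights: NetworkWeights, grad: Gradients, lr: float) -> None:
    """In-place SGD update used by the training loop."""
    weights.w1 -= lr * grad.w1
    weights.b1 -= lr * grad.b1
    weights.w2 -= lr * grad.w2
    weights.b2 -= lr * grad.b2
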