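"""Minimal feed-forward network machinery shared by the model components.

Implements exactly what the pair classifiers need: Glorot-normal
initialization, ReLU hidden layers with inverted dropout, a sigmoid output
unit, binary cross-entropy, analytic backpropagation (including the gradient
with respect to the input, needed when an embedding layer is trained jointly
upstream of the network), and Adam.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit as sigmoid

__all__ = ["sigmoid", "glorot_normal", "bce_loss", "MLP", "Adam"]

BCE_EPS = 1e-7


def glorot_normal(rng: np.random.Generator, fan_in: int, fan_out: int, shape=None):
    """Glorot (Xavier) normal draw: sd = sqrt(2 / (fan_in + fan_out))."""
    if shape is None:
        shape = (fan_out, fan_in)
    sd = np.sqrt(2.0 / (fan_in + fan_out))
    return rng.normal(0.0, sd, size=shape)


def bce_loss(predictions: np.ndarray, labels: np.ndarray) -> float:
    """Mean binary cross-entropy, -[y log p + (1-y) log(1-p)].

    Predictions are clipped to [eps, 1-eps] with eps = 1e-7 for numerical
    safety at saturated outputs.
    """
    p = np.asarray(predictions, dtype=np.float64).ravel()
    y = np.asarray(labels, dtype=np.float64).ravel()
    if p.shape != y.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {y.shape}")
    p = np.clip(p, BCE_EPS, 1.0 - BCE_EPS)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


class MLP:
    """ReLU multilayer perceptron with a single sigmoid output unit.

    ``widths`` lists the input width followed by the hidden-layer widths; the
    output layer of width 1 is implicit. Weights are Glorot-normal, biases
    zero. Dropout (inverted scaling) is applied to hidden activations and is
    active only when ``training=True`` is passed to :meth:`forward`, so
    inference is deterministic.
    """

    def __init__(self, widths, rng: np.random.Generator, dropout: float = 0.0):
        widths = list(widths)
        if len(widths) < 1 or any(w <= 0 for w in widths):
            raise ValueError(f"invalid layer widths {widths}")
        if not 0.0 <= dropout <= 0.9:
            raise ValueError(f"dropout must be in [0, 0.9], got {dropout}")
        sizes = widths + [1]
        self.dropout = float(dropout)
        self.weights = [
            glorot_normal(rng, sizes[l], sizes[l + 1])
            for l in range(len(sizes) - 1)
        ]
        self.biases = [np.zeros(sizes[l + 1]) for l in range(len(sizes) - 1)]

    @property
    def n_layers(self) -> int:
        return len(self.weights)

    @property
    def input_dim(self) -> int:
        return self.weights[0].shape[1]

    def params(self) -> list[np.ndarray]:
        out: list[np.ndarray] = []
        for W, b in zip(self.weights, self.biases):
            out.extend((W, b))
        return out

    def forward(
        self,
        X: np.ndarray,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ):
        """Forward pass. Returns (probabilities, cache-for-backward)."""
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if X.shape[1] != self.input_dim:
            raise ValueError(
                f"feature width {X.shape[1]} != network input {self.input_dim}"
            )
        a = X
        activations = [a]
        masks: list[np.ndarray | None] = []
        for l in range(self.n_layers - 1):
            z = a @ self.weights[l].T + self.biases[l]
            a = np.maximum(z, 0.0)
            if training and self.dropout > 0.0:
                if rng is None:
                    raise ValueError("training-mode dropout requires an rng")
                mask = (rng.random(a.shape) >= self.dropout) / (1.0 - self.dropout)
                a = a * mask
                masks.append(mask)
            else:
                masks.append(None)
            activations.append(a)
        z_out = a @ self.weights[-1].T + self.biases[-1]
        p = sigmoid(z_out).ravel()
        return p, (activations, masks)

    def backward(self, cache, delta_out: np.ndarray):
        """Backprop from dL/dz of the output unit.

        For BCE on a sigmoid output, ``delta_out`` is (p - y) / m. Returns
        (parameter gradients aligned with :meth:`params`, gradient w.r.t. X).
        """
        activations, masks = cache
        delta = np.atleast_2d(np.asarray(delta_out, dtype=np.float64))
        if delta.shape[0] == 1 and delta.shape[1] > 1:
            delta = delta.T
        grads_W: list[np.ndarray] = [None] * self.n_layers
        grads_b: list[np.ndarray] = [None] * self.n_layers
        grads_W[-1] = delta.T @ activations[-1]
        grads_b[-1] = delta.sum(axis=0)
        upstream = delta @ self.weights[-1]
        for l in range(self.n_layers - 2, -1, -1):
            if masks[l] is not None:
                upstream = upstream * masks[l]
            upstream = upstream * (activations[l + 1] > 0.0)
            grads_W[l] = upstream.T @ activations[l]
            grads_b[l] = upstream.sum(axis=0)
            upstream = upstream @ self.weights[l]
        grads: list[np.ndarray] = []
        for gW, gb in zip(grads_W, grads_b):
            grads.extend((gW, gb))
        return grads, upstream  # upstream is now dL/dX


class Adam:
    """Adaptive moment estimation over a fixed list of parameter arrays."""

    def __init__(self, params, lr: float = 0.001, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        if lr <= 0:
            raise ValueError(f"learning rate must be positive, got {lr}")
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]

    def step(self, params, grads) -> None:
        """Update ``params`` in place from aligned ``grads``."""
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
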