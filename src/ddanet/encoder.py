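"""Autoencoder compression of attribute matrices.

A single-hidden-layer symmetric autoencoder maps an attribute matrix (binary
drug substructure matrix R_a or real disease similarity matrix D_a) to a
compact hidden representation h = sigma(x W1 + b1), trained to reconstruct
its input under mean-squared error with plain full-batch gradient descent.
Drugs and diseases are compressed by two separately trained encoders with
identical machinery.

All hyperparameters (hidden width, epochs, learning rate, activation) are
explicit and seeded, so training is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigError

_ACTIVATIONS = {
    "sigmoid": (lambda z: 1.0 / (1.0 + np.exp(-z)), lambda a: a * (1.0 - a)),
    "tanh": (np.tanh, lambda a: 1.0 - a * a),
    "relu": (lambda z: np.maximum(z, 0.0), lambda a: (a > 0).astype(float)),
}


@dataclass
class AutoencoderParams:
    """Learned encoder/decoder weights plus the training configuration."""

    W1: np.ndarray  # (input_dim, hidden_dim)
    b1: np.ndarray  # (hidden_dim,)
    W2: np.ndarray  # (hidden_dim, input_dim)
    b2: np.ndarray  # (input_dim,)
    activation: str
    input_dim: int
    hidden_dim: int
    epochs: int
    learning_rate: float
    seed: int
    loss_history: list[float] = field(default_factory=list)


def train_autoencoder(
    matrix: np.ndarray,
    hidden_dim: int = 64,
    epochs: int = 100,
    learning_rate: float = 0.01,
    activation: str = "sigmoid",
    seed: int = 0,
) -> AutoencoderParams:
    """Fit the autoencoder on ``matrix`` (rows = items, columns = attributes).

    Returns the learned parameters with the per-epoch reconstruction MSE in
    ``loss_history``. ``hidden_dim`` must be strictly smaller than the input
    width; the input must be finite with no missing values.
    """
    X = np.asarray(matrix, dtype=float)
    if X.size == 0:
        raise ConfigError("empty attribute matrix")
    if not np.isfinite(X).all():
        raise ConfigError("attribute matrix contains non-finite values")
    n, d = X.shape
    if hidden_dim >= d:
        raise ConfigError(f"hidden_dim ({hidden_dim}) must be < input dim ({d})")
    if activation not in _ACTIVATIONS:
        raise ConfigError(f"unknown activation {activation!r}")
    act, dact = _ACTIVATIONS[activation]

    rng = np.random.default_rng(seed)
    W1 = rng.normal(0.0, 1.0 / np.sqrt(d), size=(d, hidden_dim))
    b1 = np.zeros(hidden_dim)
    W2 = rng.normal(0.0, 1.0 / np.sqrt(hidden_dim), size=(hidden_dim, d))
    b2 = np.zeros(d)

    losses = []
    for _ in range(epochs):
        H = act(X @ W1 + b1)
        Y = act(H @ W2 + b2)
        err = Y - X
        losses.append(float(np.mean(err**2)))
        # backprop; loss gradient averaged over samples (not entries), so
        # update magnitudes do not vanish with wide inputs
        dY = 2.0 * err / n * dact(Y)
        gW2 = H.T @ dY
        gb2 = dY.sum(axis=0)
        dH = dY @ W2.T * dact(H)
        gW1 = X.T @ dH
        gb1 = dH.sum(axis=0)
        W1 -= learning_rate * gW1
        b1 -= learning_rate * gb1
        W2 -= learning_rate * gW2
        b2 -= learning_rate * gb2

    return AutoencoderParams(
        W1, b1, W2, b2, activation, d, hidden_dim, epochs, learning_rate, seed, losses
    )


def encode(matrix: np.ndarray, params: AutoencoderParams) -> np.ndarray:
    """Hidden-layer representation sigma(x W1 + b1) for every row of ``matrix``.

    Pure function of its arguments: deterministic, row count preserved.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[1] != params.input_dim:
        raise ConfigError(
            f"matrix has {X.shape[1] if X.ndim == 2 else '?'} columns, "
            f"encoder expects {params.input_dim}"
        )
    act, _ = _ACTIVATIONS[params.activation]
    return act(X @ params.W1 + params.b1)
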