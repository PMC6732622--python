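"""Single-hidden-layer autoencoder for binary drug fingerprints.

Maps an n-bit fingerprint x to a low-dimensional code Y = sigmoid(W1 x + b1)
and back to a reconstruction x' = sigmoid(W2 Y + b2), trained by full-batch
gradient descent on the mean squared reconstruction error
(1/n) sum_i ||x'_i - x_i||^2. The code matrix FG (one row per drug) serves
as the learned structural feature of each drug.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .config import RunConfig
from .io import FingerprintMatrix

__all__ = [
    "AutoencoderParams",
    "EncodedFeatures",
    "sigmoid",
    "encode",
    "decode",
    "reconstruction_loss",
    "loss_gradients",
    "train_autoencoder",
    "encode_all",
]


def sigmoid(x):
    """Numerically stable logistic function 1 / (1 + exp(-x))."""
    return expit(np.asarray(x, dtype=float))


@dataclass
class AutoencoderParams:
    """Weights/biases of encoder (W1, b1) and decoder (W2, b2) plus the loss curve."""

    W1: np.ndarray  # hidden_dim x n_bits
    b1: np.ndarray  # hidden_dim
    W2: np.ndarray  # n_bits x hidden_dim
    b2: np.ndarray  # n_bits
    training_curve: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        h, d = self.W1.shape
        if self.b1.shape != (h,) or self.W2.shape != (d, h) or self.b2.shape != (d,):
            raise ValueError("inconsistent autoencoder parameter shapes")

    @property
    def hidden_dim(self) -> int:
        return self.W1.shape[0]

    @property
    def n_bits(self) -> int:
        return self.W1.shape[1]


@dataclass
class EncodedFeatures:
    """Per-drug learned structural features FG, rows in association drug order."""

    drug_ids: list[str]
    FG: np.ndarray  # n_drugs x hidden_dim, sigmoid range


def encode(x: np.ndarray, params: AutoencoderParams) -> np.ndarray:
    """Hidden code Y = sigmoid(W1 x + b1); accepts a vector or a batch of rows."""
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != params.n_bits:
        raise ValueError(f"input has {x.shape[-1]} bits, params expect {params.n_bits}")
    return sigmoid(x @ params.W1.T + params.b1)


def decode(y: np.ndarray, params: AutoencoderParams) -> np.ndarray:
    """Reconstruction x' = sigmoid(W2 Y + b2)."""
    y = np.asarray(y, dtype=float)
    if y.shape[-1] != params.hidden_dim:
        raise ValueError(f"code has length {y.shape[-1]}, params expect {params.hidden_dim}")
    return sigmoid(y @ params.W2.T + params.b2)


def reconstruction_loss(X: np.ndarray, params: AutoencoderParams) -> float:
    """Mean squared reconstruction error over the batch."""
    Xhat = decode(encode(X, params), params)
    return float(((Xhat - X) ** 2).sum() / X.shape[0])


def loss_gradients(X: np.ndarray, params: AutoencoderParams):
    """Analytic gradients of the MSE loss w.r.t. (W1, b1, W2, b2).

    Returns ``(loss, gW1, gb1, gW2, gb2)``; backpropagation through the two
    sigmoid layers, derived by hand and checked against finite differences
    in the test suite.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    H = encode(X, params)            # n x h
    Xhat = decode(H, params)         # n x d
    diff = Xhat - X
    loss = float((diff**2).sum() / n)
    delta2 = (2.0 / n) * diff * Xhat * (1.0 - Xhat)      # n x d
    gW2 = delta2.T @ H                                    # d x h
    gb2 = delta2.sum(axis=0)
    delta1 = (delta2 @ params.W2) * H * (1.0 - H)         # n x h
    gW1 = delta1.T @ X                                    # h x d
    gb1 = delta1.sum(axis=0)
    return loss, gW1, gb1, gW2, gb2


def init_params(n_bits: int, hidden_dim: int, rng: np.random.Generator) -> AutoencoderParams:
    """Glorot-uniform initialisation, biases zero."""
    r = np.sqrt(6.0 / (n_bits + hidden_dim))
    return AutoencoderParams(
        W1=rng.uniform(-r, r, size=(hidden_dim, n_bits)),
        b1=np.zeros(hidden_dim),
        W2=rng.uniform(-r, r, size=(n_bits, hidden_dim)),
        b2=np.zeros(n_bits),
    )


def train_autoencoder(F: FingerprintMatrix, cfg: RunConfig | None = None) -> AutoencoderParams:
    """Full-batch gradient descent on the reconstruction MSE.

    Deterministic under ``cfg.rng_seed``; raises if the fingerprints are not
    binary or the loss diverges (suggesting a smaller learning rate).
    """
    cfg = cfg or RunConfig()
    X = np.asarray(F.F, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least two drugs to train the autoencoder")
    if not np.isin(X, (0.0, 1.0)).all():
        raise ValueError("fingerprints must be binary")
    rng = cfg.stage_rng("autoencoder")
    params = init_params(X.shape[1], cfg.ae_hidden_dim, rng)
    lr = cfg.ae_learning_rate
    for _ in range(cfg.ae_epochs):
        loss, gW1, gb1, gW2, gb2 = loss_gradients(X, params)
        if not np.isfinite(loss):
            raise FloatingPointError(
                "autoencoder loss diverged; try a smaller ae_learning_rate"
            )
        params.training_curve.append(loss)
        params.W1 -= lr * gW1
        params.b1 -= lr * gb1
        params.W2 -= lr * gW2
        params.b2 -= lr * gb2
    params.training_curve.append(reconstruction_loss(X, params))
    return params


def encode_all(F: FingerprintMatrix, params: AutoencoderParams) -> EncodedFeatures:
    """Encode every fingerprint row; FG row i = encode(F row i)."""
    return EncodedFeatures(list(F.drug_ids), encode(F.F, params))
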