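"""Single-hidden-layer sparse autoencoder for attribute compression.

Variable-dimension raw attributes (disease similarity rows, drug fingerprint
bit vectors) are unified to a fixed code size (default 64) by an autoencoder
trained with three loss terms: mean half-squared reconstruction error, a KL
sparsity penalty pulling the mean activation of each hidden unit toward a
target rate rho, and an L2 weight-decay penalty.

The hidden layer is sigmoid so that mean activations are valid rates in
(0, 1) for the KL term; the output layer is ReLU.  Inputs are min-max scaled
to [0, 1] per feature before training (a no-op for similarity rows and bit
vectors, which already live there).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

logger = logging.getLogger(__name__)

_EPS = 1e-8


@dataclass
class SAEConfig:
    input_dim: int
    hidden_dim: int = 64
    rho: float = 0.05          # sparsity target: desired mean hidden activation
    alpha: float = 1.0         # weight of the KL sparsity term
    beta: float = 1e-4         # weight of the L2 weight decay term
    epochs: int = 100
    batch_size: int = 32
    learning_rate: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.hidden_dim < 1:
            raise ValueError("hidden_dim must be >= 1")
        if not (0.0 < self.rho < 1.0):
            raise ValueError("rho must lie in (0, 1)")
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be >= 0")


@dataclass
class SAEModel:
    W1: np.ndarray  # (input_dim, hidden_dim)
    b1: np.ndarray
    W2: np.ndarray  # (hidden_dim, input_dim)
    b2: np.ndarray
    config: SAEConfig
    feature_min: np.ndarray
    feature_range: np.ndarray
    loss_trajectory: List[Tuple[float, float, float, float]] = field(
        default_factory=list
    )

    def scale(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.feature_min) / self.feature_range

    def save(self, path) -> None:
        np.savez(
            path,
            W1=self.W1, b1=self.b1, W2=self.W2, b2=self.b2,
            feature_min=self.feature_min, feature_range=self.feature_range,
            config=np.array(
                [self.config.input_dim, self.config.hidden_dim, self.config.rho,
                 self.config.alpha, self.config.beta, self.config.epochs,
                 self.config.batch_size, self.config.learning_rate,
                 self.config.seed]
            ),
        )

    @classmethod
    def load(cls, path) -> "SAEModel":
        data = np.load(path)
        c = data["config"]
        cfg = SAEConfig(
            input_dim=int(c[0]), hidden_dim=int(c[1]), rho=float(c[2]),
            alpha=float(c[3]), beta=float(c[4]), epochs=int(c[5]),
            batch_size=int(c[6]), learning_rate=float(c[7]), seed=int(c[8]),
        )
        return cls(
            W1=data["W1"], b1=data["b1"], W2=data["W2"], b2=data["b2"],
            config=cfg, feature_min=data["feature_min"],
            feature_range=data["feature_range"],
        )


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def kl_sparsity(rho: float, rho_hat: float) -> float:
    """Bernoulli KL divergence KL(rho || rho_hat); >= 0, zero iff equal.

    Both arguments are clamped to [1e-8, 1 - 1e-8] at the boundary.
    """
    rho = float(np.clip(rho, _EPS, 1.0 - _EPS))
    rho_hat = float(np.clip(rho_hat, _EPS, 1.0 - _EPS))
    return rho * np.log(rho / rho_hat) + (1.0 - rho) * np.log(
        (1.0 - rho) / (1.0 - rho_hat)
    )


def _forward(model: SAEModel, Xs: np.ndarray):
    h_pre = Xs @ model.W1 + model.b1
    h = _sigmoid(h_pre)
    o_pre = h @ model.W2 + model.b2
    xhat = np.maximum(o_pre, 0.0)
    return h_pre, h, o_pre, xhat


def sae_loss(
    model: SAEModel, X: np.ndarray, config: Optional[SAEConfig] = None
) -> Tuple[float, float, float, float]:
    """Total, reconstruction, sparsity and weight-decay loss terms on a batch.

    reconstruction = (1/m) sum_i 0.5 ||x_i - xhat_i||^2 on the scaled inputs;
    sparsity = alpha * sum_j KL(rho || rho_hat_j) with rho_hat_j the mean
    activation of hidden unit j over the batch; decay = beta * (||W1||^2 +
    ||W2||^2).
    """
    config = config or model.config
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.size == 0 or not np.all(np.isfinite(X)):
        raise ValueError("X must be nonempty and finite")
    Xs = model.scale(X)
    _, h, _, xhat = _forward(model, Xs)
    m = Xs.shape[0]
    recon = float(0.5 * np.sum((Xs - xhat) ** 2) / m)
    rho_hat = h.mean(axis=0)
    if np.any(rho_hat <= 0.0) or np.any(rho_hat >= 1.0):
        logger.warning("mean hidden activation hit (0,1) boundary; clamping")
    sparsity = float(
        config.alpha * sum(kl_sparsity(config.rho, r) for r in rho_hat)
    )
    decay = float(config.beta * (np.sum(model.W1 ** 2) + np.sum(model.W2 ** 2)))
    total = recon + sparsity + decay
    return total, recon, sparsity, decay


def sae_gradients(
    model: SAEModel, X: np.ndarray, config: Optional[SAEConfig] = None
) -> Dict[str, np.ndarray]:
    """Analytic gradients of the total loss w.r.t. W1, b1, W2, b2."""
    config = config or model.config
    Xs = model.scale(np.atleast_2d(np.asarray(X, dtype=float)))
    m = Xs.shape[0]
    _, h, o_pre, xhat = _forward(model, Xs)

    d_opre = ((xhat - Xs) / m) * (o_pre > 0)
    gW2 = h.T @ d_opre + 2.0 * config.beta * model.W2
    gb2 = d_opre.sum(axis=0)

    d_h = d_opre @ model.W2.T
    rho_hat = np.clip(h.mean(axis=0), _EPS, 1.0 - _EPS)
    d_rho = config.alpha * (
        -config.rho / rho_hat + (1.0 - config.rho) / (1.0 - rho_hat)
    )
    d_h = d_h + d_rho / m  # broadcast over rows
    d_hpre = d_h * h * (1.0 - h)
    gW1 = Xs.T @ d_hpre + 2.0 * config.beta * model.W1
    gb1 = d_hpre.sum(axis=0)
    return {"W1": gW1, "b1": gb1, "W2": gW2, "b2": gb2}


def _init_model(X: np.ndarray, config: SAEConfig) -> SAEModel:
    rng = np.random.default_rng(config.seed)
    feature_min = X.min(axis=0)
    feature_range = X.max(axis=0) - feature_min
    feature_range[feature_range == 0.0] = 1.0
    W1 = rng.uniform(-0.05, 0.05, size=(config.input_dim, config.hidden_dim))
    W2 = rng.uniform(-0.05, 0.05, size=(config.hidden_dim, config.input_dim))
    # output thresholds start at the scaled-target midpoint so no ReLU output
    # unit is born (or easily driven) dead
    return SAEModel(
        W1=W1, b1=np.zeros(config.hidden_dim),
        W2=W2, b2=np.full(config.input_dim, 0.5),
        config=config, feature_min=feature_min, feature_range=feature_range,
    )


def train_sae(X: np.ndarray, config: SAEConfig) -> SAEModel:
    """Mini-batch gradient descent on the three-term loss; seeded, logged.

    The full-data loss tuple is recorded before training and after every
    epoch in ``model.loss_trajectory``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != config.input_dim:
        raise ValueError(
            f"rows of X have length {X.shape[1]}, expected {config.input_dim}"
        )
    if not np.all(np.isfinite(X)):
        raise ValueError("X must be finite")
    model = _init_model(X, config)
    rng = np.random.default_rng(config.seed + 1)
    m = X.shape[0]
    model.loss_trajectory.append(sae_loss(model, X, config))
    for epoch in range(config.epochs):
        order = rng.permutation(m)
        for start in range(0, m, config.batch_size):
            batch = X[order[start : start + config.batch_size]]
            grads = sae_gradients(model, batch, config)
            model.W1 -= config.learning_rate * grads["W1"]
            model.b1 -= config.learning_rate * grads["b1"]
            model.W2 -= config.learning_rate * grads["W2"]
            model.b2 -= config.learning_rate * grads["b2"]
        losses = sae_loss(model, X, config)
        if not np.isfinite(losses[0]):
            raise RuntimeError(
                f"non-finite loss at epoch {epoch}: {losses}"
            )
        model.loss_trajectory.append(losses)
    return model


def encode(model: SAEModel, X: np.ndarray) -> np.ndarray:
    """Hidden-layer codes for rows of X (pure function of the trained model)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.config.input_dim:
        raise ValueError(
            f"input dim {X.shape[1]} != model input_dim {model.config.input_dim}"
        )
    Xs = model.scale(X)
    return _sigmoid(Xs @ model.W1 + model.b1)


def write_loss_log(model: SAEModel, path) -> None:
    """Loss trajectory as CSV: epoch, total, reconstruction, sparsity, decay."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("epoch,total,reconstruction,sparsity,decay\n")
        for i, (tot, rec, spa, dec) in enumerate(model.loss_trajectory):
            fh.write(f"{i},{tot},{rec},{spa},{dec}\n")
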