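"""Gaussian-visible / Bernoulli-hidden restricted Boltzmann machine.

The model is the bipartite energy-based network

    E(v, h) = Σ_i (v_i − a_i)² / (2σ_i²) − Σ_ij (v_i / σ_i²) h_j w_ij − b·h

with real-valued visible units v and binary hidden units h, and no
intra-layer connections.  Conditionals factorize:

    p(h_j = 1 | v) = logistic(Σ_i v_i w_ij / σ_i² + b_j)
    p(v_i | h)     = N(Σ_j h_j w_ij + a_i, σ_i²)

Training is contrastive divergence (CD-k): the positive phase uses the
data with sampled hidden states; the negative phase runs k alternating
Gibbs steps using hidden samples and visible conditional means (visible
noise is never injected into the chain, a standard variance-reduction
choice).  Visible SDs σ_i are fixed at 1 by default, appropriate for
inputs min-max scaled to [0, 1].

Downstream feature vectors are the hidden activation probabilities
p(h_j=1|v), which are deterministic given the trained model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit

__all__ = [
    "TrainConfig",
    "RBMModel",
    "TrainingDivergedError",
    "init_model",
    "hidden_probs",
    "visible_mean",
    "sample_visible",
    "energy",
    "cd_train",
    "save_model",
    "load_model",
]

_P_LO = np.nextafter(0.0, 1.0)
_P_HI = np.nextafter(1.0, 0.0)


class TrainingDivergedError(RuntimeError):
    def __init__(self, epoch: int):
        super().__init__(f"non-finite parameter encountered at epoch {epoch}")
        self.epoch = epoch


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.01
    epochs: int = 100
    batch_size: int = 32
    cd_steps: int = 1
    weight_init_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.cd_steps < 1:
            raise ValueError("cd_steps must be >= 1")
        if self.weight_init_sd < 0:
            raise ValueError("weight_init_sd must be >= 0")


@dataclass
class RBMModel:
    W: np.ndarray                       # (d, h), visible i -> hidden j
    a: np.ndarray                       # visible bias, (d,)
    b: np.ndarray                       # hidden bias, (h,)
    sigma: np.ndarray                   # visible SDs, (d,), strictly positive
    trained_epochs: int = 0

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.W.ndim != 2:
            raise ValueError("W must be 2-D")
        d, h = self.W.shape
        if self.a.shape != (d,) or self.b.shape != (h,) or self.sigma.shape != (d,):
            raise ValueError("bias/sigma shapes inconsistent with W")
        if not (np.isfinite(self.W).all() and np.isfinite(self.a).all()
                and np.isfinite(self.b).all()):
            raise ValueError("model parameters must be finite")
        if (self.sigma <= 0).any():
            raise ValueError("sigma must be strictly positive")

    @property
    def d(self) -> int:
        return self.W.shape[0]

    @property
    def h(self) -> int:
        return self.W.shape[1]

    def copy(self) -> "RBMModel":
        return RBMModel(self.W.copy(), self.a.copy(), self.b.copy(),
                        self.sigma.copy(), self.trained_epochs)


def init_model(d: int, h: int, cfg: TrainConfig) -> RBMModel:
    """Gaussian-initialized weights, zero biases, unit visible SDs."""
    if d < 1 or h < 1:
        raise ValueError("layer sizes must be >= 1")
    rng = np.random.default_rng(cfg.seed)
    W = rng.normal(0.0, cfg.weight_init_sd, size=(d, h)) if cfg.weight_init_sd > 0 \
        else np.zeros((d, h))
    return RBMModel(W=W, a=np.zeros(d), b=np.zeros(h), sigma=np.ones(d))


def _check_visible(model: RBMModel, V: np.ndarray) -> np.ndarray:
    V = np.atleast_2d(np.asarray(V, dtype=float))
    if V.shape[1] != model.d:
        raise ValueError(f"expected {model.d} visible columns, got {V.shape[1]}")
    return V


def hidden_probs(model: RBMModel, V: np.ndarray) -> np.ndarray:
    """p(h_j = 1 | v) per row; entries clipped strictly inside (0, 1)."""
    V = _check_visible(model, V)
    act = (V / model.sigma**2) @ model.W + model.b
    return np.clip(expit(act), _P_LO, _P_HI)


def visible_mean(model: RBMModel, H: np.ndarray) -> np.ndarray:
    """Gaussian conditional means Σ_j h_j w_ij + a_i per row."""
    H = np.atleast_2d(np.asarray(H, dtype=float))
    if H.shape[1] != model.h:
        raise ValueError(f"expected {model.h} hidden columns, got {H.shape[1]}")
    return H @ model.W.T + model.a


def sample_visible(model: RBMModel, H: np.ndarray,
                   rng: np.random.Generator) -> np.ndarray:
    """Sampling companion of :func:`visible_mean` (adds N(0, σ_i²) noise)."""
    mean = visible_mean(model, H)
    return mean + rng.normal(0.0, model.sigma, size=mean.shape)


def energy(model: RBMModel, v: np.ndarray, h: np.ndarray) -> float:
    v = np.asarray(v, dtype=float)
    h = np.asarray(h, dtype=float)
    quad = np.sum((v - model.a) ** 2 / (2 * model.sigma**2))
    inter = (v / model.sigma**2) @ model.W @ h
    return float(quad - inter - model.b @ h)


def cd_train(model: RBMModel, X: np.ndarray,
             cfg: TrainConfig) -> tuple[RBMModel, list[float]]:
    """CD-k training; returns the updated model and per-epoch mean squared
    reconstruction error (mean-field reconstruction, computed after each
    epoch on the full data).

    On a fresh model the visible biases are initialized to the training
    column means before the first update.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 0:
        raise ValueError("empty training matrix")
    if X.shape[1] != model.d:
        raise ValueError(f"expected {model.d} columns, got {X.shape[1]}")

    model = model.copy()
    if cfg.epochs == 0:
        return model, []
    if model.trained_epochs == 0:
        model.a = X.mean(axis=0)

    rng = np.random.default_rng(cfg.seed)
    n = X.shape[0]
    inv_var = 1.0 / model.sigma**2
    errors: list[float] = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            V = X[order[start:start + cfg.batch_size]]
            B = V.shape[0]
            ph_pos = hidden_probs(model, V)
            hs = (rng.random(ph_pos.shape) < ph_pos).astype(float)

            hs_neg = hs
            for step in range(cfg.cd_steps):
                Vm = visible_mean(model, hs_neg)
                ph_neg = hidden_probs(model, Vm)
                if step < cfg.cd_steps - 1:
                    hs_neg = (rng.random(ph_neg.shape) < ph_neg).astype(float)

            grad_W = ((V * inv_var).T @ hs - (Vm * inv_var).T @ ph_neg) / B
            grad_a = ((V - Vm) * inv_var).mean(axis=0)
            grad_b = (hs - ph_neg).mean(axis=0)
            model.W += cfg.learning_rate * grad_W
            model.a += cfg.learning_rate * grad_a
            model.b += cfg.learning_rate * grad_b
        if not (np.isfinite(model.W).all() and np.isfinite(model.a).all()
                and np.isfinite(model.b).all()):
            raise TrainingDivergedError(epoch)
        recon = visible_mean(model, hidden_probs(model, X))
        errors.append(float(np.mean((X - recon) ** 2)))
        model.trained_epochs += 1
    return model, errors


def save_model(model: RBMModel, path) -> None:
    """Portable JSON serialization; float repr round-trips bit-exactly."""
    payload = {
        "format": "rbmprune-rbm-v1",
        "d": model.d,
        "h": model.h,
        "trained_epochs": model.trained_epochs,
        "W": model.W.tolist(),
        "a": model.a.tolist(),
        "b": model.b.tolist(),
        "sigma": model.sigma.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path) -> RBMModel:
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format") != "rbmprune-rbm-v1":
        raise ValueError("unrecognized model file")
    model = RBMModel(W=np.array(payload["W"], dtype=float),
                     a=np.array(payload["a"], dtype=float),
                     b=np.array(payload["b"], dtype=float),
                     sigma=np.array(payload["sigma"], dtype=float),
                     trained_epochs=int(payload["trained_epochs"]))
    if model.W.shape != (payload["d"], payload["h"]):
        raise ValueError("shape metadata mismatch")
    return model
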