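"""Deep autoencoder for compressing smoothed mutation profiles.

A 500-100-500 fully connected autoencoder maps each patient's smoothed,
min-max-scaled profile to a 100-dimensional latent vector (the encoded
matrix, EM).  Hidden layers use ReLU, f(z) = max(0, z); the output layer is
sigmoid, f(z) = 1 / (1 + e^-z), which is why inputs must be scaled to [0, 1]
per gene first.  The reconstruction loss is

    L_rec = (1/n) * sum_i || x_i - x_hat_i ||^2        (n = patients),

minimized by minibatch Adam (lr 1e-4, batch 32, <= 150 epochs) on a seeded
90/10 train/validation split; the held-out loss monitors overfitting, and
early stopping with best-weights restoration is available as an opt-in.

The whole network — forward pass, backpropagation and the Adam update — is
implemented in numpy, which keeps training bit-deterministic under a seed and
free of framework dependencies.  Latent features carry no intrinsic order or
meaning; downstream code must not assume feature identifiability across
retrains.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import D3NSError, ValidationError
from .propagation import SmoothedMatrix

__all__ = [
    "EncoderConfig",
    "TrainedEncoder",
    "EncodedMatrix",
    "ScalingRecord",
    "relu",
    "sigmoid",
    "mse_loss",
    "scale_input",
    "train_autoencoder",
    "encode",
    "TrainingDivergedError",
]


class TrainingDivergedError(D3NSError, RuntimeError):
    """Loss became non-finite during training."""


def relu(z: np.ndarray) -> np.ndarray:
    """Rectified linear unit, f(z) = max(0, z)."""
    return np.maximum(0.0, z)


def sigmoid(z: np.ndarray) -> np.ndarray:
    """Logistic function, f(z) = 1 / (1 + e^-z)."""
    return 1.0 / (1.0 + np.exp(-z))


def mse_loss(x: np.ndarray, x_hat: np.ndarray) -> float:
    """Reconstruction loss: mean over patients of the squared residual norm."""
    x = np.asarray(x, dtype=float)
    x_hat = np.asarray(x_hat, dtype=float)
    return float(np.sum((x - x_hat) ** 2) / x.shape[0])


@dataclass
class EncoderConfig:
    hidden_sizes: tuple[int, int, int] = (500, 100, 500)
    latent_dim: int = 100
    hidden_activation: str = "relu"
    output_activation: str = "sigmoid"
    learning_rate: float = 1e-4
    batch_size: int = 32
    max_epochs: int = 150
    validation_fraction: float = 0.10
    # Early stopping is opt-in: the reconstruction loss on desk-scale cohorts
    # shows a long noisy validation plateau before the latent organizes, and a
    # short patience reliably stops inside it.  None = train to max_epochs.
    early_stopping_patience: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.latent_dim != self.hidden_sizes[1]:
            raise ValueError("latent_dim must equal the middle hidden size")
        if not 0 < self.validation_fraction < 1:
            raise ValueError("validation_fraction must be in (0, 1)")
        if any(s < 1 for s in self.hidden_sizes):
            raise ValueError("all hidden sizes must be >= 1")


@dataclass
class ScalingRecord:
    """Per-gene min/max used to map the smoothed matrix into [0, 1]."""

    genes: list[str]
    mins: np.ndarray
    ranges: np.ndarray  # 0 for constant genes (which map to 0)


@dataclass
class ScaledMatrix:
    patients: list[str]
    genes: list[str]
    values: np.ndarray
    scaling: ScalingRecord


@dataclass
class TrainedEncoder:
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    genes: list[str]
    config: EncoderConfig
    training_history: pd.DataFrame  # epoch, train_loss, val_loss
    input_scaling: ScalingRecord | None = None

    def forward(self, X: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        """Full forward pass; returns (reconstruction, per-layer activations)."""
        acts = [X]
        h = X
        last = len(self.weights) - 1
        for i, (Wi, bi) in enumerate(zip(self.weights, self.biases)):
            z = h @ Wi + bi
            h = sigmoid(z) if i == last else relu(z)
            acts.append(h)
        return h, acts

    def encode_values(self, X: np.ndarray) -> np.ndarray:
        """Forward through the encoder half only (input -> bottleneck)."""
        h = X
        n_encoder = (len(self.weights) + 1) // 2  # layers up to the bottleneck
        for Wi, bi in zip(self.weights[:n_encoder], self.biases[:n_encoder]):
            h = relu(h @ Wi + bi)
        return h


@dataclass
class EncodedMatrix:
    """Patients x latent-features matrix from the trained encoder bottleneck."""

    patients: list[str]
    features: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.patients), len(self.features)):
            raise ValidationError("encoded matrix shape does not match labels")
        if not np.isfinite(self.values).all():
            raise ValidationError("encoded matrix contains non-finite entries")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.patients, columns=self.features)


def scale_input(nsm: SmoothedMatrix) -> ScaledMatrix:
    """Per-gene min-max scaling to [0, 1]; constant genes map to 0.

    Required because the sigmoid output layer can only reconstruct values in
    (0, 1).  The scaling record is retained for reproducibility.
    """
    V = np.asarray(nsm.values, dtype=float)
    if not np.isfinite(V).all():
        raise ValidationError("smoothed matrix contains non-finite entries")
    mins = V.min(axis=0)
    ranges = V.max(axis=0) - mins
    safe = np.where(ranges == 0, 1.0, ranges)
    X = (V - mins) / safe
    X[:, ranges == 0] = 0.0
    rec = ScalingRecord(genes=list(nsm.genes), mins=mins, ranges=ranges)
    return ScaledMatrix(list(nsm.patients), list(nsm.genes), X, rec)


def _init_layers(sizes: list[int], rng: np.random.Generator):
    """Fan-in uniform initialization, U(-1/sqrt(fan_in), 1/sqrt(fan_in))."""
    weights, biases = [], []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        bound = 1.0 / np.sqrt(fan_in)
        weights.append(rng.uniform(-bound, bound, size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    return weights, biases


def train_autoencoder(X: ScaledMatrix | np.ndarray, cfg: EncoderConfig) -> TrainedEncoder:
    """Train the autoencoder on a [0, 1]-scaled matrix by minibatch Adam.

    The per-epoch training and validation losses are recorded; training ends
    at ``max_epochs`` or when the validation loss has not improved for
    ``early_stopping_patience`` epochs, restoring the best validation weights.
    """
    if isinstance(X, ScaledMatrix):
        genes = X.genes
        patients = X.patients
        scaling = X.scaling
        Xv = X.values
    else:
        Xv = np.asarray(X, dtype=float)
        genes = [f"g{j}" for j in range(Xv.shape[1])]
        patients = [f"p{i}" for i in range(Xv.shape[0])]
        scaling = None
    n, d = Xv.shape
    if cfg.latent_dim > d:
        raise ValueError("latent_dim must not exceed the number of genes")

    rng = np.random.default_rng(cfg.seed)
    sizes = [d, *cfg.hidden_sizes, d]
    weights, biases = _init_layers(sizes, rng)
    n_layers = len(weights)

    # 90/10 split by random shuffle under the run seed
    perm = rng.permutation(n)
    n_val = max(1, int(round(cfg.validation_fraction * n))) if n > 1 else 0
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    if len(train_idx) == 0:
        train_idx, val_idx = perm, perm[:0]
    Xtr, Xval = Xv[train_idx], Xv[val_idx]

    # Adam state
    mW = [np.zeros_like(w) for w in weights]
    vW = [np.zeros_like(w) for w in weights]
    mB = [np.zeros_like(b) for b in biases]
    vB = [np.zeros_like(b) for b in biases]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    lr = cfg.learning_rate
    step = 0

    def batch_forward(xb):
        acts = [xb]
        h = xb
        for i in range(n_layers):
            z = h @ weights[i] + biases[i]
            h = sigmoid(z) if i == n_layers - 1 else relu(z)
            acts.append(h)
        return acts

    history = []
    best_val = np.inf
    best_weights = None
    patience = cfg.early_stopping_patience
    patience_left = patience if patience is not None else 0
    ntr = len(Xtr)

    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(ntr)
        for start in range(0, ntr, cfg.batch_size):
            xb = Xtr[order[start : start + cfg.batch_size]]
            nb = xb.shape[0]
            acts = batch_forward(xb)
            x_hat = acts[-1]
            # dL/dx_hat for L = (1/n_batch) sum_i ||x_i - x_hat_i||^2
            delta = (2.0 / nb) * (x_hat - xb) * x_hat * (1.0 - x_hat)  # sigmoid'
            step += 1
            for i in range(n_layers - 1, -1, -1):
                gW = acts[i].T @ delta
                gB = delta.sum(axis=0)
                if i > 0:
                    delta = (delta @ weights[i].T) * (acts[i] > 0)  # relu'
                for g, m, v, param in ((gW, mW, vW, weights), (gB, mB, vB, biases)):
                    m[i] = beta1 * m[i] + (1 - beta1) * g
                    v[i] = beta2 * v[i] + (1 - beta2) * g * g
                    m_hat = m[i] / (1 - beta1**step)
                    v_hat = v[i] / (1 - beta2**step)
                    param[i] = param[i] - lr * m_hat / (np.sqrt(v_hat) + eps)

        train_loss = mse_loss(Xtr, batch_forward(Xtr)[-1])
        val_loss = mse_loss(Xval, batch_forward(Xval)[-1]) if len(Xval) else train_loss
        if not np.isfinite(train_loss):
            raise TrainingDivergedError(
                "training loss diverged; try a smaller learning rate"
            )
        history.append({"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss})

        if patience is not None:
            if val_loss < best_val - 1e-12:
                best_val = val_loss
                best_weights = ([w.copy() for w in weights], [b.copy() for b in biases])
                patience_left = patience
            else:
                patience_left -= 1
                if patience_left <= 0:
                    break

    if best_weights is not None:
        weights, biases = best_weights

    return TrainedEncoder(
        weights=weights,
        biases=biases,
        genes=list(genes),
        config=cfg,
        training_history=pd.DataFrame(history),
        input_scaling=scaling,
    )


def encode(enc: TrainedEncoder, X: ScaledMatrix | np.ndarray) -> EncodedMatrix:
    """Deterministic forward pass through the encoder bottleneck."""
    if isinstance(X, ScaledMatrix):
        if X.genes != enc.genes:
            raise ValidationError("gene order differs from the encoder's training order")
        patients = X.patients
        Xv = X.values
    else:
        Xv = np.asarray(X, dtype=float)
        if Xv.shape[1] != len(enc.genes):
            raise ValidationError("input width differs from the encoder's training width")
        patients = [f"p{i}" for i in range(Xv.shape[0])]
    Z = enc.encode_values(Xv)
    features = [f"z{j + 1}" for j in range(Z.shape[1])]
    return EncodedMatrix(patients=list(patients), features=features, values=Z)
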