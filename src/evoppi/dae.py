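"""Denoising autoencoder for per-protein feature learning.

Each protein enters as a flattened, [0, 1]-scaled 20 x 20 profile matrix
(400 values).  Training corrupts every input with additive Gaussian noise,
x~ = x + g with g ~ N(0, sigma^2 I), pushes it through a sigmoid
encoder-decoder stack, and minimises the mean squared reconstruction error
against the *clean* input:

    y = s(W x~ + b)          (encoder, per layer)
    z = s(W' y + b')         (decoder, mirrored shapes)
    L(x, z) = ||x - z||^2    averaged over the batch

The encoder's deepest activations are the learned features.  Inference
always encodes clean inputs.  Everything — weight init, batch order, noise
draws — is driven by a single seed, so runs are bit-reproducible on one
machine.  Implemented directly on NumPy with an Adam optimiser; the
network is small enough (400-256-128 by default) that CPU training takes
seconds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .transforms import FixedMatrix

_FORMAT_VERSION = 1

GAUSSIAN = "gaussian"
MASKING = "masking"


@dataclass(frozen=True)
class DAEConfig:
    """Hyperparameters of the denoising autoencoder.

    ``layer_sizes`` are the encoder widths after the 400-wide input; the
    decoder mirrors them.  ``noise_sigma`` is the corruption scale: the
    standard deviation of the additive Gaussian noise (or, for
    ``noise_kind="masking"``, the fraction of inputs zeroed).
    """

    layer_sizes: tuple[int, ...] = (256, 128)
    noise_sigma: float = 0.1
    epochs: int = 100
    batch_size: int = 64
    learning_rate: float = 1e-3
    seed: int = 0
    noise_kind: str = GAUSSIAN
    input_dim: int = 400

    def __post_init__(self) -> None:
        if not self.layer_sizes or any(s < 1 for s in self.layer_sizes):
            raise ValueError("layer_sizes must be positive integers")
        if self.layer_sizes[-1] >= self.input_dim:
            raise ValueError("latent width must be smaller than the input (compression)")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if self.epochs < 1 or self.batch_size < 1 or self.learning_rate <= 0:
            raise ValueError("epochs, batch_size must be >= 1 and learning_rate > 0")
        if self.noise_kind not in (GAUSSIAN, MASKING):
            raise ValueError(f"unknown noise_kind {self.noise_kind!r}")
        object.__setattr__(self, "layer_sizes", tuple(int(s) for s in self.layer_sizes))


@dataclass
class FeatureVector:
    """A learned per-protein representation (the encoder's latent activations)."""

    protein_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"non-finite feature values for {self.protein_id!r}")


@dataclass
class DAEModel:
    """Trained encoder/decoder weights plus the config that produced them."""

    encoder_weights: list[np.ndarray]
    encoder_biases: list[np.ndarray]
    decoder_weights: list[np.ndarray]
    decoder_biases: list[np.ndarray]
    config: DAEConfig
    training_loss_history: list[float] = field(default_factory=list)

    @property
    def latent_width(self) -> int:
        return self.config.layer_sizes[-1]


def sigmoid(x):
    """Numerically stable logistic function 1 / (1 + exp(-x))."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    if out.ndim == 0:
        return float(out)
    return out


def corrupt(x: np.ndarray, noise_sigma: float, rng: np.random.Generator,
            noise_kind: str = GAUSSIAN) -> np.ndarray:
    """Corrupt an input with seeded noise; sigma 0 returns the input unchanged."""
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be non-negative")
    x = np.asarray(x, dtype=float)
    if noise_sigma == 0:
        return x.copy()
    if noise_kind == GAUSSIAN:
        return x + rng.normal(0.0, noise_sigma, size=x.shape)
    if noise_kind == MASKING:
        keep = rng.random(x.shape) >= noise_sigma
        return x * keep
    raise ValueError(f"unknown noise_kind {noise_kind!r}")


def _forward(weights, biases, x):
    """Apply affine+sigmoid layers; returns all activations, input first."""
    acts = [np.asarray(x, dtype=float)]
    for W, b in zip(weights, biases):
        acts.append(sigmoid(acts[-1] @ W + b))
    return acts


def encode(model: DAEModel, x: np.ndarray) -> np.ndarray:
    """Map a 400-vector (or batch) through the encoder stack."""
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != model.config.input_dim:
        raise ValueError(f"expected input width {model.config.input_dim}, got {x.shape[-1]}")
    return _forward(model.encoder_weights, model.encoder_biases, x)[-1]


def decode(model: DAEModel, y: np.ndarray) -> np.ndarray:
    """Map a latent vector (or batch) back to a 400-wide reconstruction."""
    y = np.asarray(y, dtype=float)
    if y.shape[-1] != model.latent_width:
        raise ValueError(f"expected latent width {model.latent_width}, got {y.shape[-1]}")
    return _forward(model.decoder_weights, model.decoder_biases, y)[-1]


def reconstruction_loss(x: np.ndarray, z: np.ndarray) -> float:
    """Squared-error reconstruction loss ||x - z||^2 of a single vector pair."""
    x = np.asarray(x, dtype=float)
    z = np.asarray(z, dtype=float)
    if x.shape != z.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {z.shape}")
    d = x - z
    return float(np.dot(d.ravel(), d.ravel()))


def _init_params(config: DAEConfig, rng: np.random.Generator):
    dims = (config.input_dim, *config.layer_sizes)
    enc_w, enc_b = [], []
    for d_in, d_out in zip(dims[:-1], dims[1:]):
        limit = np.sqrt(6.0 / (d_in + d_out))
        enc_w.append(rng.uniform(-limit, limit, size=(d_in, d_out)))
        enc_b.append(np.zeros(d_out))
    dec_w, dec_b = [], []
    for d_in, d_out in zip(dims[::-1][:-1], dims[::-1][1:]):
        limit = np.sqrt(6.0 / (d_in + d_out))
        dec_w.append(rng.uniform(-limit, limit, size=(d_in, d_out)))
        dec_b.append(np.zeros(d_out))
    return enc_w, enc_b, dec_w, dec_b


def _check_scaled(matrices: Sequence[FixedMatrix]) -> np.ndarray:
    if not matrices:
        raise ValueError("no input matrices")
    for m in matrices:
        if not m.scaled:
            raise ValueError(f"matrix for {m.protein_id!r} is not scaled to [0, 1]")
    return np.stack([m.flat() for m in matrices])


def train_dae(data: Sequence[FixedMatrix], config: DAEConfig | None = None) -> DAEModel:
    """Train a denoising autoencoder on scaled fixed-size matrices.

    Corruption noise is resampled fresh every epoch; the loss recorded per
    epoch is the mean per-sample squared reconstruction error against the
    clean inputs.  Fully reproducible given ``config.seed``.
    """
    if config is None:
        config = DAEConfig()
    X = _check_scaled(data)
    n = X.shape[0]
    rng = np.random.default_rng(config.seed)
    enc_w, enc_b, dec_w, dec_b = _init_params(config, rng)
    params = enc_w + enc_b + dec_w + dec_b  # flat view, updated in place

    # Adam state
    mom = [np.zeros_like(p) for p in params]
    vel = [np.zeros_like(p) for p in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0

    n_enc = len(enc_w)
    loss_history: list[float] = []
    for _ in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            x = X[idx]
            x_noisy = corrupt(x, config.noise_sigma, rng, config.noise_kind)

            acts = _forward(enc_w + dec_w, enc_b + dec_b, x_noisy)
            z = acts[-1]
            diff = z - x
            epoch_loss += float(np.sum(diff * diff))

            # backprop: d(mean_i ||x_i - z_i||^2)/dz = 2 (z - x) / batch
            grad_w = [None] * len(params)
            delta = (2.0 / len(idx)) * diff * z * (1.0 - z)
            all_w = enc_w + dec_w
            grads_W, grads_b = [], []
            for layer in range(len(all_w) - 1, -1, -1):
                a_prev = acts[layer]
                grads_W.append(a_prev.T @ delta)
                grads_b.append(delta.sum(axis=0))
                if layer > 0:
                    delta = (delta @ all_w[layer].T) * a_prev * (1.0 - a_prev)
            grads_W.reverse()
            grads_b.reverse()

            grads = grads_W[:n_enc] + grads_b[:n_enc] + grads_W[n_enc:] + grads_b[n_enc:]
            step += 1
            bc1 = 1.0 - beta1**step
            bc2 = 1.0 - beta2**step
            for p, g, m_, v_ in zip(params, grads, mom, vel):
                m_ *= beta1
                m_ += (1 - beta1) * g
                v_ *= beta2
                v_ += (1 - beta2) * g * g
                p -= config.learning_rate * (m_ / bc1) / (np.sqrt(v_ / bc2) + eps)
        loss_history.append(epoch_loss / n)

    return DAEModel(
        encoder_weights=enc_w, encoder_biases=enc_b,
        decoder_weights=dec_w, decoder_biases=dec_b,
        config=config, training_loss_history=loss_history,
    )


def extract_features(model: DAEModel, matrices: Sequence[FixedMatrix]) -> list[FeatureVector]:
    """Encode scaled matrices (clean, uncorrupted) into latent feature vectors."""
    X = _check_scaled(matrices)
    Y = encode(model, X)
    return [FeatureVector(protein_id=m.protein_id, values=y) for m, y in zip(matrices, Y)]


def save_model(model: DAEModel, path: str | Path) -> None:
    """Serialise a model (shapes, weights, config) to a portable JSON file."""
    blob = {
        "format_version": _FORMAT_VERSION,
        "config": asdict(model.config),
        "encoder_weights": [w.tolist() for w in model.encoder_weights],
        "encoder_biases": [b.tolist() for b in model.encoder_biases],
        "decoder_weights": [w.tolist() for w in model.decoder_weights],
        "decoder_biases": [b.tolist() for b in model.decoder_biases],
        "training_loss_history": model.training_loss_history,
    }
    Path(path).write_text(json.dumps(blob))


def load_model(path: str | Path) -> DAEModel:
    blob = json.loads(Path(path).read_text())
    version = blob.get("format_version")
    if version != _FORMAT_VERSION:
        raise ValueError(f"unsupported model format version {version!r}")
    cfg = blob["config"]
    cfg["layer_sizes"] = tuple(cfg["layer_sizes"])
    return DAEModel(
        encoder_weights=[np.array(w) for w in blob["encoder_weights"]],
        encoder_biases=[np.array(b) for b in blob["encoder_biases"]],
        decoder_weights=[np.array(w) for w in blob["decoder_weights"]],
        decoder_biases=[np.array(b) for b in blob["decoder_biases"]],
        config=DAEConfig(**cfg),
        training_loss_history=list(blob["training_loss_history"]),
    )
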