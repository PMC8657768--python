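"""Greedy layer-wise stacked autoencoder for embedding compression.

Each layer is a one-hidden-layer autoencoder (nonlinear encoder, linear
reconstruction) trained to minimize mean squared reconstruction error on
the previous layer's hidden output.  Layers are trained in sequence —
the first on the (standardized) input features, each subsequent one on
its predecessor's codes — and the final bottleneck code is the
compressed feature, e.g. 512 -> 256 -> 128 -> 64.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, NamedTuple

import numpy as np

from .embedding import EmbeddingMatrix

__all__ = [
    "StackConfig",
    "LayerParams",
    "LayerTraining",
    "StackModel",
    "default_layer_dims",
    "train_layer",
    "fit_stack",
    "encode_stack",
    "save_stack",
    "load_stack",
]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -35.0, 35.0)))


_ACTIVATIONS: dict[str, tuple[Callable, Callable]] = {
    # name -> (f, f' expressed in terms of f(x))
    "sigmoid": (_sigmoid, lambda a: a * (1.0 - a)),
    "tanh": (np.tanh, lambda a: 1.0 - a * a),
    "linear": (lambda x: x, lambda a: np.ones_like(a)),
    "relu": (lambda x: np.maximum(x, 0.0), lambda a: (a > 0).astype(np.float64)),
}


def default_layer_dims(input_dim: int, bottleneck: int = 64) -> tuple[int, ...]:
    """Halve the width from ``input_dim`` down to the bottleneck.

    E.g. 512 -> (512, 256, 128, 64): a three-level stack ending at the
    64-dimensional compressed feature.
    """
    if input_dim <= bottleneck:
        raise ValueError("input_dim must exceed the bottleneck")
    dims = [input_dim]
    while dims[-1] // 2 > bottleneck:
        dims.append(dims[-1] // 2)
    dims.append(bottleneck)
    return tuple(dims)


@dataclass(frozen=True)
class StackConfig:
    """Stacked-autoencoder hyperparameters.

    ``layer_dims`` runs input -> ... -> bottleneck and must be strictly
    decreasing.  The encoder hidden units use ``activation``; the
    reconstruction output is always linear.
    """

    layer_dims: tuple[int, ...]
    activation: str = "sigmoid"
    epochs: int = 100
    learning_rate: float = 1e-3
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        dims = tuple(self.layer_dims)
        object.__setattr__(self, "layer_dims", dims)
        if len(dims) < 2:
            raise ValueError("layer_dims needs at least input and bottleneck")
        if any(b >= a for a, b in zip(dims, dims[1:])):
            raise ValueError("layer_dims must be strictly decreasing")
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")


@dataclass(frozen=True)
class LayerParams:
    """Weights of one autoencoder layer."""

    encode_w: np.ndarray  # (in, hidden)
    encode_b: np.ndarray  # (hidden,)
    decode_w: np.ndarray  # (hidden, in)
    decode_b: np.ndarray  # (in,)
    activation: str = "sigmoid"

    def encode(self, x: np.ndarray) -> np.ndarray:
        f = _ACTIVATIONS[self.activation][0]
        return f(x @ self.encode_w + self.encode_b)

    def reconstruct(self, x: np.ndarray) -> np.ndarray:
        return self.encode(x) @ self.decode_w + self.decode_b


class LayerTraining(NamedTuple):
    params: LayerParams
    hidden: np.ndarray
    initial_mse: float
    final_mse: float


def train_layer(
    data: np.ndarray,
    hidden_dim: int,
    activation: str = "sigmoid",
    epochs: int = 100,
    learning_rate: float = 1e-3,
    batch_size: int = 32,
    seed: int = 0,
) -> LayerTraining:
    """Train one autoencoder layer by mini-batch Adam on the MSE loss.

    Weights initialize Glorot-uniform under ``seed``; rows are shuffled
    each epoch by the same generator, so the run is deterministic.
    Returns the trained parameters, the hidden codes of ``data`` and the
    reconstruction MSE before and after training.
    """
    x = np.asarray(data, dtype=np.float64)
    n, m = x.shape
    if hidden_dim >= m:
        raise ValueError(f"hidden_dim {hidden_dim} must be < input dim {m}")
    if activation not in _ACTIVATIONS:
        raise ValueError(f"unknown activation {activation!r}")
    f, fprime = _ACTIVATIONS[activation]

    rng = np.random.Generator(np.random.PCG64(seed))
    lim_e = np.sqrt(6.0 / (m + hidden_dim))
    w1 = rng.uniform(-lim_e, lim_e, size=(m, hidden_dim))
    b1 = np.zeros(hidden_dim)
    w2 = rng.uniform(-lim_e, lim_e, size=(hidden_dim, m))
    b2 = np.zeros(m)

    def mse() -> float:
        recon = f(x @ w1 + b1) @ w2 + b2
        return float(np.mean((recon - x) ** 2))

    initial = mse()

    # Adam state
    params = [w1, b1, w2, b2]
    mom = [np.zeros_like(p) for p in params]
    vel = [np.zeros_like(p) for p in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0

    for _ in range(epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            xb = x[idx]
            nb = len(idx)
            a = f(xb @ w1 + b1)
            recon = a @ w2 + b2
            err = 2.0 * (recon - xb) / (nb * m)  # d(MSE)/d(recon)
            g_w2 = a.T @ err
            g_b2 = err.sum(axis=0)
            da = err @ w2.T * fprime(a)
            g_w1 = xb.T @ da
            g_b1 = da.sum(axis=0)
            step += 1
            for p_, mo, ve, g in zip(params, mom, vel, [g_w1, g_b1, g_w2, g_b2]):
                mo *= beta1
                mo += (1 - beta1) * g
                ve *= beta2
                ve += (1 - beta2) * g * g
                mhat = mo / (1 - beta1**step)
                vhat = ve / (1 - beta2**step)
                p_ -= learning_rate * mhat / (np.sqrt(vhat) + eps)

    layer = LayerParams(
        encode_w=w1, encode_b=b1, decode_w=w2, decode_b=b2, activation=activation
    )
    return LayerTraining(
        params=layer, hidden=layer.encode(x), initial_mse=initial, final_mse=mse()
    )


@dataclass(frozen=True)
class StackModel:
    """Trained stack: standardization constants plus per-layer weights."""

    mean: np.ndarray
    std: np.ndarray
    layers: tuple[LayerParams, ...]
    layer_dims: tuple[int, ...]
    layer_mses: tuple[tuple[float, float], ...] = field(default=())

    def transform(self, x: np.ndarray) -> np.ndarray:
        """Encode rows to the bottleneck; purely per-row."""
        h = (np.asarray(x, dtype=np.float64) - self.mean) / self.std
        for layer in self.layers:
            h = layer.encode(h)
        return h


def fit_stack(data: np.ndarray, config: StackConfig) -> StackModel:
    """Greedy layer-wise training of the whole stack.

    Features are standardized per column (zero mean, unit variance)
    before the first layer; the constants are stored for reuse on new
    rows at prediction time.
    """
    x = np.asarray(data, dtype=np.float64)
    if x.shape[1] != config.layer_dims[0]:
        raise ValueError(
            f"data dim {x.shape[1]} != layer_dims[0] {config.layer_dims[0]}"
        )
    mean = x.mean(axis=0)
    std = x.std(axis=0)
    std = np.where(std < 1e-8, 1.0, std)
    h = (x - mean) / std

    layers: list[LayerParams] = []
    mses: list[tuple[float, float]] = []
    for li, hidden_dim in enumerate(config.layer_dims[1:]):
        result = train_layer(
            h,
            hidden_dim,
            activation=config.activation,
            epochs=config.epochs,
            learning_rate=config.learning_rate,
            batch_size=config.batch_size,
            seed=config.seed + li,
        )
        layers.append(result.params)
        mses.append((result.initial_mse, result.final_mse))
        h = result.hidden
    return StackModel(
        mean=mean,
        std=std,
        layers=tuple(layers),
        layer_dims=config.layer_dims,
        layer_mses=tuple(mses),
    )


def encode_stack(
    features: EmbeddingMatrix, config: StackConfig
) -> tuple[EmbeddingMatrix, StackModel]:
    """Fit the stack on an embedding and return the compressed embedding.

    Row <-> gene correspondence is preserved: each gene's compressed
    vector depends only on that gene's input vector given the weights.
    """
    if features.dim != config.layer_dims[0]:
        raise ValueError(
            f"embedding dim {features.dim} != layer_dims[0] {config.layer_dims[0]}"
        )
    model = fit_stack(features.vectors, config)
    codes = model.transform(features.vectors)
    return EmbeddingMatrix(ids=features.ids, vectors=codes), model


def save_stack(model: StackModel, path: str | Path) -> None:
    """Save stack weights as an .npz archive with a JSON manifest."""
    path = Path(path)
    arrays: dict[str, np.ndarray] = {"mean": model.mean, "std": model.std}
    for i, layer in enumerate(model.layers):
        arrays[f"l{i}_ew"] = layer.encode_w
        arrays[f"l{i}_eb"] = layer.encode_b
        arrays[f"l{i}_dw"] = layer.decode_w
        arrays[f"l{i}_db"] = layer.decode_b
    np.savez(path, **arrays)
    manifest = {
        "layer_dims": list(model.layer_dims),
        "activations": [l.activation for l in model.layers],
        "layer_mses": [list(m) for m in model.layer_mses],
    }
    path.with_suffix(".json").write_text(json.dumps(manifest, indent=2))


def load_stack(path: str | Path) -> StackModel:
    path = Path(path)
    manifest = json.loads(path.with_suffix(".json").read_text())
    data = np.load(path if path.suffix == ".npz" else path.with_suffix(".npz"))
    layers = tuple(
        LayerParams(
            encode_w=data[f"l{i}_ew"],
            encode_b=data[f"l{i}_eb"],
            decode_w=data[f"l{i}_dw"],
            decode_b=data[f"l{i}_db"],
            activation=act,
        )
        for i, act in enumerate(manifest["activations"])
    )
    return StackModel(
        mean=data["mean"],
        std=data["std"],
        layers=layers,
        layer_dims=tuple(manifest["layer_dims"]),
        layer_mses=tuple(tuple(m) for m in manifest["layer_mses"]),
    )
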