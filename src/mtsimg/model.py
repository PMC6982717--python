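"""Convolutional classifiers: architecture specs, training, prediction.

Two architectures are provided:

* ``simple`` — two 5x5 convolution layers (6 and 12 filters), each followed
  by ReLU and a 2x2/stride-2 max pool, then one fully-connected output layer;
  default learning rate 0.0023.
* ``vgg16`` — the canonical 13-conv/5-pool/3-FC VGG-16 stack with 3x3
  kernels and FC sizes (4096, 4096, 2); default learning rate 0.00023.

Convolutions use same padding, so only the pools change spatial dims: after
k pools each spatial dimension is exactly the input divided by 2**k.  The
optimiser is mini-batch SGD with momentum 0.9 on a two-class softmax
cross-entropy; early stopping monitors an internal validation split and
restores the best-validation weights.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .errors import (
    DivergenceError,
    InvalidArgumentError,
    InvalidInputError,
    ShapeError,
)

__all__ = [
    "ArchitectureSpec",
    "TrainConfig",
    "TrainedModel",
    "build_architecture",
    "train",
    "predict",
    "error_rate",
    "save_checkpoint",
    "load_checkpoint",
]

_SIMPLE_FILTERS = (6, 12)
_VGG16_PLAN = (  # conv filter counts; "P" marks a max pool
    64, 64, "P", 128, 128, "P", 256, 256, 256, "P",
    512, 512, 512, "P", 512, 512, 512, "P",
)
_VGG16_FC = (4096, 4096)

DEFAULT_LEARNING_RATE = {"simple": 0.0023, "vgg16": 0.00023}


@dataclass(frozen=True)
class ArchitectureSpec:
    """A fully resolved layer plan for one network family."""

    family: str  # "simple" | "vgg16"
    input_shape: tuple[int, int, int]  # (3, n*m, n)
    conv_kernel: int
    conv_plan: tuple  # filter counts with "P" pool markers
    fc_sizes: tuple[int, ...]  # hidden FC sizes (output layer excluded)
    n_classes: int = 2

    @property
    def n_pools(self) -> int:
        return sum(1 for x in self.conv_plan if x == "P")

    @property
    def output_spatial(self) -> tuple[int, int]:
        _, h, w = self.input_shape
        s = 2 ** self.n_pools
        return h // s, w // s

    def n_parameters(self) -> int:
        total, ch = 0, self.input_shape[0]
        for item in self.conv_plan:
            if item == "P":
                continue
            total += item * (ch * self.conv_kernel**2 + 1)
            ch = item
        dim = ch * self.output_spatial[0] * self.output_spatial[1]
        for fc in (*self.fc_sizes, self.n_classes):
            total += dim * fc + fc
            dim = fc
        return total


def build_architecture(
    family: str,
    input_shape: tuple[int, int, int],
    conv_filters: tuple[int, ...] | None = None,
) -> ArchitectureSpec:
    """Resolve a named family into an explicit layer plan for a given input.

    ``input_shape`` is (3, n*m, n).  Both spatial dims must be divisible by
    2**n_pools (4 for ``simple``, 32 for ``vgg16``) so every pool halves them
    exactly; otherwise a ShapeError explains the requirement.  ``conv_filters``
    overrides the per-conv filter counts of the ``simple`` family.
    """
    if family not in ("simple", "vgg16"):
        raise InvalidArgumentError(f"unknown family {family!r}")
    c, h, w = input_shape
    if c != 3:
        raise ShapeError(f"input must have 3 colour channels, got {c}")
    if h < 8 or w < 8:
        raise ShapeError(f"spatial dims must each be >= 8, got {h}x{w}")
    if family == "simple":
        filters = tuple(conv_filters) if conv_filters else _SIMPLE_FILTERS
        plan = tuple(x for f in filters for x in (f, "P"))
        kernel, fc_sizes = 5, ()
    else:
        plan, kernel, fc_sizes = _VGG16_PLAN, 3, _VGG16_FC
    n_pools = sum(1 for x in plan if x == "P")
    div = 2**n_pools
    if h % div or w % div:
        raise ShapeError(
            f"{family} halves spatial dims {n_pools} times; {h}x{w} is not "
            f"divisible by {div}"
        )
    return ArchitectureSpec(family, tuple(input_shape), kernel, plan, fc_sizes)


def _build_network(spec: ArchitectureSpec, rng: np.random.Generator) -> nn.Sequential:
    layers: list[nn.Layer] = []
    ch = spec.input_shape[0]
    for item in spec.conv_plan:
        if item == "P":
            layers.append(nn.MaxPool2())
        else:
            layers.append(nn.Conv2D(ch, item, spec.conv_kernel, rng))
            layers.append(nn.ReLU())
            ch = item
    layers.append(nn.Flatten())
    dim = ch * spec.output_spatial[0] * spec.output_spatial[1]
    for fc in spec.fc_sizes:
        layers.append(nn.Dense(dim, fc, rng))
        layers.append(nn.ReLU())
        dim = fc
    layers.append(nn.Dense(dim, spec.n_classes, rng))
    return nn.Sequential(layers)


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation settings; learning_rate=None uses the family default."""

    learning_rate: float | None = None
    max_epochs: int = 200
    patience: int = 10
    batch_size: int = 16
    validation_fraction: float = 0.1
    momentum: float = 0.9
    seed: int = 0

    def __post_init__(self):
        if self.patience < 1:
            raise InvalidArgumentError(f"patience must be >= 1, got {self.patience}")
        if not 0.0 < self.validation_fraction <= 0.5:
            raise InvalidArgumentError(
                f"validation_fraction must be in (0, 0.5], got {self.validation_fraction}"
            )
        if self.max_epochs < 1 or self.batch_size < 1:
            raise InvalidArgumentError("max_epochs and batch_size must be >= 1")


@dataclass
class TrainedModel:
    """A trained network plus its provenance (spec, config, loss history)."""

    spec: ArchitectureSpec
    network: nn.Sequential
    config: TrainConfig
    history: dict  # {"train_loss": [...], "val_loss": [...]}
    stopped_epoch: int


def _validate_images(images, input_shape) -> np.ndarray:
    x = np.asarray(images, dtype=np.float32)
    if x.size and (x.ndim != 4 or x.shape[1:] != tuple(input_shape)):
        raise InvalidInputError(
            f"images must have shape (N, {', '.join(map(str, input_shape))}), "
            f"got {x.shape}"
        )
    return x


def train(
    spec: ArchitectureSpec, images, labels, config: TrainConfig | None = None
) -> TrainedModel:
    """Train a network by mini-batch SGD with early stopping.

    A ``validation_fraction`` split (stratified when possible) is held out
    internally; training stops once validation loss has failed to improve
    for ``patience`` consecutive epochs, and the best-validation weights are
    restored.  Deterministic for a fixed (seed, config, data).
    """
    config = config or TrainConfig()
    x = _validate_images(images, spec.input_shape)
    y = np.asarray(labels, dtype=int)
    if x.shape[0] != y.shape[0] or x.shape[0] < 2:
        raise InvalidInputError("need >= 2 images with one label each")
    if len(np.unique(y)) < 2:
        raise InvalidInputError("training data must contain both classes")

    rng = np.random.default_rng(config.seed)
    net = _build_network(spec, rng)
    lr = (
        config.learning_rate
        if config.learning_rate is not None
        else DEFAULT_LEARNING_RATE[spec.family]
    )

    # stratified validation split: round a per-class share of the hold-out
    n = x.shape[0]
    n_val = max(1, int(round(n * config.validation_fraction)))
    order = rng.permutation(n)
    val_idx, tr_idx = [], []
    taken = {0: 0, 1: 0}
    quota = {
        c: max(1, int(round(n_val * np.mean(y == c)))) for c in (0, 1)
    }
    for i in order:
        c = int(y[i])
        if taken[c] < quota[c] and len(val_idx) < n_val + 1:
            val_idx.append(i)
            taken[c] += 1
        else:
            tr_idx.append(i)
    tr_idx, val_idx = np.array(tr_idx), np.array(val_idx)
    if len(np.unique(y[tr_idx])) < 2:
        raise InvalidInputError("validation split left single-class training data")
    x_tr, y_tr, x_val, y_val = x[tr_idx], y[tr_idx], x[val_idx], y[val_idx]

    history = {"train_loss": [], "val_loss": []}
    best_val, best_weights, since_best = np.inf, None, 0
    stopped = 0
    for epoch in range(1, config.max_epochs + 1):
        perm = rng.permutation(len(x_tr))
        losses = []
        for start in range(0, len(perm), config.batch_size):
            idx = perm[start : start + config.batch_size]
            logits = net.forward(x_tr[idx])
            loss, grad = nn.softmax_cross_entropy(logits, y_tr[idx])
            if not np.isfinite(loss):
                raise DivergenceError(epoch)
            net.backward(grad)
            net.sgd_step(lr, config.momentum)
            losses.append(loss)
        val_loss, _ = nn.softmax_cross_entropy(net.forward(x_val), y_val)
        history["train_loss"].append(float(np.mean(losses)))
        history["val_loss"].append(float(val_loss))
        stopped = epoch
        if val_loss < best_val - 1e-12:
            best_val, best_weights, since_best = val_loss, net.get_weights(), 0
        else:
            since_best += 1
            if since_best >= config.patience:
                break
    if best_weights is not None:
        net.set_weights(best_weights)
    return TrainedModel(spec, net, config, history, stopped)


def predict(model: TrainedModel, images, batch_size: int = 64) -> np.ndarray:
    """Predicted labels (argmax of class scores; ties resolve to class 0)."""
    x = _validate_images(images, model.spec.input_shape)
    if x.size == 0:
        return np.array([], dtype=int)
    out = [
        np.argmax(model.network.forward(x[i : i + batch_size]), axis=1)
        for i in range(0, x.shape[0], batch_size)
    ]
    return np.concatenate(out).astype(int)


def error_rate(predicted, actual) -> float:
    """Percentage of held-out instances misclassified: (1 - correct/N) * 100."""
    p = np.asarray(predicted)
    a = np.asarray(actual)
    if p.shape != a.shape or p.ndim != 1 or p.size < 1:
        raise InvalidArgumentError(
            f"predicted and actual must be equal-length 1-D, got {p.shape} vs {a.shape}"
        )
    return float((1.0 - np.mean(p == a)) * 100.0)


# ---------------------------------------------------------------------------
# Checkpointing (runtime artifact: architecture + weights + config + seed)


def save_checkpoint(model: TrainedModel, path) -> None:
    meta = {
        "family": model.spec.family,
        "input_shape": list(model.spec.input_shape),
        "conv_plan": list(model.spec.conv_plan),
        "config": {
            "learning_rate": model.config.learning_rate,
            "max_epochs": model.config.max_epochs,
            "patience": model.config.patience,
            "batch_size": model.config.batch_size,
            "validation_fraction": model.config.validation_fraction,
            "momentum": model.config.momentum,
            "seed": model.config.seed,
        },
        "history": model.history,
        "stopped_epoch": model.stopped_epoch,
    }
    weights = model.network.get_weights()
    np.savez(
        path,
        meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        **{f"w{i}": w for i, w in enumerate(weights)},
    )


def load_checkpoint(path) -> TrainedModel:
    with np.load(path) as archive:
        meta = json.loads(archive["meta"].tobytes().decode())
        weights = [archive[f"w{i}"] for i in range(len(archive.files) - 1)]
    spec = build_architecture(meta["family"], tuple(meta["input_shape"]))
    config = TrainConfig(**meta["config"])
    net = _build_network(spec, np.random.default_rng(config.seed))
    net.set_weights(weights)
    return TrainedModel(spec, net, config, meta["history"], meta["stopped_epoch"])
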