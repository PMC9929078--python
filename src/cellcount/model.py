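"""The CNN count regressor: architecture, training with early stopping, prediction.

The network is four [Conv(k=3, valid, ReLU) -> MaxPool(2x2, stride 2)] blocks
with filter counts 32/64/128/256, then Flatten -> Dropout(0.90) -> a single
Dense output neuron with ReLU activation (counts are non-negative), trained
with MSE loss.  All of it is configurable through :class:`ModelSpec`; the
spatial bookkeeping for 'valid' convolutions and pooling is
``s -> floor((s - kernel + 1) / 1)`` then ``s -> floor(s / 2)`` per block,
so a 200x200 input shrinks 200 -> 99 -> 48 -> 23 -> 10 before Flatten.

Training regresses raw counts.  Because count labels span hundreds while the
optimiser's step size is tuned for order-one targets, labels are divided by a
scale (default: the mean training label) during optimisation and predictions
are multiplied back, so every reported error is in count units.  Early
stopping monitors the validation MSE, waits ``patience`` epochs for an
improvement, and restores the best weights seen.
"""

from __future__ import annotations

import dataclasses
import time
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np

from . import nn
from .datasets import Bank
from .errors import ConfigurationError, ValidationError

__all__ = [
    "ModelSpec",
    "TrainConfig",
    "TrainHistory",
    "CountRegressor",
    "spatial_chain",
    "build_model",
    "train",
    "predict",
]


@dataclass(frozen=True)
class ModelSpec:
    """Architecture hyperparameters of the count regressor."""

    conv_blocks: tuple = (32, 64, 128, 256)
    kernel_size: int = 3
    pool_size: tuple = (2, 2)
    pool_strides: tuple = (2, 2)
    padding: str = "valid"
    dropout_rate: float = 0.90
    input_size: tuple = (200, 200, 1)

    def __post_init__(self) -> None:
        object.__setattr__(self, "conv_blocks", tuple(self.conv_blocks))
        if any(f <= 0 for f in self.conv_blocks):
            raise ConfigurationError(f"filter counts must be positive: {self.conv_blocks}")
        if self.kernel_size % 2 != 1 or self.kernel_size < 1:
            raise ConfigurationError(f"kernel_size must be odd, got {self.kernel_size}")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ConfigurationError(f"dropout_rate must be in [0,1), got {self.dropout_rate}")
        if self.padding != "valid":
            raise ConfigurationError("only 'valid' padding is supported")
        if tuple(self.pool_size) != (2, 2) or tuple(self.pool_strides) != (2, 2):
            raise ConfigurationError("only 2x2 pooling with stride 2 is supported")


@dataclass(frozen=True)
class TrainConfig:
    """Training knobs the architecture table leaves open."""

    optimizer: str = "adam"
    learning_rate: float = 1e-3
    clipnorm: Optional[float] = 5.0
    batch_size: int = 32
    max_epochs: int = 500
    monitor: str = "val_mse"
    patience: int = 20
    restore_best: bool = True
    label_scale: Union[float, str, None] = "auto"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ConfigurationError(f"batch_size must be >= 1, got {self.batch_size}")
        if self.patience < 1:
            raise ConfigurationError(f"patience must be >= 1, got {self.patience}")
        if self.optimizer != "adam":
            raise ConfigurationError(f"unknown optimizer {self.optimizer!r}")
        if self.monitor != "val_mse":
            raise ConfigurationError("only val_mse monitoring is supported")


@dataclass
class TrainHistory:
    """Per-epoch MSE curves (count^2 units) and stopping bookkeeping."""

    train_mse: list = field(default_factory=list)
    val_mse: list = field(default_factory=list)
    stopped_epoch: int = 0
    best_epoch: int = 0
    wall_seconds: float = 0.0

    def save(self, out_dir: str) -> None:
        """Write ``history.csv`` (epoch, train_mse, val_mse) and ``summary.json``."""
        import csv
        import json
        import os
        os.makedirs(out_dir, exist_ok=True)
        with open(os.path.join(out_dir, "history.csv"), "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["epoch", "train_mse", "val_mse"])
            for i, (tr, va) in enumerate(zip(self.train_mse, self.val_mse), 1):
                w.writerow([i, tr, va])
        with open(os.path.join(out_dir, "summary.json"), "w") as fh:
            json.dump({"stopped_epoch": self.stopped_epoch,
                       "best_epoch": self.best_epoch,
                       "best_val_mse": min(self.val_mse) if self.val_mse else None,
                       "wall_seconds": self.wall_seconds}, fh, indent=2)


def spatial_chain(side: int, n_blocks: int, kernel: int = 3) -> list[int]:
    """Spatial side length after each conv+pool block under valid padding.

    Raises :class:`ConfigurationError` naming the failing block if the input
    is too small to survive the chain.
    """
    sizes = []
    s = side
    for i in range(n_blocks):
        s = s - kernel + 1
        if s < 1:
            raise ConfigurationError(
                f"input side {side} too small: conv of block {i + 1} "
                f"would output {s} pixels")
        s = s // 2
        if s < 1:
            raise ConfigurationError(
                f"input side {side} too small: pooling of block {i + 1} "
                f"would output 0 pixels")
        sizes.append(s)
    return sizes


class CountRegressor:
    """A built (optionally trained) count-regression network."""

    def __init__(self, spec: ModelSpec, seed: int = 0):
        self.spec = spec
        side, _, channels = spec.input_size
        chain = spatial_chain(side, len(spec.conv_blocks), spec.kernel_size)
        rng = np.random.default_rng(seed)
        self._dropout_rng = np.random.default_rng(seed + 1)
        layers: list = []
        in_ch = channels
        for filters in spec.conv_blocks:
            layers.append(nn.Conv2D(in_ch, filters, spec.kernel_size, rng, relu=True))
            layers.append(nn.MaxPool2())
            in_ch = filters
        layers.append(nn.Flatten())
        layers.append(nn.Dropout(spec.dropout_rate, self._dropout_rng))
        flat = chain[-1] * chain[-1] * spec.conv_blocks[-1]
        # bias starts at 1 so the ReLU output unit is alive at initialisation;
        # with mean-scaled labels that is also the mean predictor
        layers.append(nn.Dense(flat, 1, rng, relu=True, bias_init=1.0))
        self.net = nn.Sequential(layers)
        self.spatial_sizes = chain
        self.output_scale = 1.0  # set by train(); predictions are scaled back
        self.trained = False

    def n_params(self) -> int:
        return self.net.n_params()

    def save(self, path: str) -> None:
        """Serialize spec, weights and output scale to a ``.npz`` archive."""
        import json
        arrays = {f"param_{i}": p for i, p in enumerate(self.net.params())}
        spec = {k: list(v) if isinstance(v, tuple) else v
                for k, v in dataclasses.asdict(self.spec).items()}
        np.savez(path, __meta__=np.array(json.dumps(
            {"spec": spec, "output_scale": self.output_scale,
             "trained": self.trained})), **arrays)

    @classmethod
    def load(cls, path: str) -> "CountRegressor":
        import json
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["__meta__"]))
            spec_kw = {k: tuple(v) if isinstance(v, list) else v
                       for k, v in meta["spec"].items()}
            model = cls(ModelSpec(**spec_kw))
            model.net.set_weights(
                [data[f"param_{i}"] for i in range(len(model.net.params()))])
        model.output_scale = meta["output_scale"]
        model.trained = meta["trained"]
        return model

    def forward_counts(self, x: np.ndarray, batch: int = 64) -> np.ndarray:
        """Inference on an (N, H, W, 1) stack; returns counts (scale applied)."""
        outs = []
        for i in range(0, len(x), batch):
            outs.append(self.net.forward(x[i:i + batch], train=False)[:, 0])
        return np.concatenate(outs) * self.output_scale


def build_model(spec: ModelSpec = ModelSpec(), seed: int = 0) -> CountRegressor:
    """Instantiate the network; deterministic parameter init given the seed."""
    return CountRegressor(spec, seed=seed)


def _bank_to_arrays(bank: Bank, input_size: tuple) -> tuple[np.ndarray, np.ndarray]:
    x = bank.pixel_stack()
    side = input_size[0]
    if x.shape[1:] != (side, side):
        raise ValidationError(
            f"bank images are {x.shape[1:]} but the model expects {side}x{side}")
    return x[..., None].astype(np.float32), bank.counts()


def train(model: CountRegressor, train_bank: Bank, validation_bank: Bank,
          config: TrainConfig = TrainConfig()) -> TrainHistory:
    """Fit the regressor with mini-batch Adam, early stopping on validation MSE.

    Returns the per-epoch history in raw count^2 units; the model's best
    weights (lowest validation MSE) are restored when ``restore_best`` is on.
    """
    if len(train_bank) == 0 or len(validation_bank) == 0:
        raise ValidationError("train and validation banks must be non-empty")
    x_train, y_train = _bank_to_arrays(train_bank, model.spec.input_size)
    x_val, y_val = _bank_to_arrays(validation_bank, model.spec.input_size)

    if config.label_scale == "auto":
        scale = float(max(y_train.mean(), 1e-12))
    elif config.label_scale in (None, 1, 1.0):
        scale = 1.0
    else:
        scale = float(config.label_scale)
    ys = (y_train / scale).astype(np.float32)
    model.output_scale = scale

    rng = np.random.default_rng(config.seed)
    opt = nn.Adam(model.net, lr=config.learning_rate, clipnorm=config.clipnorm)
    history = TrainHistory()
    best_val = np.inf
    best_weights = model.net.get_weights()
    best_epoch = 0
    since_best = 0
    t0 = time.perf_counter()

    n = len(ys)
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(n)
        sq_sum = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            xb, yb = x_train[idx], ys[idx]
            pred = model.net.forward(xb, train=True)[:, 0]
            resid = pred - yb
            if not np.isfinite(resid).all():
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}; try a lower learning rate")
            sq_sum += float((resid**2).sum())
            dout = (2.0 * resid / len(idx)).astype(np.float32)[:, None]
            model.net.backward(dout)
            opt.step()
        history.train_mse.append(sq_sum / n * scale**2)

        val_pred = model.forward_counts(x_val)
        val_mse = float(np.mean((val_pred - y_val) ** 2))
        history.val_mse.append(val_mse)

        if val_mse < best_val - 1e-12:
            best_val = val_mse
            best_epoch = epoch
            since_best = 0
            if config.restore_best:
                best_weights = model.net.get_weights()
        else:
            since_best += 1
        if since_best >= config.patience:
            break

    history.stopped_epoch = len(history.val_mse)
    history.best_epoch = best_epoch
    history.wall_seconds = time.perf_counter() - t0
    if config.restore_best:
        model.net.set_weights(best_weights)
    model.trained = True
    return history


def predict(model: CountRegressor, bank: Bank) -> np.ndarray:
    """Per-image count predictions, order-aligned with the bank; all >= 0."""
    if not model.trained:
        raise ValidationError("model has not been trained")
    x, _ = _bank_to_arrays(bank, model.spec.input_size)
    return model.forward_counts(x)
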