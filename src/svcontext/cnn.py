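"""Residual convolutional network for breakpoint-probability prediction.

The network maps a one-hot encoded context window (4 channels x L bp) to a
single probability that the central position is a structural-variant
breakpoint:

    1x1 conv (4 -> stem) + BatchNorm + ReLU
    n residual blocks: [conv k/p, BatchNorm, ReLU, conv k/p, skip add, ReLU]
    1x1 conv (stem -> bottleneck)
    flatten (L * bottleneck units)
    linear (hidden units) + ReLU
    linear (1) + sigmoid

Training uses binary cross-entropy, AdamW, a reduce-on-plateau learning-rate
schedule and early stopping, returning the weights from the epoch with the
lowest validation loss.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._nn import AdamW, BatchNorm1d, Conv1d, Linear, bce_with_logits, sigmoid

__all__ = ["CNNSpec", "TrainConfig", "ResidualCNN", "build_cnn", "train_cnn"]


@dataclass(frozen=True)
class CNNSpec:
    """Architecture hyperparameters.

    Defaults follow the reference configuration for 400 bp windows; the
    flattened dimension is always ``context_length * bottleneck_channels``
    (12,800 for the defaults).
    """

    context_length: int = 400
    stem_channels: int = 128
    n_residual_blocks: int = 2
    kernel_size: int = 11
    padding: int = 5
    bottleneck_channels: int = 32
    hidden_units: int = 128

    def __post_init__(self):
        if self.context_length < 2 or self.context_length % 2:
            raise ValueError("context_length must be a positive even number")
        if self.kernel_size - 2 * self.padding != 1:
            raise ValueError(
                "padding must preserve sequence length (kernel_size = 2*padding + 1)")
        for name in ("stem_channels", "n_residual_blocks", "bottleneck_channels",
                     "hidden_units"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")

    @property
    def flattened_dim(self) -> int:
        return self.context_length * self.bottleneck_channels


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation protocol.

    ``learning_rate`` and ``weight_decay`` default to the genome-scale
    reference settings; small fixtures typically need a larger learning
    rate (see docs/methods.md).
    """

    learning_rate: float = 5e-6
    weight_decay: float = 1e-3
    plateau_factor: float = 0.5
    plateau_patience: int = 3
    early_stop_patience: int = 5
    batch_size: int = 256
    max_epochs: int = 100
    improvement_threshold: float = 1e-5
    seed: int = 42

    def __post_init__(self):
        for name in ("learning_rate", "weight_decay", "plateau_factor",
                     "plateau_patience", "early_stop_patience", "batch_size",
                     "max_epochs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


class _ResidualBlock:
    def __init__(self, channels, kernel_size, padding, rng):
        self.conv1 = Conv1d(channels, channels, kernel_size, padding, rng)
        self.bn = BatchNorm1d(channels)
        self.conv2 = Conv1d(channels, channels, kernel_size, padding, rng)
        self._mask1 = None
        self._mask2 = None

    def layers(self):
        return [self.conv1, self.bn, self.conv2]

    def forward(self, x, train=False):
        h = self.conv1.forward(x, train)
        h = self.bn.forward(h, train)
        m1 = h > 0
        h = h * m1
        h = self.conv2.forward(h, train)
        out = h + x
        m2 = out > 0
        if train:
            self._mask1, self._mask2 = m1, m2
        return out * m2

    def backward(self, dout):
        d = dout * self._mask2
        dskip = d
        d = self.conv2.backward(d)
        d = d * self._mask1
        d = self.bn.backward(d)
        d = self.conv1.backward(d)
        self._mask1 = self._mask2 = None
        return d + dskip


class ResidualCNN:
    """The sequence model; call :meth:`predict_proba` on one-hot batches."""

    def __init__(self, spec: CNNSpec, seed: int = 42):
        self.spec = spec
        rng = np.random.default_rng(seed)
        s = spec
        self.stem = Conv1d(4, s.stem_channels, 1, 0, rng)
        self.stem_bn = BatchNorm1d(s.stem_channels)
        self.blocks = [
            _ResidualBlock(s.stem_channels, s.kernel_size, s.padding, rng)
            for _ in range(s.n_residual_blocks)
        ]
        self.reduce = Conv1d(s.stem_channels, s.bottleneck_channels, 1, 0, rng)
        self.fc1 = Linear(s.flattened_dim, s.hidden_units, rng)
        self.fc2 = Linear(s.hidden_units, 1, rng)
        self._cache = None

    # -- plumbing -----------------------------------------------------
    def _layers(self):
        layers = [self.stem, self.stem_bn]
        for b in self.blocks:
            layers.extend(b.layers())
        layers.extend([self.reduce, self.fc1, self.fc2])
        return layers

    def state_dict(self):
        state = {}
        for i, layer in enumerate(self._layers()):
            for name, value, _ in layer.params():
                state[f"{i}.{name}"] = value.copy()
            if isinstance(layer, BatchNorm1d):
                state[f"{i}.running_mean"] = layer.running_mean.copy()
                state[f"{i}.running_var"] = layer.running_var.copy()
        return state

    def load_state_dict(self, state):
        for i, layer in enumerate(self._layers()):
            for name, value, _ in layer.params():
                value[...] = state[f"{i}.{name}"]
            if isinstance(layer, BatchNorm1d):
                layer.running_mean = state[f"{i}.running_mean"].copy()
                layer.running_var = state[f"{i}.running_var"].copy()

    # -- forward / backward -------------------------------------------
    def forward_logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.ndim != 3 or x.shape[1] != 4 or x.shape[2] != self.spec.context_length:
            raise ValueError(
                f"expected input of shape (N, 4, {self.spec.context_length}), "
                f"got {x.shape}")
        x = np.ascontiguousarray(x, dtype=np.float32)
        h = self.stem.forward(x, train)
        h = self.stem_bn.forward(h, train)
        m0 = h > 0
        h = h * m0
        for b in self.blocks:
            h = b.forward(h, train)
        h = self.reduce.forward(h, train)
        shape_conv = h.shape
        h = h.reshape(h.shape[0], -1)
        h = self.fc1.forward(h, train)
        m1 = h > 0
        h = h * m1
        z = self.fc2.forward(h, train)
        if train:
            self._cache = (m0, m1, shape_conv)
        return z[:, 0]

    def backward(self, dlogits: np.ndarray) -> None:
        m0, m1, shape_conv = self._cache
        d = self.fc2.backward(dlogits[:, None])
        d = d * m1
        d = self.fc1.backward(d)
        d = self.reduce.backward(d.reshape(shape_conv))
        for b in reversed(self.blocks):
            d = b.backward(d)
        d = d * m0
        d = self.stem_bn.backward(d)
        self.stem.backward(d)
        self._cache = None

    def predict_proba(self, x: np.ndarray, batch_size: int = 512) -> np.ndarray:
        """Probabilities in (0, 1) using running batch-norm statistics."""
        out = np.empty(x.shape[0], dtype=np.float64)
        for i in range(0, x.shape[0], batch_size):
            out[i:i + batch_size] = sigmoid(self.forward_logits(x[i:i + batch_size]))
        return np.clip(out, 1e-12, 1.0 - 1e-12)


def build_cnn(spec: CNNSpec, seed: int = 42) -> ResidualCNN:
    return ResidualCNN(spec, seed=seed)


def train_cnn(model: ResidualCNN,
              x_train: np.ndarray, y_train: np.ndarray,
              x_val: np.ndarray, y_val: np.ndarray,
              config: TrainConfig = TrainConfig()) -> dict:
    """Fit ``model`` in place; returns the training history.

    The returned history has per-epoch ``train_loss``, ``val_loss`` and
    ``lr`` lists plus ``best_epoch``; the model is left holding the weights
    of the epoch with minimum validation loss.
    """
    if len(x_train) == 0 or len(x_val) == 0:
        raise ValueError("train and validation sets must be non-empty")
    rng = np.random.default_rng(config.seed)
    opt = AdamW(model._layers(), lr=config.learning_rate,
                weight_decay=config.weight_decay)
    history = {"train_loss": [], "val_loss": [], "lr": [], "best_epoch": -1}
    best_val = np.inf
    best_state = None
    epochs_since_improve = 0
    plateau_count = 0
    y_train = np.asarray(y_train, dtype=np.float32)
    for epoch in range(config.max_epochs):
        order = rng.permutation(len(x_train))
        epoch_loss = 0.0
        for i in range(0, len(order), config.batch_size):
            idx = order[i:i + config.batch_size]
            logits = model.forward_logits(x_train[idx], train=True)
            loss, dlogits = bce_with_logits(logits, y_train[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}")
            model.backward(dlogits)
            opt.step()
            epoch_loss += loss * len(idx)
        val_loss = _dataset_loss(model, x_val, y_val, config.batch_size)
        history["train_loss"].append(epoch_loss / len(order))
        history["val_loss"].append(val_loss)
        history["lr"].append(opt.lr)
        if val_loss < best_val - config.improvement_threshold:
            best_val = val_loss
            best_state = model.state_dict()
            history["best_epoch"] = epoch
            epochs_since_improve = 0
            plateau_count = 0
        else:
            epochs_since_improve += 1
            plateau_count += 1
            if plateau_count >= config.plateau_patience:
                opt.lr *= config.plateau_factor
                plateau_count = 0
            if epochs_since_improve >= config.early_stop_patience:
                break
    if best_state is not None:
        model.load_state_dict(best_state)
    return history


def save_cnn(path, model: ResidualCNN) -> None:
    """Checkpoint weights (npz) with a JSON architecture sidecar."""
    import json
    from dataclasses import asdict
    from pathlib import Path
    path = Path(path)
    np.savez(path.with_suffix(".npz"), **model.state_dict())
    path.with_suffix(".json").write_text(json.dumps(asdict(model.spec)))


def load_cnn(path) -> ResidualCNN:
    import json
    from pathlib import Path
    path = Path(path)
    spec = CNNSpec(**json.loads(path.with_suffix(".json").read_text()))
    model = ResidualCNN(spec)
    with np.load(path.with_suffix(".npz")) as data:
        model.load_state_dict({k: data[k] for k in data.files})
    return model


def _dataset_loss(model, x, y, batch_size):
    total = 0.0
    for i in range(0, len(x), batch_size):
        logits = model.forward_logits(x[i:i + batch_size])
        loss, _ = bce_with_logits(logits, np.asarray(y[i:i + batch_size]))
        total += loss * len(logits)
    return total / len(x)
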