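"""A small convolutional classifier for scalogram images, in pure numpy.

Architecture (fixed):

    input 28 x 28 x 3
    conv 3x3, 8 filters, pad 1   + ReLU
    maxpool 2x2, stride 2                -> 14 x 14 x 8
    conv 3x3, 16 filters, pad 1  + ReLU
    maxpool 2x2, stride 2                -> 7 x 7 x 16
    conv 3x3, 32 filters, pad 1  + ReLU  -> 7 x 7 x 32
    fully connected (n_classes)
    softmax

Training is minibatch gradient descent with one of three optimizers
(SGD with momentum 0.9; RMSProp with squared-gradient decay 0.9; Adam
with beta1 0.9, beta2 0.999), categorical cross-entropy loss, and
Glorot-uniform initialization. The final fully connected layer's
learning rate can be scaled by a multiplier, a common fine-tuning knob.
Everything is seeded and single-threaded deterministic.

The module also exposes a registry of backbone adapters so externally
supplied models (with their own forward/backward) can be trained and
evaluated through the same harness; only the small CNN ships here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = [
    "SimpleCnn", "TrainConfig", "FitResult", "ConfigurationError",
    "build_simple_cnn", "split_train_validation", "train", "predict",
    "load_backbone", "register_backbone", "save_model", "load_model",
    "SIMPLE_CNN_LAYERS",
]

#: Layer-by-layer description of the fixed architecture:
#: (kind, kernel/pool size, filters, padding/stride).
SIMPLE_CNN_LAYERS = (
    ("input", (28, 28, 3)),
    ("conv", 3, 8, 1),
    ("maxpool", 2, 2),
    ("conv", 3, 16, 1),
    ("maxpool", 2, 2),
    ("conv", 3, 32, 1),
    ("fc", "n_classes"),
    ("softmax",),
)


class ConfigurationError(ValueError):
    """Unknown backbone name or malformed configuration."""


# ---------------------------------------------------------------------------
# layers


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int,
            shape: tuple[int, ...]) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """(N,H,W,C) -> (N,H,W, k*k*C) patch matrix for a stride-1 conv."""
    n, h, w, c = x.shape
    xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
    cols = np.empty((n, h, w, k * k * c), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            cols[..., (i * k + j) * c:(i * k + j + 1) * c] = \
                xp[:, i:i + h, j:j + w, :]
    return cols


class _Conv:
    """3x3 same-padding convolution with ReLU activation."""

    def __init__(self, rng: np.random.Generator, c_in: int, c_out: int,
                 k: int = 3, pad: int = 1):
        self.k, self.pad = k, pad
        fan_in, fan_out = k * k * c_in, k * k * c_out
        self.w = _glorot(rng, fan_in, fan_out, (k * k * c_in, c_out))
        self.b = np.zeros(c_out)
        self.lr_mult = 1.0

    def forward(self, x: np.ndarray, *, train: bool = False) -> np.ndarray:
        cols = _im2col(x, self.k, self.pad)
        z = cols @ self.w + self.b
        out = np.maximum(z, 0.0)
        if train:
            self._cols, self._mask, self._in_shape = cols, z > 0, x.shape
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        grad = grad * self._mask
        n, h, w, _ = grad.shape
        g2 = grad.reshape(-1, grad.shape[-1])
        self.gw = self._cols.reshape(-1, self._cols.shape[-1]).T @ g2
        self.gb = g2.sum(axis=0)
        gcols = (g2 @ self.w.T).reshape(self._cols.shape)
        # scatter column gradients back to the padded input
        k, pad = self.k, self.pad
        c_in = self._in_shape[-1]
        gxp = np.zeros((n, h + 2 * pad, w + 2 * pad, c_in))
        for i in range(k):
            for j in range(k):
                gxp[:, i:i + h, j:j + w, :] += \
                    gcols[..., (i * k + j) * c_in:(i * k + j + 1) * c_in]
        return gxp[:, pad:pad + h, pad:pad + w, :]

    def params(self):
        return [("w", self), ("b", self)]


class _MaxPool:
    """2x2 max pooling with stride 2."""

    def forward(self, x: np.ndarray, *, train: bool = False) -> np.ndarray:
        n, h, w, c = x.shape
        xr = x.reshape(n, h // 2, 2, w // 2, 2, c)
        out = xr.max(axis=(2, 4))
        if train:
            self._mask = (xr == out[:, :, None, :, None, :])
            self._shape = x.shape
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, h, w, c = self._shape
        g = self._mask * grad[:, :, None, :, None, :]
        # a window with tied maxima splits the gradient between them
        g = g / self._mask.sum(axis=(2, 4), keepdims=True)
        return g.reshape(n, h, w, c)

    def params(self):
        return []


class _Dense:
    """Flatten + fully connected layer (logits, no activation)."""

    def __init__(self, rng: np.random.Generator, n_in: int, n_out: int):
        self.w = _glorot(rng, n_in, n_out, (n_in, n_out))
        self.b = np.zeros(n_out)
        self.lr_mult = 1.0

    def forward(self, x: np.ndarray, *, train: bool = False) -> np.ndarray:
        flat = x.reshape(x.shape[0], -1)
        if train:
            self._flat, self._in_shape = flat, x.shape
        return flat @ self.w + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.gw = self._flat.T @ grad
        self.gb = grad.sum(axis=0)
        return (grad @ self.w.T).reshape(self._in_shape)

    def params(self):
        return [("w", self), ("b", self)]


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# model


class SimpleCnn:
    """The fixed three-conv classifier; see module docstring."""

    input_shape = (28, 28, 3)

    def __init__(self, n_classes: int, seed: int = 0):
        if n_classes < 2:
            raise ValueError(f"n_classes must be >= 2, got {n_classes}")
        rng = np.random.default_rng(seed)
        self.n_classes = int(n_classes)
        self.conv1 = _Conv(rng, 3, 8)
        self.pool1 = _MaxPool()
        self.conv2 = _Conv(rng, 8, 16)
        self.pool2 = _MaxPool()
        self.conv3 = _Conv(rng, 16, 32)
        self.fc = _Dense(rng, 7 * 7 * 32, n_classes)
        self.layers = [self.conv1, self.pool1, self.conv2, self.pool2,
                       self.conv3, self.fc]
        self.layer_spec = SIMPLE_CNN_LAYERS

    def set_last_layer_lr_multiplier(self, mult: float) -> None:
        self.fc.lr_mult = float(mult)

    def forward(self, x: np.ndarray, *, train: bool = False) -> np.ndarray:
        """Return class logits for a (N, 28, 28, 3) batch."""
        x = np.asarray(x, dtype=np.float64)
        if x.ndim != 4 or x.shape[1:] != self.input_shape:
            raise ValueError(
                f"expected (N, 28, 28, 3) input, got {x.shape}")
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad: np.ndarray) -> None:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    def parameters(self):
        """Yield (layer, attr_name, lr_mult) for every trainable tensor."""
        for layer in self.layers:
            for name, owner in layer.params():
                yield owner, name, owner.lr_mult

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {"n_classes": np.array(self.n_classes)}
        for i, layer in enumerate(self.layers):
            for name, owner in layer.params():
                out[f"layer{i}.{name}"] = getattr(owner, name)
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            for name, owner in layer.params():
                val = np.asarray(state[f"layer{i}.{name}"])
                if val.shape != getattr(owner, name).shape:
                    raise ConfigurationError(
                        f"shape mismatch for layer{i}.{name}")
                setattr(owner, name, val.copy())


def build_simple_cnn(n_classes: int, seed: int = 0) -> SimpleCnn:
    """Construct the fixed small CNN with Glorot-uniform init."""
    return SimpleCnn(n_classes, seed=seed)


# ---------------------------------------------------------------------------
# optimizers


class _Optimizer:
    def __init__(self, model: SimpleCnn, lr: float):
        self.model, self.lr = model, lr
        self.state: dict[int, dict[str, np.ndarray]] = {}
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for owner, name, mult in self.model.parameters():
            w = getattr(owner, name)
            g = getattr(owner, "g" + name)
            key = (id(owner), name)
            slot = self.state.setdefault(key, self._init_slot(w))
            delta = self._delta(slot, g, self.lr * mult)
            setattr(owner, name, w - delta)

    def _init_slot(self, w):  # pragma: no cover - overridden
        raise NotImplementedError

    def _delta(self, slot, g, lr):  # pragma: no cover - overridden
        raise NotImplementedError


class _Sgdm(_Optimizer):
    momentum = 0.9

    def _init_slot(self, w):
        return {"v": np.zeros_like(w)}

    def _delta(self, slot, g, lr):
        slot["v"] = self.momentum * slot["v"] + g
        return lr * slot["v"]


class _RmsProp(_Optimizer):
    rho, eps = 0.9, 1e-8

    def _init_slot(self, w):
        return {"s": np.zeros_like(w)}

    def _delta(self, slot, g, lr):
        slot["s"] = self.rho * slot["s"] + (1 - self.rho) * g * g
        return lr * g / (np.sqrt(slot["s"]) + self.eps)


class _Adam(_Optimizer):
    b1, b2, eps = 0.9, 0.999, 1e-8

    def _init_slot(self, w):
        return {"m": np.zeros_like(w), "v": np.zeros_like(w)}

    def _delta(self, slot, g, lr):
        slot["m"] = self.b1 * slot["m"] + (1 - self.b1) * g
        slot["v"] = self.b2 * slot["v"] + (1 - self.b2) * g * g
        mhat = slot["m"] / (1 - self.b1 ** self.t)
        vhat = slot["v"] / (1 - self.b2 ** self.t)
        return lr * mhat / (np.sqrt(vhat) + self.eps)


_OPTIMIZERS = {"sgdm": _Sgdm, "rmsprop": _RmsProp, "adam": _Adam}


# ---------------------------------------------------------------------------
# training harness


@dataclass
class TrainConfig:
    """Training hyperparameters.

    ``train_val_ratio`` is the percentage split of the training portion
    into training and validation parts (e.g. (90, 10)); parts must be
    positive and sum to 100. ``last_layer_lr_multiplier`` scales the
    learning rate of the final fully connected layer's weight and bias.
    """

    method: str = "adam"
    initial_lr: float = 1e-4
    minibatch: int = 10
    epochs: int = 10
    last_layer_lr_multiplier: float = 1.0
    train_val_ratio: tuple[int, int] = (90, 10)
    seed: int = 0

    def __post_init__(self) -> None:
        self.method = self.method.lower()
        if self.method not in _OPTIMIZERS:
            raise ValueError(
                f"method must be one of {sorted(_OPTIMIZERS)}, "
                f"got {self.method!r}")
        if not (self.initial_lr > 0):
            raise ValueError("initial_lr must be > 0")
        if self.minibatch < 1:
            raise ValueError("minibatch must be >= 1")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.last_layer_lr_multiplier < 0:
            raise ValueError("last_layer_lr_multiplier must be >= 0")
        a, b = self.train_val_ratio
        if a <= 0 or b <= 0 or a + b != 100:
            raise ValueError("ratio parts must be positive and sum to 100")


@dataclass
class FitResult:
    """Trained model plus per-epoch history."""

    model: SimpleCnn
    history: list[dict] = field(default_factory=list)
    validation_accuracy: float = float("nan")
    test_accuracy: float = float("nan")


def split_train_validation(labels: np.ndarray, ratio: tuple[int, int],
                           seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Stratified index split at a percentage ratio, seeded.

    Per class the items are shuffled, the training part receives
    ``floor(n * ratio/100)`` items and the validation part the
    remainder. Returns (train_indices, validation_indices); the two are
    disjoint and together cover every index.
    """
    labels = np.asarray(labels)
    a, b = ratio
    if a <= 0 or b <= 0 or a + b != 100:
        raise ValueError("ratio parts must be positive and sum to 100")
    rng = np.random.default_rng(seed)
    train_idx: list[np.ndarray] = []
    val_idx: list[np.ndarray] = []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if idx.size < 2:
            raise ValueError(
                f"class {cls!r} has {idx.size} item(s); need >= 2")
        idx = rng.permutation(idx)
        n_train = int(np.floor(idx.size * a / 100.0))
        n_train = min(max(n_train, 1), idx.size - 1)
        train_idx.append(idx[:n_train])
        val_idx.append(idx[n_train:])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(val_idx))


def _loss_and_grad(model: SimpleCnn, x: np.ndarray, y: np.ndarray):
    logits = model.forward(x, train=True)
    probs = _softmax(logits)
    n = x.shape[0]
    eps = 1e-12
    loss = -np.log(probs[np.arange(n), y] + eps).mean()
    grad = probs.copy()
    grad[np.arange(n), y] -= 1.0
    return loss, grad / n, probs


def train(model: SimpleCnn, x_train: np.ndarray, y_train: np.ndarray,
          config: TrainConfig,
          x_val: np.ndarray | None = None,
          y_val: np.ndarray | None = None) -> FitResult:
    """Minibatch training with the configured optimizer.

    Runs exactly ``config.epochs`` passes over the training set with
    seeded shuffling; records loss, training accuracy and (when a
    validation set is given) validation accuracy per epoch.
    """
    x_train = np.asarray(x_train, dtype=np.float64)
    y_train = np.asarray(y_train, dtype=np.intp)
    if x_train.shape[0] == 0:
        raise ValueError("training set is empty")
    if x_train.shape[0] != y_train.shape[0]:
        raise ValueError("images and labels disagree in length")
    if y_train.max() >= model.n_classes:
        raise ValueError("label outside model's class range")

    model.set_last_layer_lr_multiplier(config.last_layer_lr_multiplier)
    opt = _OPTIMIZERS[config.method](model, config.initial_lr)
    rng = np.random.default_rng(config.seed)
    result = FitResult(model=model)
    n = x_train.shape[0]
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.minibatch):
            sel = order[start:start + config.minibatch]
            loss, grad, _ = _loss_and_grad(model, x_train[sel], y_train[sel])
            model.backward(grad)
            opt.step()
            losses.append(loss)
        _, train_labels = predict(model, x_train)
        row = {
            "epoch": epoch + 1,
            "loss": float(np.mean(losses)),
            "train_acc": float(np.mean(train_labels == y_train)),
        }
        if x_val is not None and len(x_val):
            _, val_labels = predict(model, x_val)
            row["val_acc"] = float(np.mean(val_labels == np.asarray(y_val)))
            result.validation_accuracy = row["val_acc"]
        result.history.append(row)
    return result


def predict(model: SimpleCnn, images: np.ndarray,
            batch: int = 256) -> tuple[np.ndarray, np.ndarray]:
    """Softmax score matrix and argmax labels (lowest index wins ties)."""
    images = np.asarray(images, dtype=np.float64)
    if images.ndim == 3:
        images = images[None]
    probs = np.vstack([
        _softmax(model.forward(images[i:i + batch]))
        for i in range(0, images.shape[0], batch)
    ])
    return probs, probs.argmax(axis=1)


# ---------------------------------------------------------------------------
# backbone registry


_BACKBONES: dict[str, Callable[..., SimpleCnn]] = {}


def register_backbone(name: str, factory: Callable[..., SimpleCnn]) -> None:
    """Register an adapter that builds a trainable model for ``name``.

    The factory must accept ``n_classes`` and ``seed`` keyword arguments
    and return an object with the SimpleCnn training interface
    (forward/backward/parameters/set_last_layer_lr_multiplier).
    """
    _BACKBONES[name] = factory


def load_backbone(name: str, n_classes: int, weights=None,
                  seed: int = 0):
    """Instantiate a registered backbone, optionally warm-started.

    ``weights=None`` means train-from-scratch semantics (random init).
    When a state-dict path or mapping is supplied, matching tensors are
    loaded before the final layer is (re)sized to ``n_classes``.
    """
    if name not in _BACKBONES:
        raise ConfigurationError(
            f"unknown backbone {name!r}; registered: {sorted(_BACKBONES)}")
    model = _BACKBONES[name](n_classes=n_classes, seed=seed)
    if weights is not None:
        state = weights if isinstance(weights, dict) else dict(
            np.load(weights, allow_pickle=False))
        try:
            model.load_state_dict(state)
        except KeyError as exc:
            raise ConfigurationError(f"malformed weights: {exc}") from exc
    return model


register_backbone("simple_cnn", lambda n_classes, seed=0:
                  build_simple_cnn(n_classes, seed=seed))


def save_model(model: SimpleCnn, path) -> None:
    """Serialize model weights to a portable .npz container."""
    np.savez(path, **model.state_dict())


def load_model(path, n_classes: int | None = None) -> SimpleCnn:
    state = dict(np.load(path, allow_pickle=False))
    n = int(state["n_classes"]) if n_classes is None else n_classes
    model = build_simple_cnn(n)
    model.load_state_dict(state)
    return model
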