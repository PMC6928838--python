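"""The eight-class patch classifier: a small CNN feature extractor plus an
MLP head, implemented directly on numpy.

Architecture (configurable): three convolution blocks (3x3 valid
convolutions with 32/64/128 filters, ReLU, 2x2 max-pooling), flatten, a
fully-connected 128-unit ReLU layer, and a fully-connected output layer
with identity (linear) transfer — class probabilities are obtained by
applying softmax at prediction time, and training folds the softmax into
the cross-entropy loss. Optimisation is Adam on mini-batches; pixel inputs
are scaled to [0, 1]; no regularisation or augmentation is applied.

Everything is deterministic for a given seed: initialisation, batch
shuffling, and hence the trained parameters.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from PIL import Image

from .geotile import Tile
from .taxonomy import CLASS_ORDER, Manifest

__all__ = [
    "TrainingConfig",
    "PatchClassifier",
    "DataError",
    "TrainingError",
    "build_model",
    "train",
    "retrain",
    "predict",
    "load_manifest_arrays",
    "save_checkpoint",
    "load_checkpoint",
]


class DataError(RuntimeError):
    """Unreadable tile file or a label outside the taxonomy."""


class TrainingError(RuntimeError):
    """Optimisation failure (e.g. non-finite loss)."""


@dataclasses.dataclass
class TrainingConfig:
    """Training profile. The defaults are the shipped profile: batch 20,
    200 iterations (read as epochs), ReLU, cross-entropy, Adam, no
    regularisation, learning rate 1e-2, max pooling, linear output
    transfer.

    ``max_steps`` caps the total number of optimiser steps for the literal
    "200 iterations = 200 optimiser steps" reading; ``None`` means epochs
    govern. Note that Adam at 1e-2 can be unstable for convolutional nets;
    1e-3 is a robust choice on the synthetic scenes.
    """

    batch_size: int = 20
    epochs: int = 200
    learning_rate: float = 1e-2
    optimizer: str = "adam"
    loss: str = "cross_entropy"
    activation: str = "relu"
    regularization: str = "none"
    pooling: str = "max"
    output_transfer: str = "linear"
    seed: int = 0
    max_steps: int | None = None
    class_weighting: bool = False
    conv_filters: tuple[int, ...] = (32, 64, 128)
    kernel_size: int = 3
    hidden_units: int = 128

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be non-negative")
        if self.optimizer != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")
        if self.loss != "cross_entropy":
            raise ValueError(f"unsupported loss {self.loss!r}")
        self.conv_filters = tuple(int(f) for f in self.conv_filters)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["conv_filters"] = list(data["conv_filters"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TrainingConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)


# ---------------------------------------------------------------------------
# layers


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """Extract all k x k patches of an NHWC batch as a matrix of rows."""
    n, h, w, c = x.shape
    oh, ow = h - k + 1, w - k + 1
    s = x.strides
    cols = np.lib.stride_tricks.as_strided(
        x, (n, oh, ow, k, k, c), (s[0], s[1], s[2], s[1], s[2], s[3])
    )
    return np.ascontiguousarray(cols).reshape(n, oh, ow, k * k * c)


class _Conv:
    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        fan_in = k * k * c_in
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (fan_in, c_out))
        self.b = np.zeros(c_out)
        self.k = k

    def forward(self, x: np.ndarray, keep: bool) -> np.ndarray:
        cols = _im2col(x, self.k)
        if keep:
            self._cols, self._x_shape = cols, x.shape
        return cols @ self.w + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, oh, ow, f = dy.shape
        k = self.k
        cols2d = self._cols.reshape(-1, self.w.shape[0])
        dy2d = dy.reshape(-1, f)
        self.dw = cols2d.T @ dy2d
        self.db = dy2d.sum(axis=0)
        dcols = (dy2d @ self.w.T).reshape(n, oh, ow, k, k, -1)
        dx = np.zeros(self._x_shape)
        for i in range(k):
            for j in range(k):
                dx[:, i : i + oh, j : j + ow, :] += dcols[:, :, :, i, j, :]
        return dx

    params = ("w", "b")


class _ReLU:
    params = ()

    def forward(self, x: np.ndarray, keep: bool) -> np.ndarray:
        if keep:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class _MaxPool:
    """2x2 max pooling, stride 2; trailing odd rows/columns are dropped."""

    params = ()

    def forward(self, x: np.ndarray, keep: bool) -> np.ndarray:
        n, h, w, c = x.shape
        h2, w2 = h // 2, w // 2
        xv = x[:, : h2 * 2, : w2 * 2, :]
        windows = (
            xv.reshape(n, h2, 2, w2, 2, c).transpose(0, 1, 3, 5, 2, 4).reshape(n, h2, w2, c, 4)
        )
        idx = windows.argmax(axis=-1)
        out = np.take_along_axis(windows, idx[..., None], axis=-1)[..., 0]
        if keep:
            self._idx, self._x_shape = idx, x.shape
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, c = self._x_shape
        h2, w2 = h // 2, w // 2
        dwin = np.zeros((n, h2, w2, c, 4))
        np.put_along_axis(dwin, self._idx[..., None], dy[..., None], axis=-1)
        dx = np.zeros(self._x_shape)
        dx[:, : h2 * 2, : w2 * 2, :] = (
            dwin.reshape(n, h2, w2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3).reshape(n, h2 * 2, w2 * 2, c)
        )
        return dx


class _Flatten:
    params = ()

    def forward(self, x: np.ndarray, keep: bool) -> np.ndarray:
        if keep:
            self._x_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._x_shape)


class _Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.w = rng.normal(0.0, np.sqrt(2.0 / n_in), (n_in, n_out))
        self.b = np.zeros(n_out)

    def forward(self, x: np.ndarray, keep: bool) -> np.ndarray:
        if keep:
            self._x = x
        return x @ self.w + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.dw = self._x.T @ dy
        self.db = dy.sum(axis=0)
        return dy @ self.w.T

    params = ("w", "b")


def softmax(logits: np.ndarray) -> np.ndarray:
    """Row-wise softmax, numerically stabilised."""
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# classifier


class PatchClassifier:
    """CNN + MLP classifier over square RGB patches.

    ``forward`` produces raw 8-vector logits (linear output transfer);
    ``predict_proba`` applies softmax.
    """

    def __init__(self, layers: list, tile_size: int, class_order: Sequence[str],
                 architecture: list[str]):
        self.layers = layers
        self.tile_size = int(tile_size)
        self.class_order = tuple(class_order)
        self.architecture = list(architecture)

    @property
    def n_classes(self) -> int:
        return len(self.class_order)

    def forward(self, x: np.ndarray, keep: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, keep)
        return x

    def backward(self, dlogits: np.ndarray) -> None:
        g = dlogits
        for layer in reversed(self.layers):
            g = layer.backward(g)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.forward(x))

    def parameters(self) -> list[tuple[object, str]]:
        return [(layer, name) for layer in self.layers for name in layer.params]

    def get_weights(self) -> list[np.ndarray]:
        return [getattr(layer, name).copy() for layer, name in self.parameters()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        pairs = self.parameters()
        if len(weights) != len(pairs):
            raise ValueError("weight list does not match architecture")
        for (layer, name), w in zip(pairs, weights):
            if getattr(layer, name).shape != w.shape:
                raise ValueError("weight shape mismatch")
            setattr(layer, name, w.copy())


def build_model(
    config: TrainingConfig, tile_size: int, n_classes: int = len(CLASS_ORDER),
    class_order: Sequence[str] = CLASS_ORDER,
) -> PatchClassifier:
    """Construct and deterministically initialise the classifier.

    He-normal initialisation from ``config.seed``. Raises if the tile is too
    small for the stack of valid convolutions and poolings.
    """
    if tile_size < 16:
        raise ValueError("tile_size must be >= 16")
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    if len(class_order) != n_classes:
        raise ValueError("class_order length must equal n_classes")
    rng = np.random.default_rng(np.random.SeedSequence([abs(int(config.seed)), 3]))
    layers: list = []
    arch: list[str] = []
    c_in, side = 3, tile_size
    for f in config.conv_filters:
        side_after = (side - config.kernel_size + 1) // 2
        if side_after < 1:
            raise ValueError(
                f"tile_size {tile_size} too small for {len(config.conv_filters)} conv blocks"
            )
        layers += [_Conv(c_in, f, config.kernel_size, rng), _ReLU(), _MaxPool()]
        arch.append(f"conv{config.kernel_size}x{config.kernel_size}({c_in}->{f})+relu+maxpool2")
        c_in, side = f, side_after
    layers.append(_Flatten())
    flat = side * side * c_in
    arch.append(f"flatten({flat})")
    layers += [_Dense(flat, config.hidden_units, rng), _ReLU()]
    arch.append(f"dense({flat}->{config.hidden_units})+relu")
    layers.append(_Dense(config.hidden_units, n_classes, rng))
    arch.append(f"dense({config.hidden_units}->{n_classes})+linear")
    return PatchClassifier(layers, tile_size, class_order, arch)


# ---------------------------------------------------------------------------
# data loading


def load_manifest_arrays(
    manifest: Manifest, class_order: Sequence[str] = CLASS_ORDER
) -> tuple[np.ndarray, np.ndarray]:
    """Load a manifest's tile files into (X in [0,1] NHWC float64, y int)."""
    if len(manifest) == 0:
        raise DataError("empty manifest")
    index = {c: i for i, c in enumerate(class_order)}
    xs, ys = [], []
    for rec in manifest.frame.itertuples():
        if rec.class_code not in index:
            raise DataError(f"label {rec.class_code!r} outside the class order")
        try:
            with Image.open(rec.tile_path) as img:
                xs.append(np.asarray(img.convert("RGB"), dtype=np.float64) / 255.0)
        except (OSError, ValueError) as exc:
            raise DataError(f"unreadable tile {rec.tile_path}: {exc}") from exc
        ys.append(index[rec.class_code])
    shapes = {a.shape for a in xs}
    if len(shapes) > 1:
        raise DataError(f"tiles have inconsistent shapes: {sorted(shapes)}")
    return np.stack(xs), np.array(ys, dtype=np.int64)


# ---------------------------------------------------------------------------
# training


class _Adam:
    def __init__(self, params: list[tuple[object, str]], lr: float):
        self.params = params
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.m = [np.zeros_like(getattr(l, n)) for l, n in params]
        self.v = [np.zeros_like(getattr(l, n)) for l, n in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for i, (layer, name) in enumerate(self.params):
            g = getattr(layer, "d" + name)
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p = getattr(layer, name)
            setattr(layer, name, p - self.lr * mhat / (np.sqrt(vhat) + self.eps))


def _xent_and_grad(
    logits: np.ndarray, y: np.ndarray, weights: np.ndarray | None
) -> tuple[float, np.ndarray, int]:
    probs = softmax(logits)
    n = len(y)
    w = weights[y] if weights is not None else np.ones(n)
    eps = 1e-12
    loss = float(-(w * np.log(probs[np.arange(n), y] + eps)).sum() / w.sum())
    grad = probs * w[:, None]
    grad[np.arange(n), y] -= w
    grad /= w.sum()
    correct = int((logits.argmax(axis=1) == y).sum())
    return loss, grad, correct


def train(
    model: PatchClassifier,
    train_manifest: Manifest,
    config: TrainingConfig,
) -> tuple[PatchClassifier, list[dict]]:
    """Train in place with mini-batch Adam on softmax cross-entropy.

    Returns the model and a history with one record per epoch:
    ``{"epoch", "loss", "accuracy"}`` (running means over the epoch's
    batches). Training starts from the model's current parameters, so
    calling this on an already-trained model continues its optimisation.

    Raises :class:`TrainingError` (naming the epoch) if the loss goes
    non-finite, and :class:`DataError` for unreadable tiles or labels
    outside the model's class order.
    """
    x, y = load_manifest_arrays(train_manifest, model.class_order)
    if x.shape[1] != model.tile_size or x.shape[2] != model.tile_size:
        raise DataError(
            f"tile size {x.shape[1]}x{x.shape[2]} does not match model input "
            f"{model.tile_size}x{model.tile_size}"
        )
    weights = None
    if config.class_weighting:
        counts = np.bincount(y, minlength=model.n_classes).astype(np.float64)
        weights = np.where(counts > 0, len(y) / (model.n_classes * np.maximum(counts, 1)), 0.0)

    rng = np.random.default_rng(np.random.SeedSequence([abs(int(config.seed)), 4]))
    opt = _Adam(model.parameters(), config.learning_rate)
    history: list[dict] = []
    steps = 0
    n = len(y)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss, epoch_correct, seen = 0.0, 0, 0
        for start in range(0, n, config.batch_size):
            if config.max_steps is not None and steps >= config.max_steps:
                break
            idx = order[start : start + config.batch_size]
            logits = model.forward(x[idx], keep=True)
            loss, grad, correct = _xent_and_grad(logits, y[idx], weights)
            if not np.isfinite(loss):
                raise TrainingError(f"non-finite training loss at epoch {epoch + 1}")
            model.backward(grad)
            opt.step()
            steps += 1
            epoch_loss += loss * len(idx)
            epoch_correct += correct
            seen += len(idx)
        if seen == 0:
            break
        history.append(
            {"epoch": epoch + 1, "loss": epoch_loss / seen, "accuracy": epoch_correct / seen}
        )
        if config.max_steps is not None and steps >= config.max_steps:
            break
    return model, history


def retrain(
    model: PatchClassifier, new_manifest: Manifest, config: TrainingConfig
) -> tuple[PatchClassifier, list[dict]]:
    """Continue training a fitted model on a new terrain's manifest.

    Warm start: the given model's parameters are the starting point (no
    reinitialisation); only the optimiser state is fresh.
    """
    return train(model, new_manifest, config)


def predict(
    model: PatchClassifier, tiles: Sequence, batch_size: int = 64
) -> list[tuple[str, np.ndarray]]:
    """Classify tiles; returns (class code, probability 8-vector) per tile.

    Accepts :class:`~greenmap.geotile.Tile` objects or raw HxWx3 arrays.
    Probabilities are the softmax of the logits; argmax ties resolve to the
    lowest class index in the canonical order.
    """
    arrays = []
    for t in tiles:
        px = t.pixels if isinstance(t, Tile) else np.asarray(t)
        if px.shape[:2] != (model.tile_size, model.tile_size):
            raise ValueError(
                f"tile shape {px.shape[:2]} does not match model input size {model.tile_size}"
            )
        arrays.append(px.astype(np.float64) / 255.0)
    out: list[tuple[str, np.ndarray]] = []
    for start in range(0, len(arrays), batch_size):
        probs = model.predict_proba(np.stack(arrays[start : start + batch_size]))
        for p in probs:
            out.append((model.class_order[int(p.argmax())], p))
    return out


# ---------------------------------------------------------------------------
# checkpoints


def save_checkpoint(model: PatchClassifier, path: str | Path,
                    config: TrainingConfig | None = None) -> None:
    """Save weights as ``.npz`` plus a JSON sidecar with class order, tile
    size, architecture and (optionally) the training config."""
    path = Path(path)
    arrays = {f"param_{i}": w for i, w in enumerate(model.get_weights())}
    np.savez(path.with_suffix(".npz"), **arrays)
    sidecar = {
        "tile_size": model.tile_size,
        "class_order": list(model.class_order),
        "architecture": model.architecture,
        "conv_filters": None,
        "config": None,
    }
    if config is not None:
        cfg = dataclasses.asdict(config)
        cfg["conv_filters"] = list(cfg["conv_filters"])
        sidecar["config"] = cfg
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(sidecar, fh, indent=2)


def load_checkpoint(path: str | Path) -> tuple[PatchClassifier, TrainingConfig]:
    """Rebuild a classifier from a checkpoint written by :func:`save_checkpoint`."""
    path = Path(path)
    with open(path.with_suffix(".json")) as fh:
        sidecar = json.load(fh)
    cfg_data = sidecar.get("config")
    config = TrainingConfig(**cfg_data) if cfg_data else TrainingConfig()
    model = build_model(
        config, sidecar["tile_size"], len(sidecar["class_order"]), sidecar["class_order"]
    )
    with np.load(path.with_suffix(".npz")) as npz:
        weights = [npz[f"param_{i}"] for i in range(len(npz.files))]
    model.set_weights(weights)
    return model, config
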