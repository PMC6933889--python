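"""The convolutional splice-site classifier.

Architecture (3-class by default):

    input (L, 4 one-hot channels)
    -> 1-D convolution, 50 kernels of size 9, stride 1, length-preserving
       zero padding, ReLU
    -> flatten
    -> fully connected, 100 units, ReLU
    -> dropout, rate 0.30 (training only)
    -> fully connected, n_classes units, softmax

Training uses softmax cross-entropy and Adam (learning rate 1e-4, 40
epochs, batch size 50 by default). The two binary site-vs-false-positive
filter variants use the same stack with a 2-unit output layer.

The network is implemented directly on NumPy: forward and backward passes
for the convolution are expressed as im2col matrix products, dropout is
inverted dropout, and initialization is Glorot uniform. A single integer
seed drives weight initialization, minibatch shuffling and dropout masks,
so training is bit-reproducible on a given platform.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .dataset import LABEL_ORDER, EncodedBatch, SpliceDataset, encode_batch
from .errors import ConfigError, ModelLoadError, ModelStateError, ShapeError

FORMAT_VERSION = 1


@dataclass(frozen=True)
class ModelSpec:
    L: int
    n_conv_layers: int = 1
    kernels: int = 50
    kernel_size: int = 9
    stride: int = 1
    fc_units: int = 100
    dropout_rate: float = 0.30
    n_classes: int = 3
    conv_activation: str = "relu"  # "relu" | "linear"

    def __post_init__(self):
        if self.L < 2:
            raise ConfigError("L must be >= 2")
        if self.kernel_size > self.L:
            raise ConfigError(
                f"kernel_size {self.kernel_size} exceeds input length {self.L}"
            )
        if not (0 <= self.dropout_rate < 1):
            raise ConfigError("dropout_rate must lie in [0, 1)")
        if self.stride < 1:
            raise ConfigError("stride must be >= 1")
        if self.n_conv_layers < 1:
            raise ConfigError("need at least one convolutional layer")
        if self.n_classes < 2:
            raise ConfigError("need at least two classes")
        if self.conv_activation not in ("relu", "linear"):
            raise ConfigError(f"unknown conv_activation {self.conv_activation!r}")

    @property
    def conv_out_len(self) -> int:
        """Feature-map length after the conv stack ('same' padding)."""
        out = self.L
        for _ in range(self.n_conv_layers):
            out = -(-out // self.stride)  # ceil
        return out


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-4
    epochs: int = 40
    batch_size: int = 50
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1:
            raise ConfigError("epochs and batch_size must be >= 1")


def count_parameters(spec: ModelSpec) -> int:
    """Closed-form trainable parameter count for a spec.

    Conv layer i: kernels * (kernel_size * in_channels + 1); FC1:
    (conv_out_len * kernels) * fc_units + fc_units; FC2:
    fc_units * n_classes + n_classes.
    """
    total = 0
    in_ch = 4
    for _ in range(spec.n_conv_layers):
        total += spec.kernels * (spec.kernel_size * in_ch + 1)
        in_ch = spec.kernels
    total += spec.conv_out_len * spec.kernels * spec.fc_units + spec.fc_units
    total += spec.fc_units * spec.n_classes + spec.n_classes
    return total


def _same_padding(length: int, kernel_size: int, stride: int) -> tuple[int, int]:
    out = -(-length // stride)
    pad = max((out - 1) * stride + kernel_size - length, 0)
    return pad // 2, pad - pad // 2


def dropout_mask(rng: np.random.Generator, shape, rate: float) -> np.ndarray:
    """Binary keep-mask for inverted dropout (1 = kept, 0 = masked)."""
    return (rng.random(shape) >= rate).astype(np.float32)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _glorot(rng: np.random.Generator, shape, fan_in: int, fan_out: int) -> np.ndarray:
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


class SpliceCNN:
    """A trainable handle: spec + weights + label order + history."""

    def __init__(
        self,
        spec: ModelSpec,
        label_order: Optional[Sequence[str]] = None,
    ):
        if label_order is None:
            if spec.n_classes == 3:
                label_order = LABEL_ORDER
            else:
                label_order = tuple(f"class_{i}" for i in range(spec.n_classes))
        if len(label_order) != spec.n_classes:
            raise ConfigError(
                f"label_order has {len(label_order)} entries for "
                f"{spec.n_classes} classes"
            )
        self.spec = spec
        self.label_order: tuple[str, ...] = tuple(label_order)
        self.params: Optional[dict[str, np.ndarray]] = None
        self.history: list[dict] = []

    # ------------------------------------------------------------------ setup

    def initialize(self, rng: np.random.Generator | int) -> "SpliceCNN":
        if isinstance(rng, (int, np.integer)):
            rng = np.random.default_rng(int(rng))
        spec = self.spec
        params: dict[str, np.ndarray] = {}
        in_ch = 4
        for i in range(spec.n_conv_layers):
            cols = spec.kernel_size * in_ch
            params[f"conv{i}_W"] = _glorot(
                rng, (cols, spec.kernels), cols, spec.kernel_size * spec.kernels
            )
            params[f"conv{i}_b"] = np.zeros(spec.kernels, dtype=np.float32)
            in_ch = spec.kernels
        flat = spec.conv_out_len * spec.kernels
        params["fc1_W"] = _glorot(rng, (flat, spec.fc_units), flat, spec.fc_units)
        params["fc1_b"] = np.zeros(spec.fc_units, dtype=np.float32)
        params["fc2_W"] = _glorot(
            rng, (spec.fc_units, spec.n_classes), spec.fc_units, spec.n_classes
        )
        params["fc2_b"] = np.zeros(spec.n_classes, dtype=np.float32)
        self.params = params
        return self

    @property
    def n_parameters(self) -> int:
        if self.params is None:
            raise ModelStateError("model has no weights; initialize or train first")
        return int(sum(p.size for p in self.params.values()))

    def _require_params(self):
        if self.params is None:
            raise ModelStateError("model has no weights; initialize or train first")

    # ---------------------------------------------------------------- forward

    def _conv_forward(self, x: np.ndarray, i: int):
        spec = self.spec
        pl, pr = _same_padding(x.shape[1], spec.kernel_size, spec.stride)
        xp = np.pad(x, ((0, 0), (pl, pr), (0, 0)))
        win = np.lib.stride_tricks.sliding_window_view(
            xp, spec.kernel_size, axis=1
        )  # (n, out_full, ch, ks)
        win = win[:, :: spec.stride]
        n, out_len = win.shape[0], win.shape[1]
        col = win.transpose(0, 1, 3, 2).reshape(n, out_len, -1)  # (n, out, ks*ch)
        pre = col @ self.params[f"conv{i}_W"] + self.params[f"conv{i}_b"]
        act = np.maximum(pre, 0) if spec.conv_activation == "relu" else pre
        return act, {"col": col, "pre": pre, "pad": (pl, pr), "in_len": x.shape[1]}

    def _conv_backward(self, dact: np.ndarray, cache: dict, i: int, grads: dict):
        spec = self.spec
        pre, col = cache["pre"], cache["col"]
        dpre = dact * (pre > 0) if spec.conv_activation == "relu" else dact
        n, out_len, k = dpre.shape
        grads[f"conv{i}_W"] = col.reshape(-1, col.shape[-1]).T @ dpre.reshape(-1, k)
        grads[f"conv{i}_b"] = dpre.sum(axis=(0, 1))
        dcol = dpre @ self.params[f"conv{i}_W"].T  # (n, out, ks*ch)
        ch = col.shape[-1] // spec.kernel_size
        dcol = dcol.reshape(n, out_len, spec.kernel_size, ch)
        pl, pr = cache["pad"]
        dxp = np.zeros((n, cache["in_len"] + pl + pr, ch), dtype=dcol.dtype)
        if spec.stride == 1:
            for j in range(spec.kernel_size):
                dxp[:, j : j + out_len, :] += dcol[:, :, j, :]
        else:
            pos = np.arange(out_len) * spec.stride
            for j in range(spec.kernel_size):
                np.add.at(dxp, (slice(None), pos + j, slice(None)), dcol[:, :, j, :])
        return dxp[:, pl : pl + cache["in_len"], :]

    def _forward(
        self,
        x: np.ndarray,
        training: bool = False,
        rng: Optional[np.random.Generator] = None,
    ):
        self._require_params()
        spec = self.spec
        if x.ndim != 3 or x.shape[1] != spec.L or x.shape[2] != 4:
            raise ShapeError(
                f"expected input of shape (n, {spec.L}, 4), got {x.shape}"
            )
        cache: dict = {"conv": []}
        h = x.astype(np.float32, copy=False)
        for i in range(spec.n_conv_layers):
            h, c = self._conv_forward(h, i)
            cache["conv"].append(c)
        n = h.shape[0]
        flat = h.reshape(n, -1)
        cache["flat"] = flat
        fc1_pre = flat @ self.params["fc1_W"] + self.params["fc1_b"]
        fc1 = np.maximum(fc1_pre, 0)
        cache["fc1_pre"] = fc1_pre
        if training and spec.dropout_rate > 0:
            if rng is None:
                raise ConfigError("training-mode forward needs an rng for dropout")
            mask = dropout_mask(rng, fc1.shape, spec.dropout_rate)
            fc1 = fc1 * mask / (1.0 - spec.dropout_rate)
            cache["drop_mask"] = mask
        cache["fc1"] = fc1
        logits = fc1 @ self.params["fc2_W"] + self.params["fc2_b"]
        cache["logits"] = logits
        return softmax(logits), cache

    def training_forward(self, x: np.ndarray, rng: np.random.Generator):
        """Forward pass in training mode; returns (probs, dropout keep-mask).

        Exposed for diagnostics (e.g. verifying the empirical dropout rate).
        """
        probs, cache = self._forward(x, training=True, rng=rng)
        return probs, cache.get("drop_mask")

    def logits(self, x: np.ndarray) -> np.ndarray:
        _, cache = self._forward(x, training=False)
        return cache["logits"]

    def predict_proba(self, windows, batch_size: int = 1024) -> np.ndarray:
        """Class probabilities for encoded arrays or sequence strings."""
        x = self._coerce_input(windows)
        out = []
        for lo in range(0, len(x), batch_size):
            probs, _ = self._forward(x[lo : lo + batch_size])
            out.append(probs)
        if not out:
            return np.zeros((0, self.spec.n_classes))
        return np.concatenate(out)

    def _coerce_input(self, windows) -> np.ndarray:
        if isinstance(windows, EncodedBatch):
            return windows.x
        if isinstance(windows, np.ndarray):
            return windows
        seqs = [w.sequence if hasattr(w, "sequence") else w for w in windows]
        return encode_batch(seqs)

    # --------------------------------------------------------------- backward

    def input_gradient(self, x: np.ndarray, class_index: int) -> np.ndarray:
        """d(pre-softmax logit of class)/d(input), dropout inactive."""
        self._require_params()
        if not (0 <= class_index < self.spec.n_classes):
            raise ConfigError(f"class index {class_index} out of range")
        _, cache = self._forward(x, training=False)
        n = x.shape[0]
        dfc1 = np.broadcast_to(
            self.params["fc2_W"][:, class_index], (n, self.spec.fc_units)
        ).copy()
        dfc1 *= cache["fc1_pre"] > 0
        dflat = dfc1 @ self.params["fc1_W"].T
        dh = dflat.reshape(n, self.spec.conv_out_len, self.spec.kernels)
        grads: dict = {}
        for i in reversed(range(self.spec.n_conv_layers)):
            dh = self._conv_backward(dh, cache["conv"][i], i, grads)
        return dh

    def _loss_and_grads(self, x, y, rng):
        probs, cache = self._forward(x, training=True, rng=rng)
        n = x.shape[0]
        eps = 1e-12
        loss = -np.log(probs[np.arange(n), y] + eps).mean()
        dlogits = probs.copy()
        dlogits[np.arange(n), y] -= 1.0
        dlogits /= n
        grads: dict[str, np.ndarray] = {}
        grads["fc2_W"] = cache["fc1"].T @ dlogits
        grads["fc2_b"] = dlogits.sum(axis=0)
        dfc1 = dlogits @ self.params["fc2_W"].T
        if "drop_mask" in cache:
            dfc1 = dfc1 * cache["drop_mask"] / (1.0 - self.spec.dropout_rate)
        dfc1 *= cache["fc1_pre"] > 0
        grads["fc1_W"] = cache["flat"].T @ dfc1
        grads["fc1_b"] = dfc1.sum(axis=0)
        dflat = dfc1 @ self.params["fc1_W"].T
        dh = dflat.reshape(x.shape[0], self.spec.conv_out_len, self.spec.kernels)
        for i in reversed(range(self.spec.n_conv_layers)):
            dh = self._conv_backward(dh, cache["conv"][i], i, grads)
        acc = float((probs.argmax(axis=1) == y).mean())
        return loss, acc, grads

    # ----------------------------------------------------------------- train

    def fit(
        self,
        train: EncodedBatch,
        validation: Optional[EncodedBatch] = None,
        config: TrainConfig = TrainConfig(),
    ) -> "SpliceCNN":
        rng = np.random.default_rng(config.seed)
        if self.params is None:
            self.initialize(rng)
        x, y = train.x, train.y
        if y.min(initial=0) < 0 or y.max(initial=0) >= self.spec.n_classes:
            raise ConfigError("training labels outside the model's label order")
        # Adam state (Keras defaults: beta1=0.9, beta2=0.999, eps=1e-7)
        m = {k: np.zeros_like(v) for k, v in self.params.items()}
        v = {k: np.zeros_like(p) for k, p in self.params.items()}
        b1, b2, eps = 0.9, 0.999, 1e-7
        t = 0
        for epoch in range(config.epochs):
            order = rng.permutation(len(x))
            losses, accs, weights = [], [], []
            for lo in range(0, len(x), config.batch_size):
                idx = order[lo : lo + config.batch_size]
                loss, acc, grads = self._loss_and_grads(x[idx], y[idx], rng)
                t += 1
                lr_t = config.learning_rate * math.sqrt(1 - b2**t) / (1 - b1**t)
                for k, g in grads.items():
                    m[k] = b1 * m[k] + (1 - b1) * g
                    v[k] = b2 * v[k] + (1 - b2) * g * g
                    self.params[k] -= lr_t * m[k] / (np.sqrt(v[k]) + eps)
                losses.append(loss)
                accs.append(acc)
                weights.append(len(idx))
            entry = {
                "epoch": epoch + 1,
                "loss": float(np.average(losses, weights=weights)),
                "accuracy": float(np.average(accs, weights=weights)),
            }
            if validation is not None and len(validation.x):
                probs = self.predict_proba(validation.x)
                vy = validation.y
                entry["val_loss"] = float(
                    -np.log(probs[np.arange(len(vy)), vy] + 1e-12).mean()
                )
                entry["val_accuracy"] = float((probs.argmax(axis=1) == vy).mean())
            self.history.append(entry)
        return self

    def evaluate_accuracy(self, batch: EncodedBatch) -> float:
        probs = self.predict_proba(batch.x)
        return float((probs.argmax(axis=1) == batch.y).mean())

    # ------------------------------------------------------------ persistence

    def save(self, path):
        self._require_params()
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        meta = {
            "format_version": FORMAT_VERSION,
            "spec": asdict(self.spec),
            "label_order": list(self.label_order),
            "history": self.history,
        }
        (path / "model.json").write_text(json.dumps(meta, indent=2))
        np.savez(path / "weights.npz", **self.params)

    @classmethod
    def load(cls, path, expected_classes: int | None = None) -> "SpliceCNN":
        path = Path(path)
        meta_file = path / "model.json"
        if not meta_file.exists():
            raise ModelLoadError(f"no saved model at {path}")
        meta = json.loads(meta_file.read_text())
        version = meta.get("format_version")
        if version != FORMAT_VERSION:
            raise ModelLoadError(
                f"saved model format {version} incompatible with "
                f"supported format {FORMAT_VERSION}"
            )
        spec = ModelSpec(**meta["spec"])
        if expected_classes is not None and spec.n_classes != expected_classes:
            raise ModelLoadError(
                f"expected a {expected_classes}-class model but "
                f"{path} holds {spec.n_classes} classes"
            )
        model = cls(spec, label_order=meta["label_order"])
        with np.load(path / "weights.npz") as blob:
            model.params = {k: blob[k].copy() for k in blob.files}
        model.history = meta.get("history", [])
        return model


# Functional wrappers matching the operation-level interface. ------------------


def build_model(
    spec: ModelSpec, label_order: Optional[Sequence[str]] = None
) -> SpliceCNN:
    return SpliceCNN(spec, label_order=label_order)


def train_model(
    model: SpliceCNN,
    train_set: SpliceDataset | EncodedBatch,
    validation_set: SpliceDataset | EncodedBatch | None,
    config: TrainConfig,
) -> SpliceCNN:
    def encode(ds):
        if ds is None:
            return None
        if isinstance(ds, EncodedBatch):
            return ds
        for w in ds:
            if w.label not in model.label_order:
                raise ConfigError(
                    f"label {w.label!r} outside model label order "
                    f"{model.label_order}"
                )
        return ds.encode(label_order=model.label_order)

    return model.fit(encode(train_set), encode(validation_set), config)


def predict_proba(model: SpliceCNN, windows) -> np.ndarray:
    return model.predict_proba(windows)


def save_model(model: SpliceCNN, path):
    model.save(path)


def load_model(path, expected_classes: int | None = None) -> SpliceCNN:
    return SpliceCNN.load(path, expected_classes=expected_classes)
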