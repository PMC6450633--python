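"""Compact CNN for 4-class OCT B-scan classification.

The default architecture takes a 128 x 342 x 3 image and consists of three
convolutional blocks — a padded 3x3 conv, an unpadded 3x3 conv, then 2x2 max
pooling — followed by flattening and dense layers of width 200, 20 and 4.
Batch normalization sits after the 200-unit dense layer and dropout (0.5) on
the last two dense connections.  All activations are ReLU except the output,
which is an independent per-class sigmoid.  The network is deliberately
small (~7.6M parameters) so that gradient-based attribution retains signal.

Classes: normal, dry AMD, wet AMD (observation only), wet AMD (anti-VEGF
injection required).
"""

from __future__ import annotations

import dataclasses
import enum
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nnlayers as nn

F32 = np.float32

DEFAULT_INPUT_SHAPE = (128, 342, 3)
DEFAULT_CONV_CHANNELS = (16, 16, 32, 32, 64, 64)
DEFAULT_DENSE_WIDTHS = (200, 20)


class ClassLabel(enum.IntEnum):
    """The four diagnostic classes, index <-> name bijection."""

    normal = 0
    dry_amd = 1
    wet_amd_observation = 2
    wet_amd_injection = 3

    @classmethod
    def from_name(cls, name: str) -> "ClassLabel":
        return cls[name]


@dataclass
class LayerSpec:
    """One architectural layer.

    ``out_channels`` doubles as the unit count for dense layers.  Conv layers
    are fixed at kernel 3, stride 1 (the only configuration the projection
    algorithm supports); max pooling is 2x2 stride 2.
    """

    kind: str  # conv_same | conv_valid | maxpool | flatten | dense | batchnorm | dropout
    out_channels: int = 0
    kernel: int = 3
    stride: int = 1
    activation: str = "none"  # relu | sigmoid | none
    dropout_rate: float = 0.0

    def __post_init__(self):
        if self.kind in ("conv_same", "conv_valid"):
            if self.kernel != 3 or self.stride != 1:
                raise ValueError("conv layers must have kernel=3, stride=1")


@dataclass
class ModelSpec:
    input_shape: tuple = DEFAULT_INPUT_SHAPE
    layers: list = field(default_factory=list)

    @property
    def num_conv_layers(self) -> int:
        return sum(1 for l in self.layers if l.kind.startswith("conv"))

    def validate(self):
        sig = [l for l in self.layers if l.activation == "sigmoid"]
        if len(sig) > 1 or (sig and self.layers[-1] is not sig[0]):
            raise ValueError("sigmoid is only allowed on the final layer")

    def to_dict(self):
        return {
            "input_shape": list(self.input_shape),
            "layers": [dataclasses.asdict(l) for l in self.layers],
        }

    @classmethod
    def from_dict(cls, d):
        return cls(
            input_shape=tuple(d["input_shape"]),
            layers=[LayerSpec(**ld) for ld in d["layers"]],
        )


def default_model_spec(
    input_shape=DEFAULT_INPUT_SHAPE,
    conv_channels=DEFAULT_CONV_CHANNELS,
    dense_widths=DEFAULT_DENSE_WIDTHS,
    num_classes=4,
    bn_after_conv_blocks=False,
) -> ModelSpec:
    """The default 6-conv / 4-dense-stage architecture.

    ``conv_channels`` is the per-conv output-channel plan (two convs per
    block); ``bn_after_conv_blocks`` optionally inserts per-channel batch
    normalization after each pooling layer.
    """
    if len(conv_channels) % 2 != 0:
        raise ValueError("conv_channels must pair up into blocks of two")
    layers = []
    for b in range(len(conv_channels) // 2):
        layers.append(LayerSpec("conv_same", conv_channels[2 * b], activation="relu"))
        layers.append(LayerSpec("conv_valid", conv_channels[2 * b + 1], activation="relu"))
        layers.append(LayerSpec("maxpool"))
        if bn_after_conv_blocks:
            layers.append(LayerSpec("batchnorm"))
    layers.append(LayerSpec("flatten"))
    layers.append(LayerSpec("dense", dense_widths[0], activation="relu"))
    layers.append(LayerSpec("batchnorm"))
    layers.append(LayerSpec("dropout", dropout_rate=0.5))
    layers.append(LayerSpec("dense", dense_widths[1], activation="relu"))
    layers.append(LayerSpec("dropout", dropout_rate=0.5))
    layers.append(LayerSpec("dense", num_classes, activation="sigmoid"))
    return ModelSpec(input_shape=tuple(input_shape), layers=layers)


@dataclass
class TrainConfig:
    """Training protocol.

    The default schedule is the 200-epoch plan (100 epochs at lr 0.01, then
    50 at 0.001, then 50 at 0.0001) with batch size 101; quick studies pass
    a shorter schedule.  ``loss='sigmoid_ce'`` is per-class sigmoid cross
    entropy against one-hot targets; ``'softmax_ce'`` is available.
    """

    epochs_schedule: list = field(
        default_factory=lambda: [(100, 0.01), (50, 0.001), (50, 0.0001)]
    )
    batch_size: int = 101
    loss: str = "sigmoid_ce"
    optimizer: str = "adam"
    init: str = "xavier"
    seed: int = 0
    bn_recalibrate: int = 256  # images used to refresh BN stats post-training (0 = off)

    def to_dict(self):
        return dataclasses.asdict(self)


class ConfigurationError(ValueError):
    pass


class TrainingDivergenceError(RuntimeError):
    pass


class Model:
    """A built network: layer objects + static shape trace.

    ``conv_positions[i-1]`` is the index (into ``layers``) of conv layer i,
    i = 1..L.  ``shape_trace`` records the output shape of every layer, used
    by the attribution projection to restore spatial dims.
    """

    def __init__(self, spec: ModelSpec, seed: int = 0):
        spec.validate()
        rng = np.random.default_rng(seed)
        self.spec = spec
        self.trained = False
        self.layers = []
        self.conv_positions = []
        shape = tuple(spec.input_shape)
        self.input_shape = shape
        self.shape_trace = []
        for pos, ls in enumerate(spec.layers):
            h, w, c = (shape if len(shape) == 3 else (None, None, shape[0]))
            if ls.kind == "conv_same":
                layer = nn.Conv2D(c, ls.out_channels, "same", relu=ls.activation == "relu", rng=rng)
                shape = (h, w, ls.out_channels)
            elif ls.kind == "conv_valid":
                layer = nn.Conv2D(c, ls.out_channels, "valid", relu=ls.activation == "relu", rng=rng)
                shape = (h - 2, w - 2, ls.out_channels)
            elif ls.kind == "maxpool":
                layer = nn.MaxPool2()
                layer.in_hw = (h, w)
                shape = (h // 2, w // 2, c)
            elif ls.kind == "flatten":
                layer = nn.Flatten()
                shape = (h * w * c,)
            elif ls.kind == "dense":
                layer = nn.Dense(shape[0], ls.out_channels, activation=ls.activation, rng=rng)
                shape = (ls.out_channels,)
            elif ls.kind == "batchnorm":
                layer = nn.BatchNorm1D(shape[0]) if len(shape) == 1 else nn.BatchNorm2D(shape[-1])
            elif ls.kind == "dropout":
                layer = nn.Dropout(ls.dropout_rate)
            else:
                raise ConfigurationError(f"unknown layer kind {ls.kind!r} at position {pos}")
            if any(d is not None and d <= 0 for d in shape):
                raise ConfigurationError(
                    f"shape propagation failed at layer {pos} ({ls.kind}): shape {shape}"
                )
            if ls.kind.startswith("conv"):
                self.conv_positions.append(pos)
            self.layers.append(layer)
            self.shape_trace.append(shape)
        self.output_dim = shape[0]

    # -- forward paths ----------------------------------------------------
    @property
    def num_conv_layers(self) -> int:
        return len(self.conv_positions)

    def _run(self, x, start_pos=0, training=False, rng=None):
        for layer in self.layers[start_pos:]:
            x = layer.forward(x, training=training, rng=rng)
        return x

    def _run_collect(self, x):
        """Eval-mode forward collecting post-activation conv feature maps."""
        feats = []
        conv_set = set(self.conv_positions)
        for pos, layer in enumerate(self.layers):
            x = layer.forward(x, training=False)
            if pos in conv_set:
                feats.append(x)
        return x, feats

    def _grad_input(self, dy, start_pos=0, guided=False):
        for layer in reversed(self.layers[start_pos:]):
            dy = layer.backward(dy, param_grads=False, guided=guided)
        return dy

    def suffix_start(self, i: int) -> int:
        """Layer-list position where the partial network F_{i+1} begins
        (the first layer after conv layer i; the whole net for i = 0)."""
        if i == 0:
            return 0
        return self.conv_positions[i - 1] + 1

    def forward(self, image: np.ndarray):
        """Full forward pass on one image.

        Returns ``(scores, features)`` where scores is the length-4 sigmoid
        output and ``features[i]`` is the post-activation feature map of conv
        layer i (``features[0]`` is the input image itself).
        """
        image = self._check_image(image)
        out, feats = self._run_collect(image[None].astype(F32))
        return out[0], [image.astype(F32)] + [f[0] for f in feats]

    def partial_forward(self, i: int, f: np.ndarray):
        """Scores of the partial network applied to feature map ``f`` of conv
        layer ``i`` (i = 0 feeds the input image through the whole net)."""
        if not 0 <= i <= self.num_conv_layers:
            raise ValueError(f"conv layer index {i} out of range 0..{self.num_conv_layers}")
        expected = self.input_shape if i == 0 else self.shape_trace[self.conv_positions[i - 1]]
        if tuple(f.shape) != tuple(expected):
            raise ValueError(f"feature map shape {f.shape} != expected {expected} for layer {i}")
        return self._run(f[None].astype(F32), start_pos=self.suffix_start(i))[0]

    def _check_image(self, image):
        image = np.asarray(image, dtype=F32)
        if image.shape != tuple(self.input_shape):
            raise ValueError(f"image shape {image.shape} != model input {self.input_shape}")
        if not np.all(np.isfinite(image)):
            raise ValueError("image contains non-finite values")
        return image

    def conv_weights(self, i: int) -> np.ndarray:
        """Weight tensor of conv layer i (1-based), shape (d_i, d_{i-1}, 3, 3)."""
        return self.layers[self.conv_positions[i - 1]].params["W"]

    # -- persistence ------------------------------------------------------
    def save(self, path, train_config: TrainConfig | None = None):
        """Write weights to ``<path>`` (npz) and a JSON sidecar with the spec."""
        path = Path(path)
        if path.suffix != ".npz":
            path = path.with_suffix(".npz")
        arrays = {}
        for pos, layer in enumerate(self.layers):
            for k, v in layer.params.items():
                arrays[f"layer{pos}_{k}"] = v
            for k in ("running_mean", "running_var"):
                if hasattr(layer, k):
                    arrays[f"layer{pos}_{k}"] = getattr(layer, k)
        np.savez(path, **arrays)
        sidecar = {
            "spec": self.spec.to_dict(),
            "trained": self.trained,
            "train_config": train_config.to_dict() if train_config else None,
        }
        sidecar_path = path.with_suffix(".json")
        sidecar_path.write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path) -> "Model":
        path = Path(path)
        if not path.exists() and path.with_suffix(".npz").exists():
            path = path.with_suffix(".npz")
        sidecar = json.loads(path.with_suffix(".json").read_text())
        model = cls(ModelSpec.from_dict(sidecar["spec"]), seed=0)
        data = np.load(path)
        for pos, layer in enumerate(model.layers):
            for k in list(layer.params):
                layer.params[k] = data[f"layer{pos}_{k}"]
            for k in ("running_mean", "running_var"):
                key = f"layer{pos}_{k}"
                if key in data:
                    setattr(layer, k, data[key])
        model.trained = bool(sidecar["trained"])
        return model


# ---------------------------------------------------------------------------
# Functional API
# ---------------------------------------------------------------------------

def build_model(spec: ModelSpec, seed: int = 0) -> Model:
    """Build an untrained, Xavier-initialized model (deterministic in seed)."""
    return Model(spec, seed=seed)


def forward(model: Model, image: np.ndarray):
    return model.forward(image)


def partial_forward(model: Model, i: int, f: np.ndarray):
    return model.partial_forward(i, f)


def count_parameters(model: Model) -> int:
    """Exact count of trainable weight/bias/BN-affine elements."""
    return sum(layer.n_params for layer in model.layers)


def predict(model: Model, image: np.ndarray):
    """Predicted class (argmax of the 4 sigmoid scores; ties -> lowest index)
    and its score."""
    if not model.trained:
        warnings.warn("predicting with an untrained model", stacklevel=2)
    scores, _ = model.forward(image)
    idx = int(np.argmax(scores))
    return ClassLabel(idx), float(scores[idx])


def _as_arrays(dataset):
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    images, labels = [], []
    for item in dataset:
        if hasattr(item, "image"):
            images.append(item.image)
            labels.append(int(item.label))
        else:
            img, lab = item
            images.append(img)
            labels.append(int(lab))
    return np.stack(images).astype(F32), np.asarray(labels, dtype=np.int64)


def _loss_and_grad(z, s, y_onehot, kind):
    """Loss value and gradient w.r.t. the final pre-activation ``z``."""
    n = z.shape[0]
    if kind == "sigmoid_ce":
        # numerically stable per-class sigmoid cross entropy on logits
        loss = np.mean(
            np.sum(np.maximum(z, 0) - z * y_onehot + np.log1p(np.exp(-np.abs(z))), axis=1)
        )
        dz = (s - y_onehot) / n
    elif kind == "softmax_ce":
        zs = z - z.max(axis=1, keepdims=True)
        p = np.exp(zs)
        p /= p.sum(axis=1, keepdims=True)
        loss = -np.mean(np.log(p[np.arange(n), y_onehot.argmax(axis=1)] + 1e-12))
        dz = (p - y_onehot) / n
    else:
        raise ValueError(f"unknown loss {kind!r}")
    return float(loss), dz.astype(F32)


def train_model(model: Model, dataset, config: TrainConfig):
    """Train with Adam under the epoch/learning-rate schedule.

    Dropout and batch normalization are active only during training.  Returns
    ``(model, history)`` where history is a list of per-epoch dicts with
    ``epoch``, ``lr``, ``loss`` and (training) ``accuracy``.  Fixed seed
    gives a bit-reproducible history.
    """
    X, y = _as_arrays(dataset)
    n = len(y)
    num_classes = model.output_dim
    if y.min() < 0 or y.max() >= num_classes:
        raise ValueError("labels out of range for the model's output layer")
    y_onehot_all = np.eye(num_classes, dtype=F32)[y]
    rng = np.random.default_rng(config.seed)
    opt = nn.Adam([l for l in model.layers if l.params])
    final_dense = model.layers[-1]
    history = []
    epoch = 0
    for n_epochs, lr in config.epochs_schedule:
        for _ in range(n_epochs):
            perm = rng.permutation(n)
            losses, correct = [], 0
            for start in range(0, n, config.batch_size):
                idx = perm[start : start + config.batch_size]
                xb, yb = X[idx], y_onehot_all[idx]
                for layer in model.layers:
                    if layer.params:
                        layer.zero_grads()
                s = model._run(xb, training=True, rng=rng)
                z = final_dense._z
                loss, dz = _loss_and_grad(z, s, yb, config.loss)
                if not np.isfinite(loss):
                    raise TrainingDivergenceError(f"non-finite loss at epoch {epoch}")
                losses.append(loss * len(idx))
                correct += int((s.argmax(axis=1) == y[idx]).sum())
                dy = final_dense.backward(dz, param_grads=True, dy_is_preact=True)
                for pos in range(len(model.layers) - 2, -1, -1):
                    layer = model.layers[pos]
                    if pos == 0 and isinstance(layer, nn.Conv2D):
                        # the input needs no gradient; skip the heaviest matmuls
                        layer.backward(dy, param_grads=True, need_input_grad=False)
                    else:
                        dy = layer.backward(dy, param_grads=True)
                opt.step(lr)
            history.append(
                {
                    "epoch": epoch,
                    "lr": lr,
                    "loss": sum(losses) / n,
                    "accuracy": correct / n,
                }
            )
            epoch += 1
    if config.bn_recalibrate:
        _recalibrate_batchnorm(model, X[: config.bn_recalibrate])
    model.trained = True
    return model, history


def _recalibrate_batchnorm(model: Model, X: np.ndarray, batch: int = 32):
    """Replace BN running statistics with full-data moments of the trained
    network's activations.  The exponential running average lags badly after
    a short high-learning-rate schedule; one inference sweep fixes the
    train/eval mismatch."""
    bn_layers = [
        (pos, l) for pos, l in enumerate(model.layers)
        if isinstance(l, (nn.BatchNorm1D, nn.BatchNorm2D))
    ]
    if not bn_layers:
        return
    for pos, layer in bn_layers:
        moments = []
        for start in range(0, len(X), batch):
            x = X[start : start + batch]
            for prior in model.layers[:pos]:
                x = prior.forward(x)
            axes = (0,) if x.ndim == 2 else (0, 1, 2)
            moments.append((x.mean(axis=axes), x.var(axis=axes), x.shape[0]))
        weights = np.array([m[2] for m in moments], dtype=np.float64)
        weights /= weights.sum()
        mean = sum(w * m for w, (m, _, _) in zip(weights, moments))
        # law of total variance across batches
        var = sum(w * (v + (m - mean) ** 2) for w, (m, v, _) in zip(weights, moments))
        layer.running_mean = mean.astype(F32)
        layer.running_var = var.astype(F32)
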