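"""The binary 3D CNN classifier, written directly on NumPy.

Architecture (reference configuration): four 3D convolutional layers
(16 filters each, 3x3x3 kernels, stride 1, dilation 1, valid padding, no
pooling), a flatten, fully connected layers of 32 and 16 rectified units
(dropout 0.2 after the first), and a 2-way softmax output.  Training uses
categorical cross-entropy with Adam at learning rate 1e-4 and batch size 8,
without class weighting; the weights of the epoch with minimum validation
loss are retained.

Convolutions run as im2col + BLAS matrix products in float32; gradients are
exact backpropagation through the same path (validated against finite
differences in the test suite).  Everything stochastic (initialization,
shuffling, dropout) is driven by explicit seeds, so training is a pure
function of (data, config, seed) on a fixed BLAS configuration.  The
forward pass can record every layer's post-activation values
(:class:`ActivationTrace`), which is what the relevance-propagation engine
consumes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "CnnSpec",
    "TrainConfig",
    "ActivationTrace",
    "Cnn3dClassifier",
    "build_cnn",
    "train",
    "ShapeError",
    "DivergenceError",
]

CLASS_NAMES = ("negative", "positive")


class ShapeError(ValueError):
    """Input grid incompatible with the layer stack."""


class DivergenceError(RuntimeError):
    """Training produced a non-finite loss."""


@dataclass(frozen=True)
class CnnSpec:
    """Layer configuration of the classifier."""

    conv_filters: tuple = (16, 16, 16, 16)
    kernel: int = 3
    fc_sizes: tuple = (32, 16)
    n_classes: int = 2
    dropout: float = 0.2

    def __post_init__(self):
        if self.kernel != 3:
            raise ValueError("only 3x3x3 kernels are supported")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")


# ---------------------------------------------------------------------------
# im2col machinery (channels-last layout: (N, D, H, W, C))

def _im2col(x: np.ndarray):
    """Unfold 3x3x3 valid-padding windows into rows of a matrix.

    Returns ``(cols, out_spatial)`` with ``cols`` of shape
    ``(N * prod(out_spatial), C * 27)``; column index order is
    (channel, dz0, dz1, dz2), matching the stored weight layout.
    """
    w = sliding_window_view(x, (3, 3, 3), axis=(1, 2, 3))
    n, d, h, ww = w.shape[:4]
    cols = w.reshape(n * d * h * ww, -1)
    return np.ascontiguousarray(cols), (d, h, ww)


def _col2im(dcols: np.ndarray, x_shape) -> np.ndarray:
    """Scatter-add column gradients/relevance back onto the input grid."""
    n, d, h, w, c = x_shape
    do, ho, wo = d - 2, h - 2, w - 2
    dcols = dcols.reshape(n, do, ho, wo, c, 3, 3, 3)
    dx = np.zeros(x_shape, dtype=dcols.dtype)
    for i in range(3):
        for j in range(3):
            for k in range(3):
                dx[:, i : i + do, j : j + ho, k : k + wo, :] += dcols[
                    :, :, :, :, :, i, j, k
                ]
    return dx


# ---------------------------------------------------------------------------
# layers

class Conv3D:
    """3x3x3 valid convolution, stride 1, optional fused ReLU."""

    kind = "conv"

    def __init__(self, cin, cout, rng, relu=True, name="conv"):
        fan_in = cin * 27
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), (fan_in, cout)).astype(
            np.float32
        )
        self.b = np.zeros(cout, dtype=np.float32)
        self.relu = relu
        self.cin, self.cout = cin, cout
        self.name = name

    def params(self):
        return [("W", self.W), ("b", self.b)]

    def forward(self, x, train=False, rng=None):
        self._x_shape = x.shape
        cols, sp = _im2col(x)
        # keep the unfolded matrix for the gradient pass only while training
        self._cols = cols if train else None
        y = cols @ self.W + self.b
        y = y.reshape((x.shape[0],) + sp + (self.cout,))
        if self.relu:
            np.maximum(y, 0.0, out=y)
        self._y = y
        return y

    def backward(self, dy):
        if self.relu:
            dy = dy * (self._y > 0)
        dyf = dy.reshape(-1, self.cout)
        cols = self._cols
        self.dW = cols.T @ dyf
        self.db = dyf.sum(axis=0)
        dcols = dyf @ self.W.T
        self._cols = None
        return _col2im(dcols, self._x_shape)


class Flatten:
    kind = "flatten"
    name = "flatten"

    def params(self):
        return []

    def forward(self, x, train=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Dense:
    kind = "dense"

    def __init__(self, nin, nout, rng, relu=True, name="fc", zero_init=False):
        # the softmax head starts at zero so the initial decision carries no
        # random readout direction; hidden layers use He-normal fan-in scaling
        if zero_init:
            self.W = np.zeros((nin, nout), dtype=np.float32)
        else:
            self.W = rng.normal(0.0, np.sqrt(2.0 / nin), (nin, nout)).astype(
                np.float32
            )
        self.b = np.zeros(nout, dtype=np.float32)
        self.relu = relu
        self.name = name

    def params(self):
        return [("W", self.W), ("b", self.b)]

    def forward(self, x, train=False, rng=None):
        self._x = x
        y = x @ self.W + self.b
        if self.relu:
            np.maximum(y, 0.0, out=y)
        self._y = y
        return y

    def backward(self, dy):
        if self.relu:
            dy = dy * (self._y > 0)
        self.dW = self._x.T @ dy
        self.db = dy.sum(axis=0)
        return dy @ self.W.T


class Dropout:
    """Inverted dropout; identity whenever ``train`` is false."""

    kind = "dropout"
    name = "dropout"

    def __init__(self, p):
        self.p = p

    def params(self):
        return []

    def forward(self, x, train=False, rng=None):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (rng.random(x.shape) >= self.p).astype(np.float32) / (
            1.0 - self.p
        )
        return x * self._mask

    def backward(self, dy):
        if self._mask is None:
            return dy
        return dy * self._mask


# ---------------------------------------------------------------------------
# model

@dataclass
class ActivationTrace:
    """Per-layer post-activation values of one forward pass.

    ``activations`` runs from the input grid through every hidden layer to
    the pre-softmax output scores; hidden entries are post-ReLU (hence
    non-negative).  Dropout is inactive, so the trace is the inference-time
    forward pass.
    """

    names: list
    kinds: list
    activations: list

    @property
    def scores(self) -> np.ndarray:
        return self.activations[-1]


def softmax(scores: np.ndarray) -> np.ndarray:
    z = scores - scores.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class Cnn3dClassifier:
    """The layered network with weights, provenance, and a trace contract."""

    def __init__(self, spec: CnnSpec, input_shape, init_seed: int = 0):
        min_dim = 2 * len(spec.conv_filters) + 1
        if len(input_shape) != 3 or min(input_shape) < min_dim:
            raise ShapeError(
                f"input shape {tuple(input_shape)} too small for "
                f"{len(spec.conv_filters)} valid 3x3x3 convolutions "
                f"(every dim must be >= {min_dim})"
            )
        self.spec = spec
        self.input_shape = tuple(int(s) for s in input_shape)
        self.init_seed = int(init_seed)
        rng = np.random.default_rng(init_seed)

        self.layers: list = []
        cin = 1
        for i, nf in enumerate(spec.conv_filters, start=1):
            self.layers.append(Conv3D(cin, nf, rng, relu=True, name=f"conv{i}"))
            cin = nf
        self.layers.append(Flatten())
        sp = tuple(s - 2 * len(spec.conv_filters) for s in self.input_shape)
        nin = cin * int(np.prod(sp))
        self.conv_out_shape = sp + (cin,)
        for i, nf in enumerate(spec.fc_sizes, start=1):
            self.layers.append(Dense(nin, nf, rng, relu=True, name=f"fc{i}"))
            if i == 1 and spec.dropout > 0:
                self.layers.append(Dropout(spec.dropout))
            nin = nf
        self.layers.append(
            Dense(nin, spec.n_classes, rng, relu=False, name="output", zero_init=True)
        )
        self.provenance: dict = {"init_seed": self.init_seed}

    # -- parameter bookkeeping ------------------------------------------------

    def parameters(self):
        out = []
        for i, layer in enumerate(self.layers):
            for pname, arr in layer.params():
                out.append(((i, pname), layer, pname, arr))
        return out

    @property
    def n_params(self) -> int:
        return int(sum(arr.size for _, _, _, arr in self.parameters()))

    def get_weights(self):
        return {f"{i}:{p}": arr.copy() for (i, p), _, _, arr in self.parameters()}

    def set_weights(self, weights):
        for (i, pname), layer, _, _ in self.parameters():
            setattr(layer, pname, weights[f"{i}:{pname}"].copy())

    @property
    def weighted_layers(self):
        """Conv/dense layers in forward order (the LRP propagation targets)."""
        return [l for l in self.layers if l.kind in ("conv", "dense")]

    # -- forward --------------------------------------------------------------

    def _as_batch(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 3:
            x = x[None]
        if x.ndim == 4:
            x = x[..., None]
        if x.shape[1:4] != self.input_shape:
            raise ShapeError(
                f"input grid {x.shape[1:4]} != classifier grid {self.input_shape}"
            )
        return x

    def forward(self, x, train=False, rng=None):
        h = self._as_batch(x)
        for layer in self.layers:
            h = layer.forward(h, train=train, rng=rng)
        return h

    def predict_scores(self, x, batch_size: int = 16) -> np.ndarray:
        """Pre-softmax scores, dropout inactive."""
        x = self._as_batch(x)
        outs = [
            self.forward(x[i : i + batch_size])
            for i in range(0, x.shape[0], batch_size)
        ]
        return np.concatenate(outs, axis=0)

    def predict(self, x) -> dict:
        """Classify one volume (or batch); returns class, probabilities, scores."""
        scores = self.predict_scores(x)
        probs = softmax(scores.astype(np.float64))
        idx = scores.argmax(axis=-1)
        labels = [CLASS_NAMES[i] for i in idx]
        single = scores.shape[0] == 1
        return {
            "class_index": int(idx[0]) if single else idx,
            "label": labels[0] if single else labels,
            "probabilities": probs[0] if single else probs,
            "scores": scores[0] if single else scores,
        }

    def forward_trace(self, vol) -> ActivationTrace:
        """Inference forward pass recording every post-activation tensor.

        The final entry equals :meth:`predict_scores` on the same input
        bitwise (identical code path, dropout inactive).
        """
        h = self._as_batch(vol)
        if h.shape[0] != 1:
            raise ShapeError("forward_trace takes a single volume")
        names, kinds, acts = ["input"], ["input"], [h[0]]
        for layer in self.layers:
            h = layer.forward(h, train=False)
            if layer.kind == "dropout":
                continue  # identity at inference
            names.append(layer.name)
            kinds.append(layer.kind)
            acts.append(h[0])
        return ActivationTrace(names=names, kinds=kinds, activations=acts)

    # -- persistence ----------------------------------------------------------

    def save(self, path):
        path = Path(path)
        arrays = {f"{i}:{p}": arr for (i, p), _, _, arr in self.parameters()}
        meta = {
            "spec": asdict(self.spec),
            "input_shape": list(self.input_shape),
            "init_seed": self.init_seed,
            "provenance": self.provenance,
        }
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), np.uint8),
                 **arrays)

    @classmethod
    def load(cls, path) -> "Cnn3dClassifier":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            spec_d = meta["spec"]
            spec = CnnSpec(
                conv_filters=tuple(spec_d["conv_filters"]),
                kernel=spec_d["kernel"],
                fc_sizes=tuple(spec_d["fc_sizes"]),
                n_classes=spec_d["n_classes"],
                dropout=spec_d["dropout"],
            )
            model = cls(spec, tuple(meta["input_shape"]), meta["init_seed"])
            model.set_weights({k: data[k] for k in data.files if k != "__meta__"})
            model.provenance = meta.get("provenance", {})
        return model


def build_cnn(
    spec: Optional[CnnSpec] = None, input_shape=(48, 56, 44), init_seed: int = 0
) -> Cnn3dClassifier:
    """Construct the (untrained) classifier with seeded initialization."""
    return Cnn3dClassifier(spec or CnnSpec(), input_shape, init_seed)


# ---------------------------------------------------------------------------
# training

@dataclass
class TrainConfig:
    epochs: int = 30
    batch_size: int = 8
    learning_rate: float = 1e-4
    beta1: float = 0.9
    beta2: float = 0.999
    adam_eps: float = 1e-8
    seed: int = 0
    verbose: bool = False


def _cross_entropy(scores: np.ndarray, y: np.ndarray):
    """Mean categorical cross-entropy and its gradient w.r.t. the scores."""
    p = softmax(scores.astype(np.float64))
    n = scores.shape[0]
    loss = float(-np.log(np.clip(p[np.arange(n), y], 1e-12, None)).mean())
    grad = p.copy()
    grad[np.arange(n), y] -= 1.0
    return loss, (grad / n).astype(np.float32)


def evaluate_loss(model: Cnn3dClassifier, X, y, batch_size: int = 16) -> float:
    scores = model.predict_scores(X, batch_size=batch_size)
    loss, _ = _cross_entropy(scores, np.asarray(y))
    return loss


def train(
    model: Cnn3dClassifier,
    X_train,
    y_train,
    X_val=None,
    y_val=None,
    config: Optional[TrainConfig] = None,
) -> dict:
    """Train in place; returns the training history.

    Optimizes categorical cross-entropy with Adam (lr 1e-4 by default),
    batch size 8, no class weighting.  When a validation set is given, the
    weights of the epoch with minimum validation loss are restored at the
    end.  Raises :class:`DivergenceError` on non-finite loss.
    """
    config = config or TrainConfig()
    y_train = np.asarray(y_train, dtype=np.int64)
    if len(y_train) == 0:
        raise ValueError("empty training set")
    X_train = model._as_batch(X_train)
    rng = np.random.default_rng(config.seed)

    params = model.parameters()
    m = {k: np.zeros_like(arr) for k, _, _, arr in params}
    v = {k: np.zeros_like(arr) for k, _, _, arr in params}
    t = 0
    history = {"train_loss": [], "val_loss": [], "best_epoch": None}
    best_val, best_weights = np.inf, None

    n = X_train.shape[0]
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb, yb = X_train[idx], y_train[idx]
            h = xb
            for layer in model.layers:
                h = layer.forward(h, train=True, rng=rng)
            loss, grad = _cross_entropy(h, yb)
            if not np.isfinite(loss):
                raise DivergenceError(f"non-finite loss at epoch {epoch}")
            epoch_loss += loss
            n_batches += 1
            g = grad
            for layer in reversed(model.layers):
                g = layer.backward(g)
            t += 1
            lr_t = config.learning_rate * (
                np.sqrt(1.0 - config.beta2**t) / (1.0 - config.beta1**t)
            )
            for key, layer, pname, arr in params:
                garr = getattr(layer, "d" + pname)
                m[key] = config.beta1 * m[key] + (1 - config.beta1) * garr
                v[key] = config.beta2 * v[key] + (1 - config.beta2) * garr**2
                arr -= (lr_t * m[key] / (np.sqrt(v[key]) + config.adam_eps)).astype(
                    arr.dtype
                )
        history["train_loss"].append(epoch_loss / max(n_batches, 1))
        if X_val is not None and len(np.atleast_1d(y_val)) > 0:
            val_loss = evaluate_loss(model, X_val, y_val)
            if not np.isfinite(val_loss):
                raise DivergenceError(f"non-finite validation loss at epoch {epoch}")
            history["val_loss"].append(val_loss)
            if val_loss < best_val:
                best_val = val_loss
                best_weights = model.get_weights()
                history["best_epoch"] = epoch
        if config.verbose:  # pragma: no cover
            msg = f"epoch {epoch}: train {history['train_loss'][-1]:.4f}"
            if history["val_loss"]:
                msg += f" val {history['val_loss'][-1]:.4f}"
            print(msg)
    if best_weights is not None:
        model.set_weights(best_weights)
    model.provenance.update(
        {
            "epochs": config.epochs,
            "train_seed": config.seed,
            "final_train_loss": history["train_loss"][-1],
            "best_epoch": history["best_epoch"],
            "best_val_loss": None if best_weights is None else float(best_val),
        }
    )
    return history
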