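"""Small trainable convolutional network for 50x50 nodule patches.

The canonical architecture alternates valid convolutions and max-pooling,

    conv(20 @ 5x5) -> pool(2x2, /2) -> conv(32 @ 5x5) -> pool(2x2, /2)
    -> conv(32 @ 5x5) -> ReLU -> pool(2x2, stride 1) -> conv(40 @ 4x4)
    -> linear 40 -> 2 -> softmax

with the exact spatial trace 50 -> 46 -> 23 -> 19 -> 9 -> 5 -> 5 -> 4 -> 1,
so a 50x50x1 patch ends at a 1x1x2 class distribution.  The 40 activations
entering the final linear projection double as the learned feature vector
used in descriptor fusion.

Everything is implemented in numpy: convolution via im2col (with the
transposed-convolution backward pass), max-pooling with argmax scatter,
mini-batch SGD on the softmax cross-entropy.  Training is deterministic
under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Sequence, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.base import BaseEstimator, ClassifierMixin

PARAMS_FORMAT_VERSION = 1


# ---------------------------------------------------------------------------
# architecture spec
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConvSpec:
    filters: int
    kernel: int
    stride: int = 1


@dataclass(frozen=True)
class PoolSpec:
    kernel: int = 2
    stride: int = 2


@dataclass(frozen=True)
class ReluSpec:
    pass


@dataclass(frozen=True)
class CNNSpec:
    """Ordered feature layers plus the linear projection + softmax head."""

    layers: Tuple[object, ...]
    input_size: int = 50
    output_classes: int = 2

    def spatial_trace(self) -> List[int]:
        """Spatial side after the input and after every conv/pool layer."""
        size = self.input_size
        trace = [size]
        for layer in self.layers:
            if isinstance(layer, ConvSpec):
                if layer.stride != 1:
                    raise ValueError("convolution stride must be 1")
                size = size - layer.kernel + 1
            elif isinstance(layer, PoolSpec):
                size = (size - layer.kernel) // layer.stride + 1
            elif isinstance(layer, ReluSpec):
                pass  # activation leaves the spatial size unchanged
            else:
                raise ValueError(f"unknown layer spec {layer!r}")
            if size < 1:
                raise ValueError("spatial size collapsed below 1; spec does not compose")
            trace.append(size)
        return trace

    @property
    def feature_dim(self) -> int:
        """Flattened dimension entering the linear projection."""
        channels = 1
        for layer in self.layers:
            if isinstance(layer, ConvSpec):
                channels = layer.filters
        return channels * self.spatial_trace()[-1] ** 2


def build_default_spec() -> CNNSpec:
    """The canonical 9-layer architecture (see module docstring)."""
    return CNNSpec(
        layers=(
            ConvSpec(20, 5),
            PoolSpec(2, 2),
            ConvSpec(32, 5),
            PoolSpec(2, 2),
            ConvSpec(32, 5),
            ReluSpec(),
            PoolSpec(2, 1),
            ConvSpec(40, 4),
        ),
        input_size=50,
        output_classes=2,
    )


@dataclass
class TrainConfig:
    """SGD hyperparameters; defaults are the package's documented choices."""

    learning_rate: float = 0.01
    batch_size: int = 32
    max_iterations: int = 1770
    seed: int = 0

    def validate(self) -> "TrainConfig":
        if self.learning_rate <= 0 or self.batch_size < 1 or self.max_iterations < 1:
            raise ValueError("hyperparameters must be positive")
        return self


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class _Conv:
    def __init__(self, in_channels: int, spec: ConvSpec, rng: np.random.Generator,
                 needs_input_grad: bool = True, dtype=np.float64):
        k = spec.kernel
        fan_in = in_channels * k * k
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                            (spec.filters, in_channels, k, k)).astype(dtype)
        self.b = np.zeros(spec.filters, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.needs_input_grad = needs_input_grad

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        o, c, k, _ = self.W.shape
        n, _, h, w = x.shape
        oh, ow = h - k + 1, w - k + 1
        windows = sliding_window_view(x, (k, k), axis=(2, 3))
        # im2col: (n*oh*ow, c*k*k) GEMM against the flattened filter bank
        cols = np.ascontiguousarray(windows.transpose(0, 2, 3, 1, 4, 5))
        cols = cols.reshape(n * oh * ow, c * k * k)
        out = cols @ self.W.reshape(o, -1).T + self.b
        if train:
            self._cols = cols
            self._x_shape = x.shape
        return out.reshape(n, oh, ow, o).transpose(0, 3, 1, 2)

    def backward(self, grad: np.ndarray) -> np.ndarray | None:
        o, c, k, _ = self.W.shape
        n, _, oh, ow = grad.shape
        g = np.ascontiguousarray(grad.transpose(0, 2, 3, 1)).reshape(-1, o)
        self.dW = (g.T @ self._cols).reshape(self.W.shape)
        self.db = g.sum(axis=0)
        if not self.needs_input_grad:
            return None
        dcols = (g @ self.W.reshape(o, -1)).reshape(n, oh, ow, c, k, k)
        dcols = dcols.transpose(0, 3, 1, 2, 4, 5)
        dx = np.zeros(self._x_shape, dtype=self.W.dtype)
        for i in range(k):  # col2im fold
            for j in range(k):
                dx[:, :, i:i + oh, j:j + ow] += dcols[:, :, :, :, i, j]
        return dx


class _Pool:
    def __init__(self, spec: PoolSpec):
        self.k = spec.kernel
        self.stride = spec.stride

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        windows = sliding_window_view(x, (self.k, self.k), axis=(2, 3))
        windows = windows[:, :, ::self.stride, ::self.stride]
        n, c, oh, ow = windows.shape[:4]
        flat = np.ascontiguousarray(windows).reshape(n, c, oh, ow, self.k * self.k)
        if train:
            self._x_shape = x.shape
            self._argmax = flat.argmax(axis=-1)
        return flat.max(axis=-1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, oh, ow = grad.shape
        h, w = self._x_shape[2:]
        dx = np.zeros(n * c * h * w, dtype=grad.dtype)
        base = (np.arange(n)[:, None, None, None] * c
                + np.arange(c)[None, :, None, None]) * (h * w)
        y0 = np.arange(oh)[None, None, :, None] * self.stride + self._argmax // self.k
        x0 = np.arange(ow)[None, None, None, :] * self.stride + self._argmax % self.k
        np.add.at(dx, (base + y0 * w + x0).ravel(), grad.ravel())
        return dx.reshape(self._x_shape)


class _Relu:
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class _Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 dtype=np.float64):
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), (n_out, n_in)).astype(dtype)
        self.b = np.zeros(n_out, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.W.T + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.dW = grad.T @ self._x
        self.db = grad.sum(axis=0)
        return grad @ self.W


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class _Network:
    """Feature layers + flatten + linear projection; softmax in the loss."""

    def __init__(self, spec: CNNSpec, rng: np.random.Generator,
                 dtype=np.float32):
        self.spec = spec
        self.dtype = np.dtype(dtype)
        self.feature_layers: List[object] = []
        channels = 1
        for i, layer_spec in enumerate(spec.layers):
            if isinstance(layer_spec, ConvSpec):
                # the input image needs no gradient, so the first layer skips dx
                self.feature_layers.append(
                    _Conv(channels, layer_spec, rng, needs_input_grad=i > 0,
                          dtype=self.dtype))
                channels = layer_spec.filters
            elif isinstance(layer_spec, PoolSpec):
                self.feature_layers.append(_Pool(layer_spec))
            elif isinstance(layer_spec, ReluSpec):
                self.feature_layers.append(_Relu())
        self.head = _Dense(spec.feature_dim, spec.output_classes, rng,
                           dtype=self.dtype)

    def features(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.feature_layers:
            x = layer.forward(x, train)
        return x.reshape(x.shape[0], -1)

    def logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.head.forward(self.features(x, train), train)

    def backward_from_logits(self, grad_logits: np.ndarray) -> None:
        grad = self.head.backward(grad_logits)
        n = grad.shape[0]
        channels = self.spec.feature_dim // self.spec.spatial_trace()[-1] ** 2
        side = self.spec.spatial_trace()[-1]
        grad = grad.reshape(n, channels, side, side)
        for layer in reversed(self.feature_layers):
            grad = layer.backward(grad)

    def parameters(self) -> List[Tuple[np.ndarray, np.ndarray]]:
        out = [(l.W, l.dW) for l in self.feature_layers if isinstance(l, _Conv)]
        out += [(l.b, l.db) for l in self.feature_layers if isinstance(l, _Conv)]
        out.append((self.head.W, self.head.dW))
        out.append((self.head.b, self.head.db))
        return out


def conv2d_forward(x: np.ndarray, weights: np.ndarray, bias: np.ndarray) -> np.ndarray:
    """Valid cross-correlation of (N,C,H,W) with (O,C,k,k) filters plus bias.

    The building block every conv layer uses; exposed for direct testing
    against an explicit quadruple-loop computation.
    """
    k = weights.shape[-1]
    cols = sliding_window_view(np.asarray(x, dtype=np.float64), (k, k), axis=(2, 3))
    return np.einsum("ncyxij,ocij->noyx", cols, weights, optimize=True) \
        + np.asarray(bias)[None, :, None, None]


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------

class SmallCNNClassifier(ClassifierMixin, BaseEstimator):
    """Two-class CNN trained with mini-batch SGD on softmax cross-entropy.

    Parameters
    ----------
    spec : CNNSpec, optional
        Architecture; defaults to :func:`build_default_spec`.
    learning_rate, batch_size, max_iter : SGD hyperparameters.
    random_state : int
        Seeds weight initialisation and batch shuffling.
    dtype : {"float32", "float64"}, default "float32"
        Arithmetic precision; single precision roughly halves training time
        and is ample for SGD, double precision is used for gradient checks.

    Attributes
    ----------
    classes_ : ndarray of the two class labels (sorted).
    loss_trace_, accuracy_trace_ : per-iteration mini-batch loss/accuracy.
    """

    def __init__(self, spec: CNNSpec | None = None, learning_rate: float = 0.01,
                 batch_size: int = 32, max_iter: int = 1770, random_state: int = 0,
                 dtype: str = "float32"):
        self.spec = spec
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_iter = max_iter
        self.random_state = random_state
        self.dtype = dtype

    # -- helpers ----------------------------------------------------------

    def _resolved_spec(self) -> CNNSpec:
        return self.spec if self.spec is not None else build_default_spec()

    def _as_input(self, X) -> np.ndarray:
        size = self._resolved_spec().input_size
        X = np.asarray(X, dtype=np.dtype(self.dtype))
        if X.ndim == 2 and X.shape == (size, size):
            X = X[None]
        elif X.ndim == 2:
            if X.shape[1] != size * size:
                raise ValueError(
                    f"expected rows of {size * size} pixels, got {X.shape[1]}"
                )
            X = X.reshape(X.shape[0], size, size)
        if X.ndim != 3 or X.shape[1:] != (size, size):
            raise ValueError(f"expected {size}x{size} patches, got shape {X.shape}")
        return X[:, None, :, :]

    def initialize(self, classes: Sequence = ("nodule", "nonnodule")) -> "SmallCNNClassifier":
        """Set up randomly initialised (untrained) parameters."""
        TrainConfig(self.learning_rate, self.batch_size, self.max_iter,
                    self.random_state).validate()
        rng = np.random.default_rng(self.random_state)
        self.network_ = _Network(self._resolved_spec(), rng,
                                 dtype=np.dtype(self.dtype))
        self.classes_ = np.asarray(sorted(classes))
        if len(self.classes_) != self._resolved_spec().output_classes:
            raise ValueError("number of classes must match the spec output")
        return self

    def _loss_and_grads(self, x: np.ndarray, y_idx: np.ndarray) -> Tuple[float, float]:
        """One forward/backward pass; returns (mean loss, batch accuracy)."""
        logits = self.network_.logits(x, train=True)
        probs = _softmax(logits)
        n = x.shape[0]
        loss = -np.mean(np.log(probs[np.arange(n), y_idx] + 1e-300))
        grad = probs.copy()
        grad[np.arange(n), y_idx] -= 1.0
        self.network_.backward_from_logits(grad / n)
        accuracy = float(np.mean(probs.argmax(axis=1) == y_idx))
        return float(loss), accuracy

    # -- sklearn API ------------------------------------------------------

    def fit(self, X, y) -> "SmallCNNClassifier":
        x = self._as_input(X)
        y = np.asarray(y)
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValueError("training data must contain at least 2 classes")
        self.initialize(classes)
        y_idx = np.searchsorted(self.classes_, y)
        rng = np.random.default_rng(self.random_state + 1)
        n = x.shape[0]
        losses, accs = [], []
        iteration = 0
        while iteration < self.max_iter:
            order = rng.permutation(n)
            for start in range(0, n, self.batch_size):
                if iteration >= self.max_iter:
                    break
                batch = order[start:start + self.batch_size]
                loss, acc = self._loss_and_grads(x[batch], y_idx[batch])
                for param, grad in self.network_.parameters():
                    param -= self.learning_rate * grad
                losses.append(loss)
                accs.append(acc)
                iteration += 1
        self.loss_trace_ = np.asarray(losses)
        self.accuracy_trace_ = np.asarray(accs)
        self.n_iter_ = iteration
        return self

    def _batched(self, x: np.ndarray, fn, width: int) -> np.ndarray:
        chunks = [fn(x[i:i + 256]) for i in range(0, x.shape[0], 256)]
        return np.concatenate(chunks) if chunks else np.empty((0, width))

    def predict_proba(self, X) -> np.ndarray:
        x = self._as_input(X)
        return self._batched(x, lambda c: _softmax(self.network_.logits(c)),
                             len(self.classes_))

    def predict(self, X) -> np.ndarray:
        return self.classes_[self.predict_proba(X).argmax(axis=1)]

    def transform(self, X) -> np.ndarray:
        """Learned feature vectors: the activations entering the projection."""
        x = self._as_input(X)
        return self._batched(x, self.network_.features,
                             self._resolved_spec().feature_dim)

    # -- persistence ------------------------------------------------------

    def save_params(self, path: str | Path) -> None:
        arrays = {"version": np.asarray(PARAMS_FORMAT_VERSION),
                  "classes": self.classes_.astype(str)}
        convs = [l for l in self.network_.feature_layers if isinstance(l, _Conv)]
        for i, conv in enumerate(convs):
            arrays[f"conv{i}_W"], arrays[f"conv{i}_b"] = conv.W, conv.b
        arrays["head_W"], arrays["head_b"] = self.network_.head.W, self.network_.head.b
        np.savez(path, **arrays)

    def load_params(self, path: str | Path) -> "SmallCNNClassifier":
        data = np.load(path, allow_pickle=False)
        if int(data["version"]) != PARAMS_FORMAT_VERSION:
            raise ValueError(f"unsupported parameter archive version {data['version']}")
        self.initialize(list(data["classes"]))
        convs = [l for l in self.network_.feature_layers if isinstance(l, _Conv)]
        for i, conv in enumerate(convs):
            conv.W[...] = data[f"conv{i}_W"]
            conv.b[...] = data[f"conv{i}_b"]
        self.network_.head.W[...] = data["head_W"]
        self.network_.head.b[...] = data["head_b"]
        return self


def forward(model: SmallCNNClassifier, patch: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Class probabilities and the 40-dim feature vector of one 50x50 patch."""
    probs = model.predict_proba(patch)[0]
    feats = model.transform(patch)[0]
    return probs, feats


def extract_features(model: SmallCNNClassifier, patches: np.ndarray) -> np.ndarray:
    """Learned feature vectors (one row per patch)."""
    return model.transform(patches)


def train(patches: np.ndarray, labels: Sequence, config: TrainConfig | None = None
          ) -> Tuple[SmallCNNClassifier, "np.ndarray"]:
    """Train the canonical network; returns (fitted model, accuracy trace)."""
    config = (config or TrainConfig()).validate()
    model = SmallCNNClassifier(
        learning_rate=config.learning_rate,
        batch_size=config.batch_size,
        max_iter=config.max_iterations,
        random_state=config.seed,
    ).fit(patches, labels)
    return model, model.accuracy_trace_
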