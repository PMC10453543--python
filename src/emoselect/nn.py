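"""Lightweight 1D convolutional network for emotion classification.

The classifier is a small 1D-CNN operating on per-window input vectors of
length ``n_channels * window_seconds * sampling_rate`` (2560 at 128 Hz for
the 10-channel / 2-s operating point, 5120 at 256 Hz). The default
architecture is four convolution blocks with (64, 32, 32, 16) filters and
kernel sizes (5, 5, 3, 1): batch normalization in the first three blocks,
average pooling (2, stride 2) at the end of the third, then flatten, a
hidden fully connected layer, dropout 0.5 and the output layer. Two dropout
layers with probability 0.25 sit inside the first two blocks. Binary tasks
use a single sigmoid unit trained with binary cross-entropy under Adadelta;
3-class tasks a softmax head with categorical cross-entropy under Adam.

Everything is implemented directly on NumPy arrays with explicit
backpropagation: convolution as an im2col GEMM (with a shift-matmul input
gradient), standard batch-norm and pooling gradients, and seeded uniform
fan-in weight initialization. Training is deterministic for a fixed seed.

``activation`` supports the standard rectifier ``max(0, a)`` and a softplus
variant ``ln(1 + e^a)``; the latter is the formula some descriptions print
under the name ReLU, kept selectable for fidelity.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

__all__ = [
    "ModelConfig",
    "activation",
    "binary_cross_entropy",
    "categorical_cross_entropy",
    "build_model",
    "Model",
    "train",
    "grid_search",
    "Cnn1DClassifier",
    "input_vector_length",
    "batch_element_count",
]

_EPS_CLIP = 1e-7


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelConfig:
    """Hyper-parameters of the 1D-CNN (defaults = the selected values)."""

    conv_layers: int = 4
    filters: tuple = (64, 32, 32, 16)
    kernels: tuple = (5, 5, 3, 1)
    batch_size: int = 64
    learning_rate: float = 0.005
    momentum: float = 0.9
    dropout_conv: float = 0.25
    dropout_fc: float = 0.5
    epochs: int = 100
    activation: str = "standard_relu"
    head: str | None = None            # sigmoid_binary / softmax_3class / auto
    optimizer: str | None = None       # adadelta / adam / sgd / auto per head
    hidden_units: int = 128
    pool_size: int = 2
    early_stop_patience: int | None = 10
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if len(self.filters) != self.conv_layers or \
                len(self.kernels) != self.conv_layers:
            raise ValueError("filters/kernels must match conv_layers")
        if self.activation not in ("standard_relu", "softplus"):
            raise ValueError(f"unknown activation {self.activation!r}")

    def replace(self, **kw) -> "ModelConfig":
        return dataclasses.replace(self, **kw)

    def resolve_head(self, n_classes: int) -> tuple[str, str]:
        """(head, optimizer) after applying the head<->optimizer pairing."""
        head = self.head
        if head is None:
            head = "sigmoid_binary" if n_classes == 2 else "softmax_3class"
        opt = self.optimizer
        if opt is None:
            opt = "adadelta" if head == "sigmoid_binary" else "adam"
        return head, opt


def input_vector_length(n_channels: int, window_seconds: float,
                        sfreq: float) -> int:
    """Length of one input vector: channels x window seconds x rate."""
    return int(round(n_channels * window_seconds * sfreq))


def batch_element_count(n_in: int, batch_size: int = 64) -> int:
    """Scalar elements in one training batch (batch_size x n_in)."""
    return int(batch_size) * int(n_in)


# ---------------------------------------------------------------------------
# activations and losses
# ---------------------------------------------------------------------------

def activation(alpha, variant: str = "standard_relu"):
    """Elementwise activation: rectifier or the softplus variant."""
    alpha = np.asarray(alpha, dtype=float)
    if variant == "standard_relu":
        return np.maximum(alpha, 0.0)
    if variant == "softplus":
        # stabilized ln(1 + e^a) = max(a, 0) + log1p(exp(-|a|))
        return np.maximum(alpha, 0.0) + np.log1p(np.exp(-np.abs(alpha)))
    raise ValueError(f"unknown activation variant {variant!r}")


def binary_cross_entropy(y, y_hat) -> float:
    """Mean binary cross-entropy with predictions clipped to
    ``[1e-7, 1 - 1e-7]``."""
    y = np.asarray(y, dtype=float).ravel()
    p = np.clip(np.asarray(y_hat, dtype=float).ravel(), _EPS_CLIP,
                1.0 - _EPS_CLIP)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def categorical_cross_entropy(y_onehot, y_hat) -> float:
    """Mean categorical cross-entropy with clipped predictions."""
    y = np.asarray(y_onehot, dtype=float)
    p = np.clip(np.asarray(y_hat, dtype=float), _EPS_CLIP, 1.0)
    return float(-np.mean(np.sum(y * np.log(p), axis=1)))


def _softmax(z):
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _sigmoid(z):
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class _Layer:
    params: dict
    grads: dict

    def __init__(self):
        self.params, self.grads = {}, {}

    def forward(self, x, training):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout):  # pragma: no cover - interface
        raise NotImplementedError


class _Conv1D(_Layer):
    def __init__(self, c_in, c_out, k, rng, dtype):
        super().__init__()
        limit = np.sqrt(1.0 / (c_in * k))
        self.params["W"] = rng.uniform(-limit, limit,
                                       size=(c_out, c_in, k)).astype(dtype)
        self.params["b"] = np.zeros(c_out, dtype=dtype)
        self.k = k

    def forward(self, x, training):
        # x: (B, C, L) -> (B, c_out, L - k + 1); valid convolution as one
        # GEMM on an im2col matrix (cached for the backward pass)
        w = self.params["W"]
        b_, c_in, l_in = x.shape
        l_out = l_in - self.k + 1
        cols = np.lib.stride_tricks.sliding_window_view(x, self.k, axis=2)
        cols = np.ascontiguousarray(cols.transpose(0, 2, 1, 3))
        cols = cols.reshape(b_ * l_out, c_in * self.k)
        self._cols, self._in_shape = cols, x.shape
        out = cols @ w.reshape(w.shape[0], -1).T
        out = out.reshape(b_, l_out, -1).transpose(0, 2, 1)
        return out + self.params["b"][None, :, None]

    def backward(self, dout):
        w = self.params["W"]
        b_, c_out, l_out = dout.shape
        self.grads["b"] = dout.sum(axis=(0, 2))
        dy = np.ascontiguousarray(dout.transpose(0, 2, 1))
        dy = dy.reshape(b_ * l_out, c_out)
        self.grads["W"] = (dy.T @ self._cols).reshape(w.shape)
        dx = np.zeros(self._in_shape, dtype=dout.dtype)
        for j in range(self.k):
            dx[:, :, j:j + l_out] += np.matmul(w[:, :, j].T, dout)
        self._cols = None
        return dx


class _BatchNorm1D(_Layer):
    def __init__(self, c, dtype, momentum=0.9, eps=1e-5):
        super().__init__()
        self.params["gamma"] = np.ones(c, dtype=dtype)
        self.params["beta"] = np.zeros(c, dtype=dtype)
        self.running_mean = np.zeros(c, dtype=dtype)
        self.running_var = np.ones(c, dtype=dtype)
        self.momentum, self.eps = momentum, eps

    @staticmethod
    def _reduce(x):
        # sum over (batch, length) via the contiguous last axis first
        return x.sum(axis=2).sum(axis=0)

    def forward(self, x, training):
        n = x.shape[0] * x.shape[2]
        if training:
            mean = self._reduce(x) / n
            var = self._reduce(x * x) / n - mean * mean
            np.maximum(var, 0.0, out=var)
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mean)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = (1.0 / np.sqrt(var + self.eps)).astype(x.dtype)
        xhat = (x - mean[None, :, None].astype(x.dtype)) * inv[None, :, None]
        self._cache = (xhat, inv) if training else None
        return self.params["gamma"][None, :, None] * xhat \
            + self.params["beta"][None, :, None]

    def backward(self, dout):
        xhat, inv = self._cache
        n = dout.shape[0] * dout.shape[2]
        self.grads["gamma"] = self._reduce(dout * xhat)
        self.grads["beta"] = self._reduce(dout)
        g = self.params["gamma"][None, :, None]
        dxhat = dout * g
        s1 = self._reduce(dxhat)[None, :, None]
        s2 = self._reduce(dxhat * xhat)[None, :, None]
        dx = (inv[None, :, None] / n) * (n * dxhat - s1 - xhat * s2)
        self._cache = None
        return dx


class _Activation(_Layer):
    def __init__(self, variant):
        super().__init__()
        self.variant = variant

    def forward(self, x, training):
        if self.variant == "standard_relu":
            self._mask = x > 0
            return x * self._mask
        self._x = x
        return np.maximum(x, 0.0) + np.log1p(np.exp(-np.abs(x)))

    def backward(self, dout):
        if self.variant == "standard_relu":
            return dout * self._mask
        return dout * _sigmoid(self._x)


class _AvgPool1D(_Layer):
    def __init__(self, size=2):
        super().__init__()
        self.size = size

    def forward(self, x, training):
        b, c, l = x.shape
        self._l_in = l
        l_out = l // self.size
        self._l_used = l_out * self.size
        return x[:, :, :self._l_used].reshape(b, c, l_out, self.size).mean(-1)

    def backward(self, dout):
        b, c, l_out = dout.shape
        dx = np.zeros((b, c, self._l_in), dtype=dout.dtype)
        dx[:, :, :self._l_used] = np.repeat(dout / self.size, self.size,
                                            axis=2)
        return dx


class _Dropout(_Layer):
    def __init__(self, p, rng):
        super().__init__()
        self.p, self.rng = p, rng

    def forward(self, x, training):
        if not training or self.p <= 0:
            self._mask = None
            return x
        u = self.rng.random(x.shape, dtype=np.float32)
        self._mask = (u >= self.p).astype(x.dtype) / x.dtype.type(1.0 - self.p)
        return x * self._mask

    def backward(self, dout):
        if self._mask is None:
            return dout
        return dout * self._mask


class _Flatten(_Layer):
    def forward(self, x, training):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class _Dense(_Layer):
    def __init__(self, n_in, n_out, rng, dtype):
        super().__init__()
        limit = np.sqrt(1.0 / n_in)
        self.params["W"] = rng.uniform(-limit, limit,
                                       size=(n_in, n_out)).astype(dtype)
        self.params["b"] = np.zeros(n_out, dtype=dtype)

    def forward(self, x, training):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout):
        self.grads["W"] = self._x.T @ dout
        self.grads["b"] = dout.sum(axis=0)
        dx = dout @ self.params["W"].T
        self._x = None
        return dx


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

class Model:
    """Layer stack plus head; built by :func:`build_model`."""

    def __init__(self, layers, head, config, n_in, n_classes, seed):
        self.layers = layers
        self.head = head
        self.config = config
        self.n_in = n_in
        self.n_classes = n_classes
        self.seed = seed
        self.history: dict = {"loss": [], "accuracy": []}

    def parameters(self):
        for i, layer in enumerate(self.layers):
            for name, p in layer.params.items():
                yield (i, name), layer, p

    def count_params(self) -> int:
        return sum(p.size for _, _, p in self.parameters())

    def _forward(self, x, training):
        out = x.reshape(x.shape[0], 1, self.n_in)
        for layer in self.layers:
            out = layer.forward(out, training)
        return out

    def predict_proba(self, x, batch_size=256):
        x = np.asarray(x, dtype=self.config.dtype)
        probs = []
        for start in range(0, x.shape[0], batch_size):
            z = self._forward(x[start:start + batch_size], training=False)
            if self.head == "sigmoid_binary":
                p1 = _sigmoid(z).ravel()
                probs.append(np.column_stack([1.0 - p1, p1]))
            else:
                probs.append(_softmax(z))
        return np.concatenate(probs)

    def loss_and_grad(self, x, y_enc, training=True):
        """Forward + backward on one batch; returns (loss, n_correct)."""
        z = self._forward(x, training)
        b = x.shape[0]
        if self.head == "sigmoid_binary":
            p = _sigmoid(z).ravel()
            loss = binary_cross_entropy(y_enc, p)
            correct = int(np.sum((p >= 0.5) == (y_enc >= 0.5)))
            dz = ((p - y_enc) / b).reshape(z.shape).astype(z.dtype)
        else:
            p = _softmax(z)
            loss = categorical_cross_entropy(y_enc, p)
            correct = int(np.sum(np.argmax(p, axis=1)
                                 == np.argmax(y_enc, axis=1)))
            dz = ((p - y_enc) / b).astype(z.dtype)
        dout = dz
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return loss, correct


def build_model(config: ModelConfig, n_in: int, n_classes: int,
                seed: int = 0) -> Model:
    """Assemble the (untrained) layer stack for the given geometry.

    Blocks: conv+BN+act (+dropout 0.25 in the first two), average pooling at
    the end of the penultimate block, no BN in the last block, then flatten,
    hidden dense, dropout 0.5 and the output head. Raises if ``n_in`` is too
    small for the receptive field.
    """
    rng = np.random.default_rng(seed)
    dtype = np.dtype(config.dtype).type
    head, _ = config.resolve_head(n_classes)
    layers: list[_Layer] = []
    c_in, length = 1, n_in
    for i, (f, k) in enumerate(zip(config.filters, config.kernels)):
        length = length - k + 1
        if length < 1:
            raise ValueError(
                f"input length {n_in} too small for the receptive field")
        layers.append(_Conv1D(c_in, f, k, rng, dtype))
        if i < config.conv_layers - 1:
            layers.append(_BatchNorm1D(f, dtype))
        layers.append(_Activation(config.activation))
        if i < 2:
            layers.append(_Dropout(config.dropout_conv, rng))
        if i == config.conv_layers - 2:
            layers.append(_AvgPool1D(config.pool_size))
            length = length // config.pool_size
            if length < 1:
                raise ValueError("input collapsed to zero length after pooling")
        c_in = f
    layers.append(_Flatten())
    layers.append(_Dense(length * c_in, config.hidden_units, rng, dtype))
    layers.append(_Activation(config.activation))
    layers.append(_Dropout(config.dropout_fc, rng))
    out_units = 1 if head == "sigmoid_binary" else n_classes
    layers.append(_Dense(config.hidden_units, out_units, rng, dtype))
    return Model(layers, head, config, n_in, n_classes, seed)


# ---------------------------------------------------------------------------
# optimizers
# ---------------------------------------------------------------------------

class _Adadelta:
    """Canonical Adadelta: rho from the momentum setting, no learning-rate
    multiplier (the method derives its own step scale)."""

    def __init__(self, rho=0.9, eps=1e-6, lr=1.0):
        self.rho, self.eps, self.lr = rho, eps, lr
        self.state = {}

    def update(self, key, p, g):
        eg, ed = self.state.setdefault(key, (np.zeros_like(p),
                                             np.zeros_like(p)))
        eg = self.rho * eg + (1 - self.rho) * g * g
        dx = -np.sqrt(ed + self.eps) / np.sqrt(eg + self.eps) * g
        ed = self.rho * ed + (1 - self.rho) * dx * dx
        self.state[key] = (eg, ed)
        p += self.lr * dx


class _Adam:
    def __init__(self, lr=0.005, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.state, self.t = {}, 0

    def begin_step(self):
        self.t += 1

    def update(self, key, p, g):
        m, v = self.state.setdefault(key, (np.zeros_like(p),
                                           np.zeros_like(p)))
        m = self.b1 * m + (1 - self.b1) * g
        v = self.b2 * v + (1 - self.b2) * g * g
        self.state[key] = (m, v)
        mhat = m / (1 - self.b1 ** self.t)
        vhat = v / (1 - self.b2 ** self.t)
        p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class _SGD:
    """Plain gradient descent with optional momentum (the literal
    ``W <- W - eta dE/dW`` update when momentum is 0)."""

    def __init__(self, lr=0.005, momentum=0.0):
        self.lr, self.momentum = lr, momentum
        self.state = {}

    def update(self, key, p, g):
        v = self.state.setdefault(key, np.zeros_like(p))
        v = self.momentum * v - self.lr * g
        self.state[key] = v
        p += v


def _make_optimizer(name: str, config: ModelConfig):
    if name == "adadelta":
        return _Adadelta(rho=config.momentum)
    if name == "adam":
        return _Adam(lr=config.learning_rate)
    if name == "sgd":
        return _SGD(lr=config.learning_rate, momentum=config.momentum)
    raise ValueError(f"unknown optimizer {name!r}")


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _encode(y, classes, head):
    lookup = {c: i for i, c in enumerate(classes)}
    idx = np.array([lookup[v] for v in y])
    if head == "sigmoid_binary":
        return idx.astype(float)
    onehot = np.zeros((len(y), len(classes)))
    onehot[np.arange(len(y)), idx] = 1.0
    return onehot


def train(model: Model, x, y, config: ModelConfig | None = None,
          seed: int = 0, classes=None) -> Model:
    """Mini-batch training with per-epoch loss/accuracy history.

    Stops early (when ``early_stop_patience`` is set) if the epoch loss has
    not improved by 1e-4 within the patience window, or once training
    accuracy stays >= 99.9% for three consecutive epochs. Training is
    deterministic for fixed seed and thread configuration. A non-finite
    loss aborts with diagnostics.
    """
    config = config or model.config
    x = np.asarray(x, dtype=config.dtype)
    y = np.asarray(y)
    classes = np.asarray(sorted(np.unique(y)) if classes is None else classes)
    _, opt_name = config.resolve_head(len(classes))
    y_enc = _encode(y, classes, model.head)
    opt = _make_optimizer(opt_name, config)
    rng = np.random.default_rng(seed)
    n = x.shape[0]
    best_loss, since_best, high_acc_streak = np.inf, 0, 0
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses, n_correct = [], 0
        for start in range(0, n, config.batch_size):
            sel = order[start:start + config.batch_size]
            if hasattr(opt, "begin_step"):
                opt.begin_step()
            loss, correct = model.loss_and_grad(x[sel], y_enc[sel],
                                                training=True)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss {loss} at epoch {epoch}, batch "
                    f"{start // config.batch_size}; aborting")
            for (i, name), layer, p in model.parameters():
                opt.update((i, name), p, layer.grads[name].astype(p.dtype))
            losses.append(loss)
            n_correct += correct
        acc = n_correct / n  # running training accuracy over the epoch
        epoch_loss = float(np.mean(losses))
        model.history["loss"].append(epoch_loss)
        model.history["accuracy"].append(acc)
        if config.early_stop_patience:
            if epoch_loss < best_loss - 1e-4:
                best_loss, since_best = epoch_loss, 0
            else:
                since_best += 1
            high_acc_streak = high_acc_streak + 1 if acc >= 0.999 else 0
            if since_best >= config.early_stop_patience or high_acc_streak >= 3:
                break
    model.classes_ = classes
    return model


# ---------------------------------------------------------------------------
# grid search
# ---------------------------------------------------------------------------

def grid_search(space: dict, x_train, y_train, x_val, y_val,
                budget: int | None = None, seed: int = 0,
                base: ModelConfig | None = None):
    """Exhaustive (or budget-capped) search over config overrides.

    ``space`` maps ModelConfig field names to candidate value lists. Returns
    ``(best_config, results)`` where results is a list of
    ``(config, val_accuracy, n_params)``; ties in accuracy go to the model
    with fewer parameters, then to grid order.
    """
    from sklearn.model_selection import ParameterGrid

    if not space or any(len(v) == 0 for v in space.values()):
        raise ValueError("empty grid")
    base = base or ModelConfig()
    points = list(ParameterGrid({k: list(v) for k, v in space.items()}))
    if budget is not None:
        points = points[:budget]
    classes = np.asarray(sorted(np.unique(y_train)))
    results = []
    for point in points:
        config = base.replace(**point)
        model = build_model(config, x_train.shape[1], len(classes), seed=seed)
        train(model, x_train, y_train, config, seed=seed, classes=classes)
        probs = model.predict_proba(x_val)
        acc = float(np.mean(classes[np.argmax(probs, axis=1)] == y_val))
        results.append((config, acc, model.count_params()))
    best = max(enumerate(results),
               key=lambda t: (t[1][1], -t[1][2], -t[0]))[1][0]
    return best, results


# ---------------------------------------------------------------------------
# sklearn estimator
# ---------------------------------------------------------------------------

class Cnn1DClassifier(BaseEstimator, ClassifierMixin):
    """Scikit-learn classifier facade over the NumPy 1D-CNN.

    ``X`` is (n_samples, n_in) with one row per window vector. Binary
    problems get a sigmoid head trained with Adadelta; 3-class problems a
    softmax head with Adam (both overridable).
    """

    def __init__(self, conv_layers: int = 4, filters: tuple = (64, 32, 32, 16),
                 kernels: tuple = (5, 5, 3, 1), batch_size: int = 64,
                 learning_rate: float = 0.005, momentum: float = 0.9,
                 dropout_conv: float = 0.25, dropout_fc: float = 0.5,
                 epochs: int = 100, activation: str = "standard_relu",
                 head: str | None = None, optimizer: str | None = None,
                 hidden_units: int = 128, pool_size: int = 2,
                 early_stop_patience: int | None = 10, dtype: str = "float32",
                 random_state: int = 0):
        self.conv_layers = conv_layers
        self.filters = filters
        self.kernels = kernels
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.dropout_conv = dropout_conv
        self.dropout_fc = dropout_fc
        self.epochs = epochs
        self.activation = activation
        self.head = head
        self.optimizer = optimizer
        self.hidden_units = hidden_units
        self.pool_size = pool_size
        self.early_stop_patience = early_stop_patience
        self.dtype = dtype
        self.random_state = random_state

    def _config(self) -> ModelConfig:
        fields = {f.name for f in dataclasses.fields(ModelConfig)}
        kw = {k: v for k, v in self.get_params().items() if k in fields}
        kw["filters"] = tuple(kw["filters"])
        kw["kernels"] = tuple(kw["kernels"])
        return ModelConfig(**kw)

    def fit(self, X, y):
        X = np.asarray(X)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (n_samples, n_in)")
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y disagree on n_samples")
        self.classes_ = np.asarray(sorted(np.unique(y)))
        if self.classes_.size < 2:
            raise ValueError("need at least two classes")
        config = self._config()
        head, _ = config.resolve_head(self.classes_.size)
        if head == "sigmoid_binary" and self.classes_.size != 2:
            raise ValueError("sigmoid head requires exactly two classes")
        self.model_ = build_model(config, X.shape[1], self.classes_.size,
                                  seed=self.random_state)
        train(self.model_, X, y, config, seed=self.random_state,
              classes=self.classes_)
        self.history_ = self.model_.history
        return self

    def predict_proba(self, X):
        if not hasattr(self, "model_"):
            raise RuntimeError("classifier is not fitted")
        return self.model_.predict_proba(np.asarray(X))

    def predict(self, X):
        probs = self.predict_proba(X)
        return self.classes_[np.argmax(probs, axis=1)]
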