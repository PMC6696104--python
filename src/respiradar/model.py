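"""Parameterized 1D convolutional network for respiration-window classification.

Architecture family: ``depth`` x [conv1d(kernel KS, KC filters, same padding,
stride 1) -> ReLU -> maxpool(2)] -> flatten -> dropout -> dense DLNC1 (ReLU)
-> dense DLNC2 (ReLU) -> 5-way softmax.  Dropout is parameterized by the KEEP
fraction (default 0.6: 60% of the serialized features are used each step).

The network is implemented directly on numpy (float32, im2col convolutions
via BLAS matmuls, Adam optimizer, softmax cross-entropy); all stochasticity
(weight init, shuffling, dropout masks) flows from one seeded Generator, so a
fixed seed reproduces a run exactly on one machine.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .datatypes import CLASS_INDEX, CLASS_ORDER, PatternClass, WindowSample

__all__ = [
    "ParamCombo",
    "TrainConfig",
    "Model1D",
    "TrainedModel",
    "ArchitectureError",
    "REFERENCE_COMBO",
    "build_model",
    "train",
    "predict",
    "flatten_length",
    "standardize_windows",
]


class ArchitectureError(ValueError):
    """A parameter combination that cannot produce a valid layer stack."""


@dataclass(frozen=True)
class ParamCombo:
    """One concrete hyperparameter assignment.

    ``conv_layers`` is a (kernel_size, kernel_count) pair per convolutional
    layer; ``dense_neurons`` the two fully-connected layer widths.
    """

    conv_layers: tuple[tuple[int, int], ...]
    dense_neurons: tuple[int, int]
    dropout_keep: float = 0.6

    def __post_init__(self) -> None:
        if len(self.conv_layers) < 1:
            raise ValueError("at least one convolutional layer is required")
        for i, (ks, kc) in enumerate(self.conv_layers):
            if ks < 1 or ks % 2 == 0:
                raise ValueError(
                    f"conv layer {i + 1}: kernel size must be odd positive, got {ks}")
            if kc < 1:
                raise ValueError(
                    f"conv layer {i + 1}: kernel count must be >= 1, got {kc}")
        if len(self.dense_neurons) != 2 or min(self.dense_neurons) < 1:
            raise ValueError("dense_neurons must be two positive widths")
        if not (0.0 < self.dropout_keep <= 1.0):
            raise ValueError("dropout_keep must lie in (0, 1]")

    @property
    def depth(self) -> int:
        return len(self.conv_layers)


#: the architecture used for the final evaluation: depth 3, kernels 29/25/21
#: with 64/64/128 filters, dense layers 2048/1024
REFERENCE_COMBO = ParamCombo(
    conv_layers=((29, 64), (25, 64), (21, 128)),
    dense_neurons=(2048, 1024),
)


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 40
    batch_size: int = 10
    seed: int = 0
    n_classes: int = 5
    input_len: int = 250
    learning_rate: float = 1e-3

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if self.input_len < 1:
            raise ValueError("input_len must be >= 1")


def flatten_length(combo: ParamCombo, input_len: int) -> int:
    """Serialized feature count after the conv/pool stack.

    Same-padding stride-1 convolutions preserve length; each pool-2 halves it
    (floor).  Raises :class:`ArchitectureError` naming the layer at which the
    pooled length would reach zero.
    """
    L = input_len
    for i, (_ks, _kc) in enumerate(combo.conv_layers):
        L = L // 2
        if L == 0:
            raise ArchitectureError(
                f"pooled length reaches 0 after conv layer {i + 1} "
                f"(input_len={input_len}, depth={combo.depth})")
    return L * combo.conv_layers[-1][1]


def standardize_windows(samples: Sequence[WindowSample]) -> np.ndarray:
    """Stack windows and standardize each to zero mean, unit variance.

    Radar amplitudes carry an arbitrary scale, so every window is normalized
    independently before entering any classifier.
    """
    X = np.stack([s.values for s in samples]).astype(np.float32)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    return (X - mu) / (sd + np.float32(1e-8))


def _labels_to_indices(samples: Sequence[WindowSample]) -> np.ndarray:
    try:
        return np.array([CLASS_INDEX[s.label] for s in samples], dtype=np.int64)
    except KeyError as exc:  # pragma: no cover - defensive
        raise ValueError(f"unknown class label: {exc.args[0]}") from exc


# ---------------------------------------------------------------- layer math

def _conv1d_cols(x: np.ndarray, K: int) -> np.ndarray:
    """im2col for same-padded stride-1 1-D convolution.

    x: (N, L, Cin) -> (N*L, K*Cin) with kernel-tap-major ordering.
    """
    N, L, Cin = x.shape
    pad = K // 2
    xp = np.pad(x, ((0, 0), (pad, pad), (0, 0)))
    cols = sliding_window_view(xp, K, axis=1)          # (N, L, Cin, K)
    return np.ascontiguousarray(cols.transpose(0, 1, 3, 2)).reshape(N * L, K * Cin)


def _conv1d_forward(x, W, b):
    """x (N,L,Cin), W (K,Cin,Cout) -> y (N,L,Cout); returns (y, cols)."""
    N, L, Cin = x.shape
    K, _, Cout = W.shape
    cols = _conv1d_cols(x, K)
    y = cols @ W.reshape(K * Cin, Cout)
    y += b
    return y.reshape(N, L, Cout), cols


def _conv1d_backward(dy, cols, W, x_shape):
    """Gradients of a same-padded conv: (dx, dW, db)."""
    N, L, Cin = x_shape
    K, _, Cout = W.shape
    dyf = dy.reshape(N * L, Cout)
    dW = (cols.T @ dyf).reshape(K, Cin, Cout)
    db = dyf.sum(axis=0)
    # adjoint of a same-padded odd-K conv is the same-padded conv with the
    # kernel flipped along taps and transposed in channels
    W_flip = W[::-1].transpose(0, 2, 1)                # (K, Cout, Cin)
    dcols = _conv1d_cols(dy, K)
    dx = (dcols @ W_flip.reshape(K * Cout, Cin)).reshape(N, L, Cin)
    return dx, dW, db


def _maxpool2_forward(x):
    """Non-overlapping max pool of size 2 (odd tail dropped).

    Ties route the gradient to the earlier sample, matching a first-argmax
    convention.
    """
    N, L, C = x.shape
    L2 = L // 2
    a = x[:, 0:2 * L2:2]
    b = x[:, 1:2 * L2:2]
    right = b > a
    y = np.where(right, b, a)
    return y, (right, x.shape)


def _maxpool2_backward(dy, cache):
    right, (N, L, C) = cache
    L2 = L // 2
    dx = np.zeros((N, L, C), dtype=dy.dtype)
    left = ~right
    dx[:, 0:2 * L2:2][left] = dy[left]
    dx[:, 1:2 * L2:2][right] = dy[right]
    return dx


def _softmax(z):
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


# ------------------------------------------------------------------- network

class Model1D:
    """An (initially untrained) network built from a :class:`ParamCombo`."""

    def __init__(self, combo: ParamCombo, cfg: TrainConfig):
        self.combo = combo
        self.cfg = cfg
        self.flatten_len = flatten_length(combo, cfg.input_len)  # validates
        self.params: Optional[list[np.ndarray]] = None

    # -- parameter handling ------------------------------------------------
    def init_weights(self, rng: np.random.Generator) -> None:
        params: list[np.ndarray] = []
        cin = 1
        for ks, kc in self.combo.conv_layers:
            std = np.sqrt(2.0 / (ks * cin))
            params.append(rng.normal(0.0, std, (ks, cin, kc)).astype(np.float32))
            params.append(np.zeros(kc, dtype=np.float32))
            cin = kc
        widths = [self.flatten_len, *self.combo.dense_neurons, self.cfg.n_classes]
        for i in range(len(widths) - 1):
            fan_in, fan_out = widths[i], widths[i + 1]
            gain = 2.0 if i < len(widths) - 2 else 1.0  # ReLU layers vs output
            std = np.sqrt(gain / fan_in)
            params.append(rng.normal(0.0, std, (fan_in, fan_out)).astype(np.float32))
            params.append(np.zeros(fan_out, dtype=np.float32))
        self.params = params

    # -- forward/backward ---------------------------------------------------
    def forward(self, X: np.ndarray, train: bool = False,
                rng: Optional[np.random.Generator] = None):
        """X (N, input_len) standardized -> class probabilities (N, n_classes).

        Returns ``(probs, cache)``; the cache is consumed by :meth:`backward`.
        """
        assert self.params is not None, "weights not initialized"
        p = self.params
        h = np.asarray(X, dtype=np.float32)[:, :, None]  # (N, L, 1)
        cache: list = []
        k = 0
        for _ in self.combo.conv_layers:
            W, b = p[k], p[k + 1]
            z, cols = _conv1d_forward(h, W, b)
            relu_mask = z > 0
            a = z * relu_mask
            pooled, pool_cache = _maxpool2_forward(a)
            cache.append(("conv", h.shape, cols, relu_mask, pool_cache))
            h = pooled
            k += 2
        N = h.shape[0]
        flat = h.reshape(N, -1)
        keep = np.float32(self.combo.dropout_keep)
        if train and keep < 1.0:
            if rng is None:
                raise ValueError("training forward pass needs an rng for dropout")
            mask = (rng.random(flat.shape) < keep).astype(np.float32) / keep
            flat = flat * mask
        else:
            mask = None
        cache.append(("dropout", h.shape, mask))
        h2 = flat
        for j in range(2):
            W, b = p[k], p[k + 1]
            z = h2 @ W + b
            relu_mask = z > 0
            cache.append(("dense", h2, relu_mask))
            h2 = z * relu_mask
            k += 2
        W, b = p[k], p[k + 1]
        logits = h2 @ W + b
        cache.append(("out", h2))
        return _softmax(logits), cache

    def backward(self, probs: np.ndarray, y: np.ndarray, cache: list):
        """Cross-entropy gradient for all parameters (same order as params)."""
        p = self.params
        N = probs.shape[0]
        dz = probs.copy()
        dz[np.arange(N), y] -= 1.0
        dz /= np.float32(N)

        grads: list[np.ndarray] = [None] * len(p)  # type: ignore[list-item]
        k = len(p) - 2
        tag, h2 = cache[-1]
        grads[k] = h2.T @ dz
        grads[k + 1] = dz.sum(axis=0)
        dh = dz @ p[k].T
        ci = len(cache) - 2
        for _ in range(2):
            k -= 2
            tag, h_in, relu_mask = cache[ci]
            dz = dh * relu_mask
            grads[k] = h_in.T @ dz
            grads[k + 1] = dz.sum(axis=0)
            dh = dz @ p[k].T
            ci -= 1
        tag, pooled_shape, mask = cache[ci]
        if mask is not None:
            dh = dh * mask
        dh = dh.reshape(pooled_shape)
        ci -= 1
        for _ in self.combo.conv_layers:
            k -= 2
            tag, x_shape, cols, relu_mask, pool_cache = cache[ci]
            dz3 = _maxpool2_backward(dh, pool_cache) * relu_mask
            dh, grads[k], grads[k + 1] = _conv1d_backward(dz3, cols, p[k], x_shape)
            ci -= 1
        return grads


try:  # fused single-pass update; the step is memory-bound on ~10M parameters
    from numba import njit as _njit

    @_njit(cache=False)
    def _adam_kernel(p, g, m, v, lr_t, b1, b2, c1, c2, eps):  # pragma: no cover
        # moments of weights with (near-)zero gradient decay exponentially;
        # flush them to zero before they reach float32 subnormal range, where
        # x86 arithmetic is an order of magnitude slower
        tiny = np.float32(1e-30)
        for i in range(p.size):
            gi = g[i]
            mi = b1 * m[i] + c1 * gi
            vi = b2 * v[i] + c2 * gi * gi
            if -tiny < mi < tiny:
                mi = np.float32(0.0)
            if vi < tiny:
                vi = np.float32(0.0)
            m[i] = mi
            v[i] = vi
            p[i] -= lr_t * mi / (np.sqrt(vi) + eps)

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a declared dependency
    _HAVE_NUMBA = False


class _Adam:
    """Adam with bias correction, in-place in float32.

    The update is fused into a single pass per parameter array (numba);
    element-wise arithmetic matches the plain-numpy fallback exactly.
    """

    def __init__(self, params, lr=1e-3, b1=0.9, b2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.scratch = None if _HAVE_NUMBA else [np.empty_like(p) for p in params]
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        lr_t = np.float32(
            self.lr * np.sqrt(1 - self.b2 ** self.t) / (1 - self.b1 ** self.t))
        b1, b2 = np.float32(self.b1), np.float32(self.b2)
        c1, c2 = np.float32(1 - self.b1), np.float32(1 - self.b2)
        eps = np.float32(self.eps)
        if _HAVE_NUMBA:
            for p, g, m, v in zip(params, grads, self.m, self.v):
                _adam_kernel(p.ravel(), np.ascontiguousarray(g).ravel(),
                             m.ravel(), v.ravel(), lr_t, b1, b2, c1, c2, eps)
            return
        tiny = np.float32(1e-30)
        for p, g, m, v, s in zip(params, grads, self.m, self.v, self.scratch):
            m *= b1
            np.multiply(g, c1, out=s)
            m += s
            m[np.abs(m) < tiny] = 0.0
            v *= b2
            np.multiply(g, g, out=s)
            s *= c2
            v += s
            v[v < tiny] = 0.0
            np.sqrt(v, out=s)
            s += eps
            np.divide(m, s, out=s)
            s *= lr_t
            p -= s


@dataclass
class TrainedModel:
    """A trained network: architecture, weights, and per-epoch history."""

    architecture: ParamCombo
    config: TrainConfig
    weights: list[np.ndarray]
    history: pd.DataFrame
    classes: tuple[PatternClass, ...] = CLASS_ORDER

    def _network(self) -> Model1D:
        net = Model1D(self.architecture, self.config)
        net.params = self.weights
        return net


def build_model(combo: ParamCombo, cfg: TrainConfig = TrainConfig(),
                dropout_as_drop_fraction: bool = False) -> Model1D:
    """Validate a parameter combination and return the untrained network.

    ``dropout_as_drop_fraction`` flips the dropout interpretation (treat the
    configured ratio as the fraction dropped rather than kept).
    """
    if dropout_as_drop_fraction:
        combo = replace(combo, dropout_keep=1.0 - combo.dropout_keep)
    return Model1D(combo, cfg)


def _eval_metrics(net: Model1D, X: np.ndarray, y: np.ndarray,
                  batch: int = 64) -> tuple[float, float]:
    n = X.shape[0]
    loss_sum = 0.0
    correct = 0
    for i in range(0, n, batch):
        probs, _ = net.forward(X[i:i + batch], train=False)
        yi = y[i:i + batch]
        loss_sum += -np.log(
            np.maximum(probs[np.arange(len(yi)), yi], 1e-12)).sum()
        correct += int((probs.argmax(axis=1) == yi).sum())
    return correct / n, loss_sum / n


def train(
    model: Model1D,
    train_samples: Sequence[WindowSample],
    val_samples: Sequence[WindowSample] = (),
    cfg: Optional[TrainConfig] = None,
) -> TrainedModel:
    """Train with softmax cross-entropy and Adam; record per-epoch history.

    Weight initialization, batch shuffling, and dropout masks all derive from
    ``cfg.seed``; a fixed seed reproduces the run on one device.
    """
    cfg = cfg or model.cfg
    if len(train_samples) == 0:
        raise ValueError("empty training set")
    X = standardize_windows(train_samples)
    if X.shape[1] != cfg.input_len:
        raise ValueError(
            f"window length {X.shape[1]} != configured input_len {cfg.input_len}")
    y = _labels_to_indices(train_samples)
    if len(val_samples):
        Xv = standardize_windows(val_samples)
        yv = _labels_to_indices(val_samples)
    else:
        Xv = yv = None

    rng = np.random.default_rng(cfg.seed)
    model.init_weights(rng)
    opt = _Adam(model.params, lr=cfg.learning_rate)
    n = X.shape[0]
    rows = []
    for epoch in range(1, cfg.epochs + 1):
        perm = rng.permutation(n)
        loss_sum = 0.0
        correct = 0
        for i in range(0, n, cfg.batch_size):
            sel = perm[i:i + cfg.batch_size]
            xb, yb = X[sel], y[sel]
            probs, cache = model.forward(xb, train=True, rng=rng)
            loss_sum += -np.log(
                np.maximum(probs[np.arange(len(yb)), yb], 1e-12)).sum()
            correct += int((probs.argmax(axis=1) == yb).sum())
            grads = model.backward(probs, yb, cache)
            opt.step(model.params, grads)
        row = {
            "epoch": epoch,
            "train_acc": correct / n,
            "train_loss": loss_sum / n,
        }
        if Xv is not None:
            va, vl = _eval_metrics(model, Xv, yv)
            row["val_acc"], row["val_loss"] = va, vl
        else:
            row["val_acc"] = row["val_loss"] = float("nan")
        rows.append(row)
    return TrainedModel(architecture=model.combo, config=cfg,
                        weights=model.params, history=pd.DataFrame(rows))


def predict(
    model: TrainedModel,
    samples: Sequence[WindowSample],
    batch_size: int = 64,
) -> tuple[np.ndarray, list[PatternClass]]:
    """Class probabilities and argmax labels (ties break to the lowest index).

    Scores per sample are non-negative and sum to 1.
    """
    if len(samples) == 0:
        return np.zeros((0, len(model.classes))), []
    net = model._network()
    X = standardize_windows(samples)
    if X.shape[1] != model.config.input_len:
        raise ValueError(
            f"window length {X.shape[1]} != model input_len {model.config.input_len}")
    chunks = []
    for i in range(0, X.shape[0], batch_size):
        probs, _ = net.forward(X[i:i + batch_size], train=False)
        chunks.append(probs)
    probs = np.concatenate(chunks).astype(np.float64)
    labels = [model.classes[int(i)] for i in probs.argmax(axis=1)]
    return probs, labels
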