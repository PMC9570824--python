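"""CRNN dense detector for 60-s respiratory segments, in NumPy.

The network maps one z-scored 480-sample window (60 s at 8 Hz) to 60
per-second class-probability vectors:

    4 x [ (conv1d-BN-ReLU) x 2, maxpool, dropout ]   64 filters, kernel 3
    bidirectional LSTM, 128 units per direction
    frame-wise FC 128 + ReLU + dropout
    frame-wise FC n_classes + softmax

The max-pool strides are (2, 2, 2, 1), so the temporal axis shrinks by
exactly 8: 480 input samples -> 60 output frames at 1 Hz, aligned with the
1-s reference labels.  The training objective is frame-wise cross-entropy
plus soft Dice loss (smoothing 1), the optimizer is Adam.

Everything — layers, backpropagation (including backprop through time for
the BiLSTM), the loss gradient, Adam — is implemented here on NumPy
arrays; gradients are validated against central differences in the test
suite.  Arithmetic defaults to float32 for speed; a float64 switch exists
for gradient checking.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

N_FRAMES = 60
SEGMENT_SAMPLES = 480


class ConfigError(ValueError):
    pass


class ModelInputError(ValueError):
    pass


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    The product of ``pool_strides`` must equal the input-rate /
    label-rate ratio (8), otherwise per-frame predictions would not line
    up with the 1-s labels.
    """

    n_classes: int = 2
    conv_filters: int = 64
    kernel: int = 3
    conv_blocks: int = 4
    pool_strides: tuple[int, ...] = (2, 2, 2, 1)
    rnn_units: int = 128
    fc_units: int = 128
    dropout: float = 0.2
    seed: int = 0
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if self.n_classes not in (2, 4):
            raise ConfigError("n_classes must be 2 (binary) or 4 (multiclass)")
        if len(self.pool_strides) != self.conv_blocks:
            raise ConfigError("need one pool stride per conv block")
        if int(np.prod(self.pool_strides)) != 8:
            raise ConfigError(
                f"pool strides {self.pool_strides} downsample by "
                f"{int(np.prod(self.pool_strides))}, not 8: per-frame outputs "
                "would not align with the 1-s labels"
            )


@dataclass
class FramePredictions:
    """Per-second class probabilities for one segment.

    probs : (n_frames, n_classes), rows sum to 1
    times_s : frame timestamps (second starts, relative to segment start)
    """

    probs: np.ndarray
    times_s: np.ndarray

    @property
    def abnormal(self) -> np.ndarray:
        """Abnormal score per frame: 1 - P(Normal)."""
        return 1.0 - self.probs[:, 0]


# ---------------------------------------------------------------------------
# parameters and layers
# ---------------------------------------------------------------------------

class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


def _glorot(rng: np.random.Generator, shape: tuple[int, ...], dtype) -> np.ndarray:
    fan_in, fan_out = shape[0] if len(shape) == 2 else int(np.prod(shape[:-1])), shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


class Conv1D:
    """Same-padded 1-D convolution, channels-last (B, L, C_in) -> (B, L, F)."""

    def __init__(self, c_in: int, filters: int, kernel: int, rng, dtype):
        self.k = kernel
        self.W = Param(_glorot(rng, (c_in * kernel, filters), dtype))
        self.b = Param(np.zeros(filters, dtype=dtype))

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        B, L, C = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (p, p), (0, 0)))
        cols = np.lib.stride_tricks.sliding_window_view(xp, self.k, axis=1)
        # cols: (B, L, C, k) -> (B*L, C*k); kernel tap varies fastest
        self._cols = np.ascontiguousarray(cols).reshape(B * L, C * self.k)
        self._shape = (B, L, C)
        out = self._cols @ self.W.value + self.b.value
        return out.reshape(B, L, -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, L, C = self._shape
        d2 = dout.reshape(B * L, -1)
        self.W.grad += self._cols.T @ d2
        self.b.grad += d2.sum(axis=0)
        dcols = (d2 @ self.W.value.T).reshape(B, L, C, self.k)
        p = self.k // 2
        dxp = np.zeros((B, L + 2 * p, C), dtype=dout.dtype)
        for j in range(self.k):
            dxp[:, j : j + L, :] += dcols[:, :, :, j]
        return dxp[:, p : p + L, :]


class BatchNorm1D:
    """Per-channel batch normalization over the batch and time axes."""

    def __init__(self, channels: int, dtype, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Param(np.ones(channels, dtype=dtype))
        self.beta = Param(np.zeros(channels, dtype=dtype))
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self.momentum = momentum
        self.eps = eps

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 1))
            var = x.var(axis=(0, 1))
            self.running_mean = (
                self.momentum * self.running_mean + (1 - self.momentum) * mean
            )
            self.running_var = (
                self.momentum * self.running_var + (1 - self.momentum) * var
            )
        else:
            mean, var = self.running_mean, self.running_var
        self._inv_sd = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean) * self._inv_sd
        self._n = x.shape[0] * x.shape[1]
        return self.gamma.value * self._xhat + self.beta.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv_sd, n = self._xhat, self._inv_sd, self._n
        self.gamma.grad += (dout * xhat).sum(axis=(0, 1))
        self.beta.grad += dout.sum(axis=(0, 1))
        dxhat = dout * self.gamma.value
        return (
            inv_sd
            / n
            * (
                n * dxhat
                - dxhat.sum(axis=(0, 1))
                - xhat * (dxhat * xhat).sum(axis=(0, 1))
            )
        )


class ReLU:
    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class MaxPool1D:
    """Window-2 max pool with configurable stride (stride 1 keeps length)."""

    def __init__(self, stride: int, window: int = 2):
        self.stride = stride
        self.window = window

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        B, L, C = x.shape
        n_out = -(-L // self.stride)  # ceil
        need = (n_out - 1) * self.stride + self.window
        if need > L:
            x = np.pad(x, ((0, 0), (0, need - L), (0, 0)), constant_values=-np.inf)
        win = np.lib.stride_tricks.sliding_window_view(x, self.window, axis=1)
        win = win[:, :: self.stride][:, :n_out]  # (B, n_out, C, window)
        self._arg = np.argmax(win, axis=3)
        self._in_len = L
        out = np.take_along_axis(win, self._arg[..., None], axis=3)[..., 0]
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, n_out, C = dout.shape
        dx = np.zeros((B, self._in_len + self.window, C), dtype=dout.dtype)
        pos = np.arange(n_out)[None, :, None] * self.stride + self._arg
        b_idx = np.arange(B)[:, None, None]
        c_idx = np.arange(C)[None, None, :]
        np.add.at(dx, (b_idx, pos, c_idx), dout)
        return dx[:, : self._in_len, :]


class Dropout:
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate = rate
        self.rng = rng

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dout
        return dout * self._mask


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


class BiLSTM:
    """Bidirectional LSTM over (B, T, C); output is the concatenation
    (B, T, 2H) of the forward and backward passes.

    Gate layout along the last weight axis is (input, forget, cell, output).
    Backward-in-time gradients are accumulated step by step (truncated
    nowhere: full BPTT over the 60 frames).
    """

    def __init__(self, c_in: int, units: int, rng, dtype):
        self.H = units
        self.dirs = []
        for _ in range(2):
            self.dirs.append(
                {
                    "W": Param(_glorot(rng, (c_in, 4 * units), dtype)),
                    "U": Param(_glorot(rng, (units, 4 * units), dtype)),
                    "b": Param(np.zeros(4 * units, dtype=dtype)),
                }
            )

    def params(self):
        return [p for d in self.dirs for p in (d["W"], d["U"], d["b"])]

    def _run(self, x: np.ndarray, d: dict) -> tuple[np.ndarray, dict]:
        B, T, C = x.shape
        H = self.H
        W, U, b = d["W"].value, d["U"].value, d["b"].value
        h = np.zeros((B, H), dtype=x.dtype)
        c = np.zeros((B, H), dtype=x.dtype)
        xw = x.reshape(B * T, C) @ W
        xw = xw.reshape(B, T, 4 * H) + b
        cache = {"i": [], "f": [], "g": [], "o": [], "c": [], "tc": [], "hprev": []}
        out = np.zeros((B, T, H), dtype=x.dtype)
        for t in range(T):
            cache["hprev"].append(h)
            a = xw[:, t] + h @ U
            i = _sigmoid(a[:, :H])
            f = _sigmoid(a[:, H : 2 * H])
            g = np.tanh(a[:, 2 * H : 3 * H])
            o = _sigmoid(a[:, 3 * H :])
            c_prev = c
            c = f * c_prev + i * g
            tc = np.tanh(c)
            h = o * tc
            out[:, t] = h
            cache["i"].append(i)
            cache["f"].append(f)
            cache["g"].append(g)
            cache["o"].append(o)
            cache["c"].append((c_prev, c))
            cache["tc"].append(tc)
        return out, cache

    def _run_back(self, x, dout, d, cache) -> np.ndarray:
        B, T, C = x.shape
        H = self.H
        W, U = d["W"].value, d["U"].value
        dh_next = np.zeros((B, H), dtype=x.dtype)
        dc_next = np.zeros((B, H), dtype=x.dtype)
        da_all = np.zeros((B, T, 4 * H), dtype=x.dtype)
        for t in range(T - 1, -1, -1):
            i, f, g, o = (cache[k][t] for k in ("i", "f", "g", "o"))
            c_prev, c = cache["c"][t]
            tc = cache["tc"][t]
            dh = dout[:, t] + dh_next
            do = dh * tc
            dc = dh * o * (1 - tc * tc) + dc_next
            di = dc * g
            dg = dc * i
            df = dc * c_prev
            dc_next = dc * f
            da = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g * g), do * o * (1 - o)],
                axis=1,
            )
            da_all[:, t] = da
            d["U"].grad += cache["hprev"][t].T @ da
            dh_next = da @ U.T
        d["W"].grad += x.reshape(B * T, C).T @ da_all.reshape(B * T, 4 * H)
        d["b"].grad += da_all.sum(axis=(0, 1))
        return (da_all.reshape(B * T, 4 * H) @ W.T).reshape(B, T, C)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        out_f, self._cache_f = self._run(x, self.dirs[0])
        out_b, self._cache_b = self._run(x[:, ::-1], self.dirs[1])
        return np.concatenate([out_f, out_b[:, ::-1]], axis=2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        H = self.H
        dx_f = self._run_back(self._x, dout[:, :, :H], self.dirs[0], self._cache_f)
        dx_b = self._run_back(
            self._x[:, ::-1], dout[:, ::-1, H:], self.dirs[1], self._cache_b
        )
        return dx_f + dx_b[:, ::-1]


class Dense:
    """Frame-wise fully connected layer (B, T, C_in) -> (B, T, C_out)."""

    def __init__(self, c_in: int, c_out: int, rng, dtype):
        self.W = Param(_glorot(rng, (c_in, c_out), dtype))
        self.b = Param(np.zeros(c_out, dtype=dtype))

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, T, C = self._x.shape
        self.W.grad += self._x.reshape(B * T, C).T @ dout.reshape(B * T, -1)
        self.b.grad += dout.sum(axis=(0, 1))
        return dout @ self.W.value.T


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------

class CRNN:
    """The dense detector; ``build_model`` is the public constructor."""

    def __init__(self, cfg: ModelConfig):
        self.cfg = cfg
        dtype = np.dtype(cfg.dtype)
        self.dtype = dtype
        rng = np.random.default_rng(cfg.seed)
        self._dropout_rng = np.random.default_rng(cfg.seed + 1)
        layers: list = []
        c_in = 1
        for block in range(cfg.conv_blocks):
            for _ in range(2):
                layers.append(Conv1D(c_in, cfg.conv_filters, cfg.kernel, rng, dtype))
                layers.append(BatchNorm1D(cfg.conv_filters, dtype))
                layers.append(ReLU())
                c_in = cfg.conv_filters
            layers.append(MaxPool1D(cfg.pool_strides[block]))
            layers.append(Dropout(cfg.dropout, self._dropout_rng))
        layers.append(BiLSTM(c_in, cfg.rnn_units, rng, dtype))
        layers.append(Dense(2 * cfg.rnn_units, cfg.fc_units, rng, dtype))
        layers.append(ReLU())
        layers.append(Dropout(cfg.dropout, self._dropout_rng))
        layers.append(Dense(cfg.fc_units, cfg.n_classes, rng, dtype))
        self.layers = layers

    # -- plumbing -----------------------------------------------------------
    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    def get_weights(self) -> list[np.ndarray]:
        ws = [p.value.copy() for p in self.params()]
        for layer in self.layers:
            if isinstance(layer, BatchNorm1D):
                ws.append(layer.running_mean.copy())
                ws.append(layer.running_var.copy())
        return ws

    def set_weights(self, ws: Sequence[np.ndarray]) -> None:
        ps = self.params()
        for p, w in zip(ps, ws):
            p.value[...] = w
        rest = list(ws[len(ps) :])
        for layer in self.layers:
            if isinstance(layer, BatchNorm1D):
                layer.running_mean[...] = rest.pop(0)
                layer.running_var[...] = rest.pop(0)

    def save(self, path: str | Path) -> None:
        np.savez_compressed(
            path,
            *self.get_weights(),
            n_classes=self.cfg.n_classes,
            seed=self.cfg.seed,
        )

    @classmethod
    def load(cls, path: str | Path, cfg: ModelConfig | None = None) -> "CRNN":
        with np.load(path) as d:
            if cfg is None:
                cfg = ModelConfig(
                    n_classes=int(d["n_classes"]), seed=int(d["seed"])
                )
            model = cls(cfg)
            ws = [d[f"arr_{i}"] for i in range(len(model.get_weights()))]
        model.set_weights(ws)
        return model

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Windows (B, n_samples) -> per-frame probabilities (B, n_frames, C).

        The input length must be a multiple of 8; 480 samples give the
        standard 60 frames.
        """
        x = np.asarray(x, dtype=self.dtype)
        if x.ndim == 1:
            x = x[None, :]
        if x.shape[1] % 8 != 0:
            raise ModelInputError(
                f"input length {x.shape[1]} is not a multiple of the "
                "temporal downsampling factor 8"
            )
        h = x[:, :, None]
        for layer in self.layers:
            h = layer.forward(h, train)
        self._logits = h
        return softmax(h)

    def backward(self, dlogits: np.ndarray) -> None:
        g = dlogits.astype(self.dtype)
        for layer in reversed(self.layers):
            g = layer.backward(g)


def build_model(cfg: ModelConfig) -> CRNN:
    """Construct the CRNN; deterministic given ``cfg.seed``."""
    return CRNN(cfg)


def predict_segment(model: CRNN, window_480: Sequence[float]) -> FramePredictions:
    """Inference on one z-normalized 480-sample window."""
    w = np.asarray(window_480, dtype=float)
    if w.shape != (SEGMENT_SAMPLES,):
        raise ModelInputError(f"expected a ({SEGMENT_SAMPLES},) window, got {w.shape}")
    probs = model.forward(w[None, :], train=False)[0]
    return FramePredictions(
        probs=probs.astype(float), times_s=np.arange(N_FRAMES, dtype=float)
    )


def predict_batches(
    model: CRNN, windows: np.ndarray, batch_size: int = 256
) -> np.ndarray:
    """Inference over (n, 480) windows; returns (n, 60, n_classes)."""
    outs = []
    for i in range(0, windows.shape[0], batch_size):
        outs.append(model.forward(windows[i : i + batch_size], train=False))
    return np.concatenate(outs, axis=0).astype(float)


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

DICE_SMOOTH = 1.0


def _dice_per_class(probs: np.ndarray, targets: np.ndarray, eps: float):
    p = probs.reshape(-1, probs.shape[-1])
    t = targets.reshape(-1, targets.shape[-1])
    inter = (p * t).sum(axis=0)
    sums = p.sum(axis=0) + t.sum(axis=0)
    return (2.0 * inter + eps) / (sums + eps)


def loss_ce_dice(
    probs: np.ndarray, one_hot_targets: np.ndarray, eps: float = DICE_SMOOTH
) -> float:
    """Frame-wise cross-entropy plus soft Dice loss.

    ``probs`` and ``one_hot_targets`` share a (..., n_classes) shape.  The
    cross-entropy term is averaged over frames; the Dice term is
    ``1 - mean_c D_c`` with the soft Dice coefficient ``D_c`` computed per
    class over all frames, smoothed by ``eps``.
    """
    probs = np.asarray(probs, dtype=float)
    targets = np.asarray(one_hot_targets, dtype=float)
    if probs.shape != targets.shape:
        raise ModelInputError(
            f"shape mismatch: probs {probs.shape} vs targets {targets.shape}"
        )
    if np.any(probs < 0) or np.any(probs > 1):
        raise ModelInputError("probabilities outside [0, 1]")
    p = np.clip(probs, 1e-12, 1.0)
    ce = float(-(targets * np.log(p)).sum() / max(targets[..., 0].size, 1))
    dice = float(1.0 - _dice_per_class(probs, targets, eps).mean())
    return ce + dice


def loss_and_logit_grad(
    probs: np.ndarray, targets: np.ndarray, eps: float = DICE_SMOOTH
) -> tuple[float, np.ndarray]:
    """Loss value and its gradient with respect to the pre-softmax logits."""
    n_frames = int(np.prod(probs.shape[:-1]))
    C = probs.shape[-1]
    loss = loss_ce_dice(probs, targets, eps)
    # cross-entropy through softmax
    dlogits = (probs - targets) / n_frames
    # Dice term: dL/dp, then through the softmax Jacobian
    p2 = probs.reshape(n_frames, C)
    t2 = targets.reshape(n_frames, C)
    inter = (p2 * t2).sum(axis=0)
    sums = p2.sum(axis=0) + t2.sum(axis=0)
    denom = sums + eps
    ddice_dp = -(2.0 * t2 * denom - (2.0 * inter + eps)) / (denom * denom) / C
    dot = (ddice_dp * p2).sum(axis=1, keepdims=True)
    dlogits = dlogits + (p2 * (ddice_dp - dot)).reshape(probs.shape)
    return loss, dlogits


class Adam:
    """Adam with bias correction; ``lr`` is mutable for plateau scheduling."""

    def __init__(
        self,
        params: Sequence[Param],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-7,
    ):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr1 = 1.0 - b1**self.t
        corr2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.value -= self.lr * (m / corr1) / (np.sqrt(v / corr2) + self.eps)


def one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    out = np.zeros(labels.shape + (n_classes,), dtype=float)
    np.put_along_axis(out, labels[..., None], 1.0, axis=-1)
    return out
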