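"""Minimal numpy neural-network layers with manual backpropagation.

Only what the two classifier variants need: temporal convolution, max
pooling, an LSTM cell unrolled over time, dense layers, inverted dropout,
softmax cross-entropy, and Adam.  Every layer keeps its forward cache on
the instance, so a layer instance is used by one forward/backward pair at
a time (training here is single-threaded and sequential).
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit as _sigmoid

#: all parameters and activations are float32 — halves memory traffic and
#: roughly doubles throughput on the CPU-only training path
DTYPE = np.float32

__all__ = [
    "Conv1d",
    "MaxPool1d",
    "ReLU",
    "LSTM",
    "Dense",
    "Dropout",
    "softmax",
    "softmax_cross_entropy",
    "Adam",
]


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(DTYPE)


class Layer:
    """Base: subclasses fill ``params`` and matching ``grads`` dicts."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv1d(Layer):
    """Temporal convolution with 'same' zero padding, stride 1.

    Input (B, C_in, T) -> output (B, C_out, T).
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        self.c_in, self.c_out, self.kernel = c_in, c_out, kernel
        self.params["W"] = _glorot(rng, c_in * kernel, c_out, (c_in * kernel, c_out))
        self.params["b"] = np.zeros(c_out, dtype=DTYPE)
        self.pad_l = (kernel - 1) // 2
        self.pad_r = kernel // 2

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        B, C, T = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad_l, self.pad_r)))
        # (B, C, T, k) windows -> (B*T, C*k)
        cols = np.lib.stride_tricks.sliding_window_view(xp, self.kernel, axis=2)
        cols = np.ascontiguousarray(cols.transpose(0, 2, 1, 3)).reshape(
            B * T, C * self.kernel
        )
        y = cols @ self.params["W"] + self.params["b"]
        self._cache = (cols, x.shape)
        return y.reshape(B, T, self.c_out).transpose(0, 2, 1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, x_shape = self._cache
        B, C, T = x_shape
        dflat = np.ascontiguousarray(dy.transpose(0, 2, 1)).reshape(B * T, self.c_out)
        self.grads["W"] = cols.T @ dflat
        self.grads["b"] = dflat.sum(axis=0)
        dcols = (dflat @ self.params["W"].T).reshape(B, T, C, self.kernel)
        dxp = np.zeros((B, C, T + self.pad_l + self.pad_r), dtype=dy.dtype)
        for j in range(self.kernel):
            dxp[:, :, j : j + T] += dcols[:, :, :, j].transpose(0, 2, 1)
        return dxp[:, :, self.pad_l : self.pad_l + T]


class MaxPool1d(Layer):
    """Non-overlapping temporal max pooling; trailing remainder is dropped."""

    def __init__(self, size: int = 2):
        super().__init__()
        self.size = size

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        B, C, T = x.shape
        To = T // self.size
        xr = x[:, :, : To * self.size].reshape(B, C, To, self.size)
        out = xr.max(axis=3)
        self._cache = (xr, out, x.shape)
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xr, out, x_shape = self._cache
        To = dy.shape[2]
        # route gradient to the first maximal element of each pool (argmax rule)
        is_max = xr == out[..., None]
        first = is_max.cumsum(axis=3) == 1
        dxr = (is_max & first) * dy[..., None]
        dx = np.zeros(x_shape, dtype=dy.dtype)
        dx[:, :, : To * self.size] = dxr.reshape(dy.shape[0], dy.shape[1], -1)
        return dx


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class LSTM(Layer):
    """Unrolled LSTM returning the final hidden state.

    Input (B, T, D) -> output (B, H).  Gate order in the stacked weight
    matrices is (input, forget, cell, output); forget bias starts at 1.
    """

    def __init__(self, d_in: int, hidden: int, rng: np.random.Generator):
        super().__init__()
        self.d_in, self.hidden = d_in, hidden
        H = hidden
        self.params["Wx"] = _glorot(rng, d_in, 4 * H, (d_in, 4 * H))
        self.params["Wh"] = _glorot(rng, H, 4 * H, (H, 4 * H))
        b = np.zeros(4 * H, dtype=DTYPE)
        b[H : 2 * H] = 1.0
        self.params["b"] = b

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        B, T, D = x.shape
        H = self.hidden
        h = np.zeros((B, H), dtype=x.dtype)
        c = np.zeros((B, H), dtype=x.dtype)
        steps = []
        Wx, Wh, b = self.params["Wx"], self.params["Wh"], self.params["b"]
        for t in range(T):
            xt = x[:, t, :]
            z = xt @ Wx + h @ Wh + b
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H : 2 * H])
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = _sigmoid(z[:, 3 * H :])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            steps.append((xt, h, c, i, f, g, o, tc))
            h = o * tc
            c = c_new
        self._cache = (steps, x.shape)
        return h

    def backward(self, dh_last: np.ndarray) -> np.ndarray:
        steps, x_shape = self._cache
        B, T, D = x_shape
        H = self.hidden
        Wx, Wh = self.params["Wx"], self.params["Wh"]
        dWx = np.zeros_like(Wx)
        dWh = np.zeros_like(Wh)
        db = np.zeros_like(self.params["b"])
        dx = np.zeros(x_shape, dtype=dh_last.dtype)
        dh = dh_last
        dc = np.zeros((B, H), dtype=dh_last.dtype)
        for t in range(T - 1, -1, -1):
            xt, h_prev, c_prev, i, f, g, o, tc = steps[t]
            do = dh * tc
            dc = dc + dh * o * (1.0 - tc * tc)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g * g),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            dWx += xt.T @ dz
            dWh += h_prev.T @ dz
            db += dz.sum(axis=0)
            dx[:, t, :] = dz @ Wx.T
            dh = dz @ Wh.T
            dc = dc * f
        self.grads["Wx"], self.grads["Wh"], self.grads["b"] = dWx, dWh, db
        return dx


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        super().__init__()
        self.params["W"] = _glorot(rng, d_in, d_out, (d_in, d_out))
        self.params["b"] = np.zeros(d_out, dtype=DTYPE)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads["W"] = self._x.T @ dy
        self.grads["b"] = dy.sum(axis=0)
        return dy @ self.params["W"].T


class Dropout(Layer):
    """Inverted dropout; identity at inference. Needs an rng at train time."""

    def __init__(self, rate: float):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng: np.random.Generator | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        if self.rng is None:
            raise RuntimeError("Dropout.rng must be set before training")
        keep = 1.0 - self.rate
        self._mask = ((self.rng.random(x.shape) < keep) / keep).astype(DTYPE)
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dy
        return dy * self._mask


def softmax(logits: np.ndarray) -> np.ndarray:
    z = np.asarray(logits, dtype=np.float64)
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray, y: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and gradient w.r.t. logits.

    ``y`` holds integer class indices, shape (B,).
    """
    B = logits.shape[0]
    p = softmax(logits)
    loss = float(-np.log(np.clip(p[np.arange(B), y], 1e-12, None)).mean())
    dlogits = p.copy()
    dlogits[np.arange(B), y] -= 1.0
    return loss, (dlogits / B).astype(DTYPE)


class Adam:
    """Adam over a list of (params, grads) dict pairs, one per layer."""

    def __init__(
        self,
        layers,
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.layers = [l for l in layers if l.params]
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [
            {k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers
        ]
        self.v = [
            {k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers
        ]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr1 = 1.0 - b1**self.t
        corr2 = 1.0 - b2**self.t
        for li, layer in enumerate(self.layers):
            for k, p in layer.params.items():
                g = layer.grads[k]
                m = self.m[li][k]
                v = self.v[li][k]
                m *= b1
                m += (1 - b1) * g
                v *= b2
                v += (1 - b2) * g * g
                p -= self.lr * (m / corr1) / (np.sqrt(v / corr2) + self.eps)
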