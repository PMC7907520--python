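"""Minimal NumPy neural-network layers with exact backpropagation.

Sized for this problem: one-channel 28×28 feature mappings, batches of
~50, two convolutional layers. Convolutions use im2col + BLAS matmul;
everything is float64 and deterministic given the generator passed at
construction time. Layers expose ``forward(x, train)`` /
``backward(grad)`` and flat ``params``/``grads`` lists consumed by the
Adam optimizer.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Layer", "Conv2D", "Conv1D", "MaxPool2D", "MaxPool1D",
    "GlobalAvgPool1D", "SEBlock", "Flatten", "Dropout", "Dense",
    "Adam", "sigmoid", "relu",
]


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _he_normal(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), shape)


def _glorot_uniform(rng: np.random.Generator, shape: tuple[int, ...],
                    fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, shape)


class Conv2D(Layer):
    """Stride-1 'same' 2D convolution with optional ReLU."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, activation: str | None = "relu") -> None:
        super().__init__()
        if kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd for 'same' padding")
        self.cin, self.cout, self.k = in_channels, out_channels, kernel_size
        self.activation = activation
        fan_in = in_channels * kernel_size * kernel_size
        self.W = _he_normal(rng, (out_channels, fan_in), fan_in)
        self.b = np.zeros(out_channels)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = sliding_window_view(xp, (self.k, self.k), axis=(2, 3))  # (n,c,h,w,k,k)
        return win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * self.k * self.k)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        if c != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {c}")
        cols = self._im2col(x)
        pre = cols @ self.W.T + self.b
        pre = pre.reshape(n, h, w, self.cout).transpose(0, 3, 1, 2)
        self._cols, self._shape = cols, (n, c, h, w)
        if self.activation == "relu":
            self._mask = pre > 0
            return np.where(self._mask, pre, 0.0)
        self._mask = None
        return pre

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        if self._mask is not None:
            grad = np.where(self._mask, grad, 0.0)
        dpre = grad.transpose(0, 2, 3, 1).reshape(n * h * w, self.cout)
        self.grads[0][...] = dpre.T @ self._cols
        self.grads[1][...] = dpre.sum(axis=0)
        dcols = dpre @ self.W  # (n*h*w, c*k*k)
        dcols = dcols.reshape(n, h, w, c, self.k, self.k).transpose(0, 3, 1, 2, 4, 5)
        p = self.k // 2
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p))
        for i in range(self.k):
            for j in range(self.k):
                dxp[:, :, i:i + h, j:j + w] += dcols[:, :, :, :, i, j]
        return dxp[:, :, p:p + h, p:p + w]


class Conv1D(Layer):
    """Stride-1 'same' 1D convolution with optional ReLU."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, activation: str | None = "relu") -> None:
        super().__init__()
        if kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd for 'same' padding")
        self.cin, self.cout, self.k = in_channels, out_channels, kernel_size
        self.activation = activation
        fan_in = in_channels * kernel_size
        self.W = _he_normal(rng, (out_channels, fan_in), fan_in)
        self.b = np.zeros(out_channels)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, length = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p)))
        win = sliding_window_view(xp, self.k, axis=2)  # (n,c,L,k)
        cols = win.transpose(0, 2, 1, 3).reshape(n * length, c * self.k)
        pre = (cols @ self.W.T + self.b).reshape(n, length, self.cout).transpose(0, 2, 1)
        self._cols, self._shape = cols, (n, c, length)
        if self.activation == "relu":
            self._mask = pre > 0
            return np.where(self._mask, pre, 0.0)
        self._mask = None
        return pre

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, length = self._shape
        if self._mask is not None:
            grad = np.where(self._mask, grad, 0.0)
        dpre = grad.transpose(0, 2, 1).reshape(n * length, self.cout)
        self.grads[0][...] = dpre.T @ self._cols
        self.grads[1][...] = dpre.sum(axis=0)
        dcols = (dpre @ self.W).reshape(n, length, c, self.k).transpose(0, 2, 1, 3)
        p = self.k // 2
        dxp = np.zeros((n, c, length + 2 * p))
        for i in range(self.k):
            dxp[:, :, i:i + length] += dcols[:, :, :, i]
        return dxp[:, :, p:p + length]


class MaxPool2D(Layer):
    """Non-overlapping max pooling; spatial dims must divide the size."""

    def __init__(self, size: int = 2) -> None:
        super().__init__()
        self.s = size

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        s = self.s
        if h % s or w % s:
            raise ValueError(f"spatial dims ({h},{w}) not divisible by pool size {s}")
        xr = x.reshape(n, c, h // s, s, w // s, s).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(n, c, h // s, w // s, s * s)
        self._argmax = xr.argmax(axis=-1)
        self._shape = (n, c, h, w)
        return np.take_along_axis(xr, self._argmax[..., None], axis=-1)[..., 0]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        s = self.s
        d = np.zeros((n, c, h // s, w // s, s * s))
        np.put_along_axis(d, self._argmax[..., None], grad[..., None], axis=-1)
        d = d.reshape(n, c, h // s, w // s, s, s).transpose(0, 1, 2, 4, 3, 5)
        return d.reshape(n, c, h, w)


class MaxPool1D(Layer):
    def __init__(self, size: int = 2) -> None:
        super().__init__()
        self.s = size

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, length = x.shape
        s = self.s
        if length % s:
            raise ValueError(f"length {length} not divisible by pool size {s}")
        xr = x.reshape(n, c, length // s, s)
        self._argmax = xr.argmax(axis=-1)
        self._shape = (n, c, length)
        return np.take_along_axis(xr, self._argmax[..., None], axis=-1)[..., 0]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, length = self._shape
        d = np.zeros((n, c, length // self.s, self.s))
        np.put_along_axis(d, self._argmax[..., None], grad[..., None], axis=-1)
        return d.reshape(n, c, length)


class GlobalAvgPool1D(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=2)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, length = self._shape
        return np.repeat(grad[:, :, None], length, axis=2) / length


class SEBlock(Layer):
    """Squeeze-and-excitation channel attention.

    Squeeze: global average over the spatial plane gives a channel
    descriptor z. Excite: a two-layer bottleneck (reduction ratio r)
    with ReLU then sigmoid yields gates s ∈ (0,1)^C. Scale: each
    channel is multiplied by its gate. ``gate_override`` forces every
    gate to a constant (1.0 reduces the block to the identity — the
    no-attention ablation).
    """

    def __init__(self, channels: int, reduction: int, rng: np.random.Generator) -> None:
        super().__init__()
        if channels % reduction:
            raise ValueError(f"channels {channels} not divisible by reduction {reduction}")
        self.c, self.r = channels, reduction
        hidden = channels // reduction
        self.W1 = _he_normal(rng, (hidden, channels), channels)
        self.W2 = _glorot_uniform(rng, (channels, hidden), hidden, channels)
        self.params = [self.W1, self.W2]
        self.grads = [np.zeros_like(self.W1), np.zeros_like(self.W2)]
        self.gate_override: float | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        if c != self.c:
            raise ValueError(f"expected {self.c} channels, got {c}")
        if self.gate_override is not None:
            self._x = x
            return x * self.gate_override
        z = x.mean(axis=(2, 3))                    # squeeze
        a = z @ self.W1.T
        hdd = relu(a)
        s = sigmoid(hdd @ self.W2.T)               # excite
        self._x, self._z, self._a, self._h, self._s = x, z, a, hdd, s
        return x * s[:, :, None, None]             # scale

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self.gate_override is not None:
            self.grads[0][...] = 0.0
            self.grads[1][...] = 0.0
            return grad * self.gate_override
        x, z, a, hdd, s = self._x, self._z, self._a, self._h, self._s
        n, c, h, w = x.shape
        dx = grad * s[:, :, None, None]
        ds = (grad * x).sum(axis=(2, 3))
        dlin = ds * s * (1.0 - s)
        self.grads[1][...] = dlin.T @ hdd
        dh = dlin @ self.W2
        da = np.where(a > 0, dh, 0.0)
        self.grads[0][...] = da.T @ z
        dz = da @ self.W1
        dx += dz[:, :, None, None] / (h * w)
        return dx


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class Dropout(Layer):
    """Inverted dropout; identity at inference time."""

    def __init__(self, rate: float, rng: np.random.Generator) -> None:
        super().__init__()
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad if self._mask is None else grad * self._mask


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 activation: str | None = None) -> None:
        super().__init__()
        self.activation = activation
        if activation == "relu":
            self.W = _he_normal(rng, (out_features, in_features), in_features)
        else:
            self.W = _glorot_uniform(rng, (out_features, in_features),
                                     in_features, out_features)
        self.b = np.zeros(out_features)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        pre = x @ self.W.T + self.b
        self._x = x
        if self.activation == "relu":
            self._cache = pre > 0
            return np.where(self._cache, pre, 0.0)
        if self.activation == "sigmoid":
            self._cache = sigmoid(pre)
            return self._cache
        self._cache = None
        return pre

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self.activation == "relu":
            dpre = np.where(self._cache, grad, 0.0)
        elif self.activation == "sigmoid":
            s = self._cache
            dpre = grad * s * (1.0 - s)
        else:
            dpre = grad
        self.grads[0][...] = dpre.T @ self._x
        self.grads[1][...] = dpre.sum(axis=0)
        return dpre @ self.W


class Adam:
    """Adaptive moment estimation with the standard bias correction."""

    def __init__(self, params: list[np.ndarray], grads: list[np.ndarray],
                 lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8) -> None:
        self.params, self.grads = params, grads
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
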