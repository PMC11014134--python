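"""Minimal NumPy neural-network layers with manual backpropagation.

Float32 throughout; layers expose ``forward(x, train)`` / ``backward(grad)``
and a ``params`` list of :class:`Param`. Convolutions are im2col + GEMM with
'same' padding and stride 1; pooling is 2x2 max. The LSTM implements full
backpropagation through time with the usual i/f/g/o gating and a +1 forget
bias. Initialization is seeded through a generator passed at construction,
so models are bit-reproducible.
"""

from __future__ import annotations

import numpy as np

F32 = np.float32


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value.astype(F32)
        self.grad = np.zeros_like(self.value)


class Layer:
    params: list[Param]

    def __init__(self):
        self.params = []

    def forward(self, x, train: bool):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad):  # pragma: no cover - interface
        raise NotImplementedError


class Conv2d(Layer):
    """3x3 (configurable) same-padding stride-1 convolution, NCHW."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        self.k = kernel
        self.in_ch, self.out_ch = in_ch, out_ch
        fan_in = in_ch * kernel * kernel
        bound = 1.0 / np.sqrt(fan_in)
        self.W = Param(rng.uniform(-bound, bound, (out_ch, in_ch, kernel, kernel)))
        self.b = Param(rng.uniform(-bound, bound, out_ch))
        self.params = [self.W, self.b]

    def _cols(self, x):
        n, c, h, w = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        view = np.lib.stride_tricks.sliding_window_view(xp, (self.k, self.k), axis=(2, 3))
        # (n, c, h, w, k, k) -> (n*h*w, c*k*k)
        return view.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * self.k * self.k)

    def forward(self, x, train: bool):
        self._shape = x.shape
        self._cols_cache = np.ascontiguousarray(self._cols(x))
        n, c, h, w = x.shape
        wmat = self.W.value.reshape(self.out_ch, -1)
        out = self._cols_cache @ wmat.T + self.b.value
        return out.reshape(n, h, w, self.out_ch).transpose(0, 3, 1, 2)

    def backward(self, grad):
        n, c, h, w = self._shape
        g = grad.transpose(0, 2, 3, 1).reshape(n * h * w, self.out_ch)
        self.W.grad += (g.T @ self._cols_cache).reshape(self.W.value.shape)
        self.b.grad += g.sum(axis=0)
        dcols = g @ self.W.value.reshape(self.out_ch, -1)  # (n*h*w, c*k*k)
        dcols = dcols.reshape(n, h, w, c, self.k, self.k)
        p = self.k // 2
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=F32)
        for di in range(self.k):
            for dj in range(self.k):
                dxp[:, :, di:di + h, dj:dj + w] += dcols[:, :, :, :, di, dj].transpose(0, 3, 1, 2)
        return dxp[:, :, p:p + h, p:p + w]


class BatchNorm2d(Layer):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.params = [self.gamma, self.beta]
        self.running_mean = np.zeros(channels, dtype=F32)
        self.running_var = np.ones(channels, dtype=F32)
        self.momentum, self.eps = momentum, eps

    def forward(self, x, train: bool):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean).astype(F32)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(F32)
        else:
            mean, var = self.running_mean, self.running_var
        self._istd = (1.0 / np.sqrt(var + self.eps)).astype(F32)[None, :, None, None]
        self._xhat = (x - mean[None, :, None, None]) * self._istd
        self._train = train
        return self.gamma.value[None, :, None, None] * self._xhat + self.beta.value[None, :, None, None]

    def backward(self, grad):
        self.gamma.grad += (grad * self._xhat).sum(axis=(0, 2, 3))
        self.beta.grad += grad.sum(axis=(0, 2, 3))
        g = grad * self.gamma.value[None, :, None, None]
        if not self._train:
            return g * self._istd
        m = grad.shape[0] * grad.shape[2] * grad.shape[3]
        sum_g = g.sum(axis=(0, 2, 3), keepdims=True)
        sum_gx = (g * self._xhat).sum(axis=(0, 2, 3), keepdims=True)
        return self._istd * (g - sum_g / m - self._xhat * sum_gx / m)


class ReLU(Layer):
    def forward(self, x, train: bool):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class MaxPool2x2(Layer):
    def forward(self, x, train: bool):
        n, c, h, w = x.shape
        h2, w2 = h // 2, w // 2
        xr = x[:, :, :h2 * 2, :w2 * 2].reshape(n, c, h2, 2, w2, 2)
        xr = xr.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h2, w2, 4)
        self._idx = np.argmax(xr, axis=-1)
        self._inshape = x.shape
        return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, grad):
        n, c, h, w = self._inshape
        h2, w2 = h // 2, w // 2
        flat = np.zeros((n, c, h2, w2, 4), dtype=F32)
        np.put_along_axis(flat, self._idx[..., None], grad[..., None], axis=-1)
        out = flat.reshape(n, c, h2, w2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return out.reshape(n, c, h2 * 2, w2 * 2)


class Dropout(Layer):
    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        self.rate = rate
        self.rng = rng

    def forward(self, x, train: bool):
        if not train or self.rate <= 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(F32) / F32(keep)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class Linear(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        super().__init__()
        bound = 1.0 / np.sqrt(d_in)
        self.W = Param(rng.uniform(-bound, bound, (d_in, d_out)))
        self.b = Param(rng.uniform(-bound, bound, d_out))
        self.params = [self.W, self.b]

    def forward(self, x, train: bool):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, grad):
        self.W.grad += self._x.T @ grad
        self.b.grad += grad.sum(axis=0)
        return grad @ self.W.value.T


class LSTM(Layer):
    """Single LSTM layer over (N, T, D); returns the full hidden sequence."""

    def __init__(self, d_in: int, hidden: int, rng: np.random.Generator):
        super().__init__()
        self.d_in, self.hidden = d_in, hidden
        bound = 1.0 / np.sqrt(hidden)
        self.Wx = Param(rng.uniform(-bound, bound, (d_in, 4 * hidden)))
        self.Wh = Param(rng.uniform(-bound, bound, (hidden, 4 * hidden)))
        b = rng.uniform(-bound, bound, 4 * hidden)
        b[hidden:2 * hidden] += 1.0  # forget-gate bias
        self.b = Param(b)
        self.params = [self.Wx, self.Wh, self.b]

    def forward(self, x, train: bool):
        n, t, d = x.shape
        hdim = self.hidden
        self._x = x
        h = np.zeros((n, hdim), dtype=F32)
        c = np.zeros((n, hdim), dtype=F32)
        self._cache = []
        hs = np.empty((n, t, hdim), dtype=F32)
        for step in range(t):
            gates = x[:, step] @ self.Wx.value + h @ self.Wh.value + self.b.value
            i = _sigmoid(gates[:, :hdim])
            f = _sigmoid(gates[:, hdim:2 * hdim])
            g = np.tanh(gates[:, 2 * hdim:3 * hdim])
            o = _sigmoid(gates[:, 3 * hdim:])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            self._cache.append((h, c, i, f, g, o, tc))
            h, c = h_new, c_new
            hs[:, step] = h
        self._hs = hs
        return hs

    def backward(self, grad):
        n, t, hdim = grad.shape
        x = self._x
        dx = np.zeros_like(x)
        dh_next = np.zeros((n, hdim), dtype=F32)
        dc_next = np.zeros((n, hdim), dtype=F32)
        for step in range(t - 1, -1, -1):
            h_prev, c_prev, i, f, g, o, tc = self._cache[step]
            dh = grad[:, step] + dh_next
            do = dh * tc
            dc = dh * o * (1 - tc**2) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dgates = np.concatenate([
                di * i * (1 - i), df * f * (1 - f),
                dg * (1 - g**2), do * o * (1 - o),
            ], axis=1).astype(F32)
            self.Wx.grad += x[:, step].T @ dgates
            self.Wh.grad += h_prev.T @ dgates
            self.b.grad += dgates.sum(axis=0)
            dx[:, step] = dgates @ self.Wx.value.T
            dh_next = dgates @ self.Wh.value.T
            dc_next = dc * f
        return dx


def _sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(probs: np.ndarray, labels: np.ndarray) -> float:
    """Mean negative log-likelihood of the true classes."""
    p = probs[np.arange(len(labels)), labels]
    return float(-np.log(np.maximum(p, 1e-12)).mean())


def softmax_ce_grad(probs: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Gradient of mean CE w.r.t. the logits feeding the softmax."""
    g = probs.copy()
    g[np.arange(len(labels)), labels] -= 1.0
    return (g / len(labels)).astype(F32)


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        corr1 = 1 - b1**self.t
        corr2 = 1 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m += (1 - b1) * (p.grad - m)
            v += (1 - b2) * (p.grad**2 - v)
            p.value -= (self.lr * (m / corr1)
                        / (np.sqrt(v / corr2) + self.eps)).astype(F32)
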