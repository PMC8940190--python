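"""Minimal NumPy neural-network core for frame-level sequence classifiers.

Implements dense, LSTM, GRU and bidirectional-sum layers with manual
backpropagation (full BPTT), inverted dropout, a masked softmax
cross-entropy head, and the Adam optimizer.  Everything runs in float32;
all randomness flows through explicit ``numpy.random.Generator`` objects
so training is bit-reproducible for a fixed seed.

Shapes: sequence batches are (B, T, D) with a boolean validity mask
(B, T); padding sits at the end of each row.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

__all__ = [
    "Param", "Dense", "LSTMLayer", "GRULayer", "BiSumLayer", "Dropout",
    "Adam", "softmax", "masked_cross_entropy", "reverse_padded",
    "glorot", "sigmoid",
]

_DT = np.float32


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - np.max(x, axis=axis, keepdims=True)
    e = np.exp(z)
    return e / np.sum(e, axis=axis, keepdims=True)


def glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in, fan_out = shape[0], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(_DT)


class Param:
    """A trainable array with its gradient accumulator."""

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=_DT)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


def reverse_padded(x: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """Reverse each row's valid prefix, leaving trailing padding in place."""
    B, T = x.shape[0], x.shape[1]
    t = np.arange(T)[None, :]
    lens = np.asarray(lengths)[:, None]
    idx = np.where(t < lens, lens - 1 - t, t)
    return x[np.arange(B)[:, None], idx]


class Dense:
    """Affine map applied to the last axis."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.W = Param(glorot(rng, (d_in, d_out)))
        self.b = Param(np.zeros(d_out, dtype=_DT))
        self._x = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x2 = self._x.reshape(-1, self._x.shape[-1])
        d2 = dout.reshape(-1, dout.shape[-1])
        self.W.grad += x2.T @ d2
        self.b.grad += d2.sum(axis=0)
        return dout @ self.W.value.T


class Relu:
    def __init__(self):
        self._mask = None

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class Dropout:
    """Inverted dropout; identity when ``training`` is False."""

    def __init__(self, rate: float):
        self.rate = rate
        self._mask = None

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool,
                rng: Optional[np.random.Generator] = None) -> np.ndarray:
        if not training or self.rate <= 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(_DT) / _DT(keep)
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout if self._mask is None else dout * self._mask


class LSTMLayer:
    """Unidirectional LSTM over (B, T, D) inputs; gate order i, f, g, o."""

    def __init__(self, d_in: int, n_cells: int, rng: np.random.Generator):
        H = n_cells
        self.H = H
        self.Wx = Param(glorot(rng, (d_in, 4 * H)))
        self.Wh = Param(glorot(rng, (H, 4 * H)))
        b = np.zeros(4 * H, dtype=_DT)
        b[H:2 * H] = 1.0          # forget-gate bias
        self.b = Param(b)
        self._cache = None

    def params(self) -> list[Param]:
        return [self.Wx, self.Wh, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, T, _ = x.shape
        H = self.H
        h = np.zeros((B, H), dtype=_DT)
        c = np.zeros((B, H), dtype=_DT)
        hs = np.empty((B, T, H), dtype=_DT)
        cache = []
        x_proj = x @ self.Wx.value + self.b.value       # (B, T, 4H)
        for t in range(T):
            a = x_proj[:, t] + h @ self.Wh.value
            i = sigmoid(a[:, :H])
            f = sigmoid(a[:, H:2 * H])
            g = np.tanh(a[:, 2 * H:3 * H])
            o = sigmoid(a[:, 3 * H:])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            cache.append((i, f, g, o, c, tc, h))
            h, c = h_new, c_new
            hs[:, t] = h
        self._cache = (x, cache)
        return hs

    def backward(self, dhs: np.ndarray) -> np.ndarray:
        x, cache = self._cache
        B, T, D = x.shape
        H = self.H
        dx = np.zeros_like(x)
        dh_rec = np.zeros((B, H), dtype=_DT)
        dc = np.zeros((B, H), dtype=_DT)
        da_all = np.empty((B, T, 4 * H), dtype=_DT)
        for t in range(T - 1, -1, -1):
            i, f, g, o, c_prev, tc, h_prev = cache[t]
            dh = dhs[:, t] + dh_rec
            do = dh * tc
            dc = dc + dh * o * (1.0 - tc * tc)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            da = np.concatenate([di * i * (1 - i), df * f * (1 - f),
                                 dg * (1 - g * g), do * o * (1 - o)], axis=1)
            da_all[:, t] = da
            self.Wh.grad += h_prev.T @ da
            dh_rec = da @ self.Wh.value.T
            dc = dc * f
        da2 = da_all.reshape(B * T, 4 * H)
        self.Wx.grad += x.reshape(B * T, D).T @ da2
        self.b.grad += da2.sum(axis=0)
        dx = da_all @ self.Wx.value.T
        return dx


class GRULayer:
    """Unidirectional GRU (update/reset gates, candidate with post-matmul
    reset, i.e. n = tanh(x Wxn + r * (h Whn + bhn) + bxn))."""

    def __init__(self, d_in: int, n_cells: int, rng: np.random.Generator):
        H = n_cells
        self.H = H
        self.Wx = Param(glorot(rng, (d_in, 3 * H)))       # r, z, n
        self.Wh = Param(glorot(rng, (H, 3 * H)))
        self.b = Param(np.zeros(3 * H, dtype=_DT))
        self.bh = Param(np.zeros(H, dtype=_DT))           # candidate hidden bias
        self._cache = None

    def params(self) -> list[Param]:
        return [self.Wx, self.Wh, self.b, self.bh]

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, T, _ = x.shape
        H = self.H
        h = np.zeros((B, H), dtype=_DT)
        hs = np.empty((B, T, H), dtype=_DT)
        cache = []
        x_proj = x @ self.Wx.value + self.b.value
        for t in range(T):
            rz_h = h @ self.Wh.value[:, :2 * H]
            r = sigmoid(x_proj[:, t, :H] + rz_h[:, :H])
            z = sigmoid(x_proj[:, t, H:2 * H] + rz_h[:, H:])
            hn_lin = h @ self.Wh.value[:, 2 * H:] + self.bh.value
            n = np.tanh(x_proj[:, t, 2 * H:] + r * hn_lin)
            h_new = (1.0 - z) * n + z * h
            cache.append((r, z, n, hn_lin, h))
            h = h_new
            hs[:, t] = h
        self._cache = (x, cache)
        return hs

    def backward(self, dhs: np.ndarray) -> np.ndarray:
        x, cache = self._cache
        B, T, D = x.shape
        H = self.H
        dh_rec = np.zeros((B, H), dtype=_DT)
        da_all = np.empty((B, T, 3 * H), dtype=_DT)
        for t in range(T - 1, -1, -1):
            r, z, n, hn_lin, h_prev = cache[t]
            dh = dhs[:, t] + dh_rec
            dz = dh * (h_prev - n)
            dn = dh * (1.0 - z)
            dh_prev = dh * z
            dn_pre = dn * (1.0 - n * n)
            dr = dn_pre * hn_lin
            dhn_lin = dn_pre * r
            self.Wh.grad[:, 2 * H:] += h_prev.T @ dhn_lin
            self.bh.grad += dhn_lin.sum(axis=0)
            dh_prev += dhn_lin @ self.Wh.value[:, 2 * H:].T
            dr_pre = dr * r * (1.0 - r)
            dz_pre = dz * z * (1.0 - z)
            drz = np.concatenate([dr_pre, dz_pre], axis=1)
            self.Wh.grad[:, :2 * H] += h_prev.T @ drz
            dh_prev += drz @ self.Wh.value[:, :2 * H].T
            da_all[:, t] = np.concatenate([dr_pre, dz_pre, dn_pre], axis=1)
            dh_rec = dh_prev
        da2 = da_all.reshape(B * T, 3 * H)
        self.Wx.grad += x.reshape(B * T, D).T @ da2
        self.b.grad += da2.sum(axis=0)
        return da_all @ self.Wx.value.T


class BiSumLayer:
    """Bidirectional recurrent layer whose directional outputs are summed.

    The forward unit reads the sequence left-to-right, the backward unit
    right-to-left (reversal respects true lengths); the layer output is
    the elementwise sum, so the hidden width stays ``n_cells``.
    """

    def __init__(self, d_in: int, n_cells: int, rng: np.random.Generator,
                 cell: str = "lstm"):
        layer_cls = LSTMLayer if cell == "lstm" else GRULayer
        self.fwd = layer_cls(d_in, n_cells, rng)
        self.bwd = layer_cls(d_in, n_cells, rng)
        self._lengths = None

    def params(self) -> list[Param]:
        return self.fwd.params() + self.bwd.params()

    def forward(self, x: np.ndarray, lengths: np.ndarray) -> np.ndarray:
        self._lengths = lengths
        y_f = self.fwd.forward(x)
        y_b = reverse_padded(self.bwd.forward(reverse_padded(x, lengths)), lengths)
        return y_f + y_b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dx_f = self.fwd.backward(dout)
        dx_b = reverse_padded(
            self.bwd.backward(reverse_padded(dout, self._lengths)), self._lengths)
        return dx_f + dx_b


def masked_cross_entropy(logits: np.ndarray, labels: np.ndarray,
                         mask: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean frame-level cross-entropy over valid frames.

    ``logits`` (B, T, K); ``labels`` (B,) class indices broadcast to all
    frames of the utterance; ``mask`` (B, T) boolean.  Returns the loss
    and d(loss)/d(logits).
    """
    probs = softmax(logits, axis=-1)
    n_valid = int(mask.sum())
    B, T, K = logits.shape
    onehot = np.zeros((B, 1, K), dtype=_DT)
    onehot[np.arange(B), 0, labels] = 1.0
    p_true = np.clip(probs[np.arange(B)[:, None], np.arange(T)[None, :],
                           labels[:, None]], 1e-12, None)
    loss = float(-(np.log(p_true) * mask).sum() / n_valid)
    dlogits = (probs - onehot) * mask[:, :, None].astype(_DT) / _DT(n_valid)
    return loss, dlogits


class Adam:
    """Adam optimizer over a parameter list."""

    def __init__(self, params: list[Param], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * p.grad
            v[...] = b2 * v + (1 - b2) * p.grad ** 2
            m_hat = m / (1 - b1 ** self.t)
            v_hat = v / (1 - b2 ** self.t)
            p.value -= (self.lr * m_hat / (np.sqrt(v_hat) + self.eps)).astype(_DT)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
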