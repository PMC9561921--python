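"""Minimal seeded neural-network engine (numpy, CPU).

Implements exactly the layers the attention CNN needs — 2-D convolution
(as a tap loop of BLAS matmuls), batch normalization, ELU, dropout,
max-pooling over time, linear layers, softmax attention over one feature
axis — each with an analytic backward pass, plus Adam and the
categorical cross-entropy.  No autograd framework is available in the
target environment, so gradients are derived by hand and verified
numerically in the test suite.

Conventions: feature maps are (batch, filters, channels, time) float32;
weights initialize U(-1/sqrt(fan_in), +1/sqrt(fan_in)) from a seeded
Generator; softmax subtracts the row max before exponentiating.
"""

from __future__ import annotations

import numpy as np
from scipy import fft as sfft


class Param:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("name", "value", "grad")

    def __init__(self, name: str, value: np.ndarray):
        self.name = name
        self.value = value.astype(np.float32)
        self.grad = np.zeros_like(self.value)


def _init_uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(np.float32)


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x, train=False, rng=None):  # pragma: no cover
        raise NotImplementedError

    def backward(self, g):  # pragma: no cover
        raise NotImplementedError


class Identity(Layer):
    def forward(self, x, train=False, rng=None):
        return x

    def backward(self, g):
        return g


class Conv2d(Layer):
    """2-D convolution (cross-correlation), stride 1, optional time padding.

    pad = (left, right) zeros on the time axis.  Every kernel in this
    architecture spans a single axis, so two implementations are
    provided: an FFT path along the time axis (kernels (1, k) with
    k >= 8 — circular correlation over ``next_fast_len`` points is
    alias-free because N >= padded length), and a tap loop of
    (C_out, C_in) matmuls used for channel-axis kernels and as the
    cross-check reference.  Both forward and backward convolutions go
    through the same machinery.
    """

    def __init__(self, name, in_ch, out_ch, kernel, pad=(0, 0), rng=None):
        self.kh, self.kw = kernel
        self.pad = pad
        fan_in = in_ch * self.kh * self.kw
        self.W = Param(f"{name}.W",
                       _init_uniform(rng, (out_ch, in_ch, self.kh, self.kw),
                                     fan_in))
        self.b = Param(f"{name}.b", _init_uniform(rng, (out_ch,), fan_in))
        self.use_fft = self.kh == 1 and self.kw >= 8

    def params(self):
        return [self.W, self.b]

    # -- FFT path (time-axis kernels) -----------------------------------

    def _fft_forward(self, xp):
        B, Cin, H, Wp = xp.shape
        Cout = self.W.value.shape[0]
        k = self.kw
        Wo = Wp - k + 1
        N = sfft.next_fast_len(Wp)
        Xf = sfft.rfft(xp, n=N, axis=3)                      # (B,Cin,H,F)
        Wf = sfft.rfft(self.W.value[:, :, 0, :], n=N, axis=-1)
        F = Xf.shape[3]
        # correlation theorem: valid outputs of x (*) w = irfft(Xf conj(Wf))
        Xt = Xf.transpose(3, 0, 2, 1).reshape(F, B * H, Cin)
        Yt = Xt @ np.conj(Wf).transpose(2, 1, 0)             # (F,B*H,Cout)
        Yf = Yt.reshape(F, B, H, Cout).transpose(1, 3, 2, 0)
        out = sfft.irfft(Yf, n=N, axis=3)[:, :, :, :Wo].astype(np.float32)
        self._Xt, self._N, self._Wp = Xt, N, Wp
        return out

    def _fft_backward(self, g):
        B, Cout, Ho, Wo = g.shape
        Cin = self.W.value.shape[1]
        k = self.kw
        N, Wp = self._N, self._Wp
        Gf = sfft.rfft(g, n=N, axis=3)
        F = Gf.shape[3]
        Gt = Gf.transpose(3, 0, 2, 1).reshape(F, B * Ho, Cout)
        Wf = sfft.rfft(self.W.value[:, :, 0, :], n=N, axis=-1)
        # dW: correlation of the input with the output gradient
        dWt = np.matmul(self._Xt.transpose(0, 2, 1), np.conj(Gt))
        dWf = dWt.transpose(1, 2, 0)                          # (Cin,Cout,F)
        dW = sfft.irfft(dWf, n=N, axis=-1)[:, :, :k]
        self.W.grad += np.conj(dW).transpose(1, 0, 2)[:, :, None, :]
        # dx: full convolution of the gradient with the kernel
        dXt = Gt @ Wf.transpose(2, 0, 1)                      # (F,B*H,Cin)
        dXf = dXt.reshape(F, B, Ho, Cin).transpose(1, 3, 2, 0)
        return sfft.irfft(dXf, n=N, axis=3)[:, :, :, :Wp].astype(np.float32)

    # -- tap-loop path (reference / channel-axis kernels) ----------------

    def _tap_forward(self, xp):
        B, _, H, W = xp.shape
        Ho, Wo = H - self.kh + 1, W - self.kw + 1
        out = np.zeros((self.W.value.shape[0], B, Ho, Wo), dtype=np.float32)
        for i in range(self.kh):
            for j in range(self.kw):
                xs = xp[:, :, i : i + Ho, j : j + Wo]
                out += np.tensordot(self.W.value[:, :, i, j], xs,
                                    axes=([1], [1]))
        return np.moveaxis(out, 0, 1)

    def _tap_backward(self, g):
        xp = self._xp
        B, _, Ho, Wo = g.shape
        dxp = np.zeros_like(xp)
        gm = np.moveaxis(g, 1, 0)  # (Cout, B, Ho, Wo)
        for i in range(self.kh):
            for j in range(self.kw):
                xs = xp[:, :, i : i + Ho, j : j + Wo]
                self.W.grad[:, :, i, j] += np.tensordot(
                    gm, xs, axes=([1, 2, 3], [0, 2, 3])
                )
                dxp[:, :, i : i + Ho, j : j + Wo] += np.moveaxis(
                    np.tensordot(self.W.value[:, :, i, j], gm,
                                 axes=([0], [0])),
                    0, 1,
                )
        return dxp

    # -- public entry points ---------------------------------------------

    def forward(self, x, train=False, rng=None):
        pl, pr = self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (0, 0), (pl, pr))) if pl or pr else x
        if self.use_fft:
            out = self._fft_forward(xp)
        else:
            self._xp = xp
            out = self._tap_forward(xp)
        return out + self.b.value[None, :, None, None]

    def backward(self, g):
        self.b.grad += g.sum(axis=(0, 2, 3))
        dxp = self._fft_backward(g) if self.use_fft else self._tap_backward(g)
        pl, pr = self.pad
        if pl or pr:
            dxp = dxp[:, :, :, pl : dxp.shape[3] - pr]
        return dxp


class BatchNorm2d(Layer):
    """Per-filter normalization over (batch, channels, time)."""

    def __init__(self, name, n_ch, eps=1e-5, momentum=0.1):
        self.eps, self.momentum = eps, momentum
        self.gamma = Param(f"{name}.gamma", np.ones(n_ch, dtype=np.float32))
        self.beta = Param(f"{name}.beta", np.zeros(n_ch, dtype=np.float32))
        self.running_mean = np.zeros(n_ch, dtype=np.float32)
        self.running_var = np.ones(n_ch, dtype=np.float32)

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train=False, rng=None):
        axes = (0, 2, 3)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var)
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps).astype(np.float32)
        self._xhat = ((x - mean[None, :, None, None])
                      / self._std[None, :, None, None]).astype(np.float32)
        self._train = train
        return (self.gamma.value[None, :, None, None] * self._xhat
                + self.beta.value[None, :, None, None])

    def backward(self, g):
        axes = (0, 2, 3)
        xhat = self._xhat
        self.gamma.grad += (g * xhat).sum(axis=axes)
        self.beta.grad += g.sum(axis=axes)
        gs = self.gamma.value[None, :, None, None] / self._std[None, :, None, None]
        if not self._train:
            return g * gs
        m = g.mean(axis=axes, keepdims=True)
        mx = (g * xhat).mean(axis=axes, keepdims=True)
        return gs * (g - m - xhat * mx)


class ELU(Layer):
    def __init__(self, alpha=1.0):
        self.alpha = alpha

    def forward(self, x, train=False, rng=None):
        neg = self.alpha * np.expm1(np.minimum(x, 0.0))
        self._mask = x > 0
        self._neg = neg
        return np.where(self._mask, x, neg).astype(np.float32)

    def backward(self, g):
        return np.where(self._mask, g, g * (self._neg + self.alpha))


class Dropout(Layer):
    """Inverted dropout; identity in eval mode."""

    def __init__(self, p=0.5):
        self.p = p

    def forward(self, x, train=False, rng=None):
        if not train or self.p == 0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = (
            rng.random(x.shape, dtype=np.float32) < keep
        ).astype(np.float32) / keep
        return x * self._mask

    def backward(self, g):
        return g if self._mask is None else g * self._mask


class MaxPoolTime(Layer):
    """Non-overlapping max pooling (1, k) with stride k on the time axis."""

    def __init__(self, k=5):
        self.k = k

    def forward(self, x, train=False, rng=None):
        B, F, C, T = x.shape
        assert T % self.k == 0, "time length must divide the pool size"
        xr = x.reshape(B, F, C, T // self.k, self.k)
        self._arg = xr.argmax(axis=-1)
        self._shape = x.shape
        return xr.max(axis=-1)

    def backward(self, g):
        B, F, C, T = self._shape
        gr = np.zeros((B, F, C, T // self.k, self.k), dtype=g.dtype)
        np.put_along_axis(gr, self._arg[..., None], g[..., None], axis=-1)
        return gr.reshape(self._shape)


class Linear(Layer):
    """Affine map on the last axis; arbitrary leading axes."""

    def __init__(self, name, n_in, n_out, rng=None):
        self.W = Param(f"{name}.W", _init_uniform(rng, (n_out, n_in), n_in))
        self.b = Param(f"{name}.b", _init_uniform(rng, (n_out,), n_in))

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=False, rng=None):
        self._x = x
        return x @ self.W.value.T + self.b.value

    def backward(self, g):
        n_in = self.W.value.shape[1]
        n_out = self.W.value.shape[0]
        self.W.grad += g.reshape(-1, n_out).T @ self._x.reshape(-1, n_in)
        self.b.grad += g.reshape(-1, n_out).sum(axis=0)
        return g @ self.W.value


class AxisAttention(Layer):
    """Squeeze-style softmax attention over one feature-map axis.

    Pools the map over ``pool_axis`` (2 = channels for temporal
    attention, 3 = time for spatial attention), passes the pooled
    statistics through a bottleneck (Linear → tanh → Linear, weights
    shared across filters), and softmax-normalizes along the attended
    axis.  The map is rescaled elementwise by the resulting probability
    weights; no post-scaling is applied (the following batch norm
    absorbs the 1/N shrinkage).
    """

    def __init__(self, name, axis_len, hidden, pool_axis, rng=None,
                 force_uniform=False):
        if pool_axis not in (2, 3):
            raise ValueError("pool_axis must be 2 (channels) or 3 (time)")
        self.pool_axis = pool_axis
        self.lin1 = Linear(f"{name}.lin1", axis_len, hidden, rng=rng)
        self.lin2 = Linear(f"{name}.lin2", hidden, axis_len, rng=rng)
        self.force_uniform = force_uniform
        self.weights: np.ndarray | None = None  # last (B, F, L) probabilities

    def params(self):
        return self.lin1.params() + self.lin2.params()

    def forward(self, x, train=False, rng=None):
        if x.ndim != 4:
            raise ValueError("attention expects (batch, filters, "
                             "channels, time) feature maps")
        self._x = x
        L = x.shape[2] if self.pool_axis == 3 else x.shape[3]
        if self.force_uniform:
            shape = list(x.shape)
            shape[self.pool_axis] = 1
            B, F = x.shape[:2]
            self.weights = np.full((B, F, L), 1.0 / L, dtype=np.float32)
            self._a = None
            return x * np.float32(1.0 / L)
        pooled = x.mean(axis=self.pool_axis)                    # (B,F,L)
        self._h = np.tanh(self.lin1.forward(pooled))
        z = self.lin2.forward(self._h)
        self._a = softmax(z, axis=-1).astype(np.float32)
        self.weights = self._a
        return x * np.expand_dims(self._a, self.pool_axis)

    def backward(self, g):
        x = self._x
        if self._a is None:  # forced-uniform path
            L = x.shape[2] if self.pool_axis == 3 else x.shape[3]
            return g * np.float32(1.0 / L)
        a = np.expand_dims(self._a, self.pool_axis)
        dx = g * a
        da = (g * x).sum(axis=self.pool_axis)                   # (B,F,L)
        dz = self._a * (da - (da * self._a).sum(axis=-1, keepdims=True))
        dh = self.lin2.backward(dz)
        dpooled = self.lin1.backward(dh * (1.0 - self._h**2))
        n_pool = x.shape[self.pool_axis]
        dx += np.expand_dims(dpooled, self.pool_axis) / n_pool
        return dx


class Adam:
    """Adam with bias correction (beta1=0.9, beta2=0.999)."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        c1 = 1 - b1**self.t
        c2 = 1 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad**2
            p.value -= self.lr * (m / c1) / (np.sqrt(v / c2) + self.eps)


def cross_entropy(logits: np.ndarray, y: np.ndarray):
    """Mean categorical cross-entropy and its gradient w.r.t. logits."""
    p = softmax(logits, axis=-1)
    n = len(y)
    loss = -np.log(np.clip(p[np.arange(n), y], 1e-12, None)).mean()
    grad = p.copy()
    grad[np.arange(n), y] -= 1.0
    return float(loss), (grad / n).astype(np.float32)
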