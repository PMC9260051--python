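"""Minimal neural-network layers with explicit forward/backward passes.

The reconstruction networks in this package are small (a voxel-wise MLP,
a fingerprint MLP surrogate, and a 2-D u-net operating on a single fixed
input), so the layers are written directly on numpy arrays in float32 with
hand-derived gradients: dense and 3x3 convolution (im2col + BLAS matmul),
batch normalization over spatial positions, leaky-ReLU, inverted dropout,
nearest-neighbor upsampling, and an Adam optimizer.  Everything is
deterministic given the `numpy` Generator handed to the constructors.

Convolutions process one image at a time in (channels, H, W) layout; dense
layers process (batch, features).
"""

from __future__ import annotations

import numpy as np

__all__ = ["Param", "Dense", "LeakyReLU", "Dropout", "Conv2d", "BatchNorm2d",
           "NearestUpsample2", "Adam", "Sequential"]

DTYPE = np.float32


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value):
        self.value = np.asarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)


class Layer:
    def params(self):
        return []

    def forward(self, x, train=True):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, g):  # pragma: no cover - interface
        raise NotImplementedError


class Dense(Layer):
    """Affine layer y = x @ W + b for (batch, features) inputs."""

    def __init__(self, n_in, n_out, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.W = Param(rng.standard_normal((n_in, n_out)) * scale)
        self.b = Param(np.zeros(n_out))
        self._x = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=True):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, g):
        self.W.grad += self._x.T @ g
        self.b.grad += g.sum(axis=0)
        return g @ self.W.value.T


class LeakyReLU(Layer):
    def __init__(self, slope=0.1):
        self.slope = DTYPE(slope)
        self._mask = None

    def forward(self, x, train=True):
        self._mask = x >= 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, g):
        return np.where(self._mask, g, self.slope * g)


class Dropout(Layer):
    """Inverted dropout; identity when rate == 0 or in eval mode."""

    def __init__(self, rate, rng: np.random.Generator):
        if not (0 <= rate < 1):
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng
        self._mask = None

    def forward(self, x, train=True):
        if not train or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(DTYPE) / DTYPE(keep)
        return x * self._mask

    def backward(self, g):
        if self._mask is None:
            return g
        return g * self._mask


class Conv2d(Layer):
    """3x3 (or kxk) 'same' convolution on (C, H, W), stride 1 or 2."""

    def __init__(self, c_in, c_out, rng: np.random.Generator, ksize=3, stride=1):
        if ksize % 2 != 1:
            raise ValueError("odd kernel sizes only")
        scale = np.sqrt(2.0 / (c_in * ksize * ksize))
        self.W = Param(rng.standard_normal((c_in * ksize * ksize, c_out)) * scale)
        self.b = Param(np.zeros(c_out))
        self.ksize = ksize
        self.stride = stride
        self.c_in, self.c_out = c_in, c_out
        self._cols = None
        self._inshape = None

    def params(self):
        return [self.W, self.b]

    def _im2col(self, x):
        k, s = self.ksize, self.stride
        pad = k // 2
        xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
        win = win[:, ::s, ::s]                     # (C, H', W', k, k)
        c, ho, wo = win.shape[:3]
        cols = win.transpose(1, 2, 0, 3, 4).reshape(ho * wo, c * k * k)
        return np.ascontiguousarray(cols), ho, wo

    def forward(self, x, train=True):
        self._inshape = x.shape
        cols, ho, wo = self._im2col(x)
        self._cols = cols
        out = cols @ self.W.value + self.b.value
        return out.reshape(ho, wo, self.c_out).transpose(2, 0, 1)

    def backward(self, g):
        c_in, H, W = self._inshape
        k, s = self.ksize, self.stride
        pad = k // 2
        co, ho, wo = g.shape
        gmat = g.transpose(1, 2, 0).reshape(ho * wo, co)
        self.W.grad += self._cols.T @ gmat
        self.b.grad += gmat.sum(axis=0)
        gcols = (gmat @ self.W.value.T).reshape(ho, wo, c_in, k, k)
        dxp = np.zeros((c_in, H + 2 * pad, W + 2 * pad), dtype=g.dtype)
        for dy in range(k):
            for dx in range(k):
                dxp[:, dy:dy + s * ho:s, dx:dx + s * wo:s] += (
                    gcols[:, :, :, dy, dx].transpose(2, 0, 1))
        return dxp[:, pad:pad + H, pad:pad + W]


class BatchNorm2d(Layer):
    """Channel-wise normalization over spatial positions (single image)."""

    def __init__(self, c, momentum=0.1, eps=1e-5):
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))
        self.momentum = momentum
        self.eps = DTYPE(eps)
        self.running_mean = np.zeros(c, dtype=DTYPE)
        self.running_var = np.ones(c, dtype=DTYPE)
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train=True):
        if train:
            mu = x.mean(axis=(1, 2))
            var = x.var(axis=(1, 2))
            self.running_mean += self.momentum * (mu - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu[:, None, None]) * inv[:, None, None]
        self._cache = (xhat, inv, train)
        return self.gamma.value[:, None, None] * xhat + self.beta.value[:, None, None]

    def backward(self, g):
        xhat, inv, train = self._cache
        self.gamma.grad += (g * xhat).sum(axis=(1, 2))
        self.beta.grad += g.sum(axis=(1, 2))
        gh = g * self.gamma.value[:, None, None]
        if not train:
            return gh * inv[:, None, None]
        n = xhat.shape[1] * xhat.shape[2]
        return (inv[:, None, None] / n) * (
            n * gh
            - gh.sum(axis=(1, 2), keepdims=True)
            - xhat * (gh * xhat).sum(axis=(1, 2), keepdims=True)
        )


class NearestUpsample2(Layer):
    """2x nearest-neighbor upsampling on (C, H, W)."""

    def forward(self, x, train=True):
        return x.repeat(2, axis=1).repeat(2, axis=2)

    def backward(self, g):
        c, h2, w2 = g.shape
        return g.reshape(c, h2 // 2, 2, w2 // 2, 2).sum(axis=(2, 4))


class Sequential(Layer):
    def __init__(self, *layers):
        self.layers = list(layers)

    def params(self):
        out = []
        for lay in self.layers:
            out.extend(lay.params())
        return out

    def forward(self, x, train=True):
        for lay in self.layers:
            x = lay.forward(x, train=train)
        return x

    def backward(self, g):
        for lay in reversed(self.layers):
            g = lay.backward(g)
        return g


class Adam:
    """Adam optimizer over a fixed parameter list; zeroes grads on step."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
            p.grad[:] = 0.0

    def zero_grad(self):
        for p in self.params:
            p.grad[:] = 0.0
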