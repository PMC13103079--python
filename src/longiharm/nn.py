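"""Minimal CPU neural-network layers with explicit forward/backward passes.

Implements just what the translation model needs: 2D convolution (im2col),
instance normalization, ReLU / leaky ReLU / sigmoid, residual blocks, a
sequential container and Adam. Every layer's ``forward`` returns
``(output, cache)``; ``backward(cache, grad_out)`` accumulates parameter
gradients (so one layer instance can appear in several forward applications
per iteration, as the cycle paths require) and returns the input gradient.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "Conv2d",
    "InstanceNorm2d",
    "ReLU",
    "LeakyReLU",
    "Sigmoid",
    "ResidualBlock",
    "Sequential",
    "Adam",
]

F32 = np.float32


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=F32)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad.fill(0.0)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray):  # -> (y, cache)
        raise NotImplementedError

    def backward(self, cache, grad_out: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2d(Layer):
    """Same/valid 2D convolution via im2col. Input (N, Cin, H, W)."""

    def __init__(self, cin: int, cout: int, k: int, stride: int = 1, pad: int | None = None,
                 rng: np.random.Generator | None = None):
        self.cin, self.cout, self.k, self.stride = cin, cout, k, stride
        self.pad = (k - 1) // 2 if pad is None else pad
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / (cin * k * k))
        self.W = Param(rng.normal(0.0, scale, size=(cout, cin, k, k)))
        self.b = Param(np.zeros(cout))

    def params(self):
        return [self.W, self.b]

    def forward(self, x):
        x = np.asarray(x, dtype=F32)
        n, cin, h, w = x.shape
        if cin != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {cin}")
        p, k, s = self.pad, self.k, self.stride
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        ho = (h + 2 * p - k) // s + 1
        wo = (w + 2 * p - k) // s + 1
        # conv as a sum of k*k shifted 1x1 convolutions (batched matmuls)
        y = np.zeros((n, self.cout, ho * wo), dtype=F32)
        xs_flat = []
        for ki in range(k):
            for kj in range(k):
                xs = xp[:, :, ki : ki + s * ho : s, kj : kj + s * wo : s]
                xs = np.ascontiguousarray(xs).reshape(n, cin, ho * wo)
                y += self.W.value[:, :, ki, kj] @ xs
                xs_flat.append(xs)
        y = y.reshape(n, self.cout, ho, wo)
        y += self.b.value[None, :, None, None]
        return y, (xs_flat, x.shape, (ho, wo))

    def backward(self, cache, grad_out):
        xs_flat, x_shape, (ho, wo) = cache
        n, cin, h, w = x_shape
        p, k, s = self.pad, self.k, self.stride
        go = np.ascontiguousarray(grad_out, dtype=F32).reshape(n, self.cout, ho * wo)
        self.b.grad += go.sum(axis=(0, 2))
        dxp = np.zeros((n, cin, h + 2 * p, w + 2 * p), dtype=F32)
        for ki in range(k):
            for kj in range(k):
                xs = xs_flat[ki * k + kj]
                self.W.grad[:, :, ki, kj] += (go @ xs.transpose(0, 2, 1)).sum(axis=0)
                dxs = (self.W.value[:, :, ki, kj].T @ go).reshape(n, cin, ho, wo)
                dxp[:, :, ki : ki + s * ho : s, kj : kj + s * wo : s] += dxs
        return dxp[:, :, p : p + h, p : p + w] if p else dxp


class InstanceNorm2d(Layer):
    """Per-sample, per-channel normalization over spatial dims, affine."""

    EPS = 1e-5

    def __init__(self, c: int):
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x):
        mu = x.mean(axis=(2, 3), keepdims=True)
        var = x.var(axis=(2, 3), keepdims=True)
        inv = 1.0 / np.sqrt(var + self.EPS)
        xhat = (x - mu) * inv
        y = xhat * self.gamma.value[None, :, None, None] + self.beta.value[None, :, None, None]
        return y.astype(F32), (xhat, inv)

    def backward(self, cache, grad_out):
        xhat, inv = cache
        g = self.gamma.value[None, :, None, None]
        self.gamma.grad += (grad_out * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += grad_out.sum(axis=(0, 2, 3))
        dxhat = grad_out * g
        m = xhat.shape[2] * xhat.shape[3]
        dx = (
            inv / m * (m * dxhat - dxhat.sum(axis=(2, 3), keepdims=True)
                       - xhat * (dxhat * xhat).sum(axis=(2, 3), keepdims=True))
        )
        return dx.astype(F32)


class ReLU(Layer):
    def forward(self, x):
        y = np.maximum(x, 0)
        return y, (x > 0)

    def backward(self, cache, grad_out):
        return grad_out * cache


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.2):
        self.slope = slope

    def forward(self, x):
        mask = x > 0
        return np.where(mask, x, self.slope * x).astype(F32), mask

    def backward(self, cache, grad_out):
        return np.where(cache, grad_out, self.slope * grad_out).astype(F32)


class Sigmoid(Layer):
    def forward(self, x):
        y = 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))
        return y.astype(F32), y

    def backward(self, cache, grad_out):
        y = cache
        return (grad_out * y * (1.0 - y)).astype(F32)


class ResidualBlock(Layer):
    """conv-norm-relu-conv-norm plus skip connection."""

    def __init__(self, c: int, norm: str = "instance", rng: np.random.Generator | None = None):
        self.conv1 = Conv2d(c, c, 3, rng=rng)
        self.conv2 = Conv2d(c, c, 3, rng=rng)
        self.norm1 = InstanceNorm2d(c) if norm == "instance" else None
        self.norm2 = InstanceNorm2d(c) if norm == "instance" else None
        self.relu = ReLU()

    def params(self):
        ps = self.conv1.params() + self.conv2.params()
        for nrm in (self.norm1, self.norm2):
            if nrm is not None:
                ps += nrm.params()
        return ps

    def forward(self, x):
        h, c1 = self.conv1.forward(x)
        n1 = None
        if self.norm1 is not None:
            h, n1 = self.norm1.forward(h)
        h, cr = self.relu.forward(h)
        h, c2 = self.conv2.forward(h)
        n2 = None
        if self.norm2 is not None:
            h, n2 = self.norm2.forward(h)
        return (x + h).astype(F32), (c1, n1, cr, c2, n2)

    def backward(self, cache, grad_out):
        c1, n1, cr, c2, n2 = cache
        g = grad_out
        if self.norm2 is not None:
            g = self.norm2.backward(n2, g)
        g = self.conv2.backward(c2, g)
        g = self.relu.backward(cr, g)
        if self.norm1 is not None:
            g = self.norm1.backward(n1, g)
        g = self.conv1.backward(c1, g)
        return (grad_out + g).astype(F32)


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x):
        caches = []
        for layer in self.layers:
            x, c = layer.forward(x)
            caches.append(c)
        return x, caches

    def backward(self, caches, grad_out):
        for layer, c in zip(reversed(self.layers), reversed(caches)):
            grad_out = layer.backward(c, grad_out)
        return grad_out


class Adam:
    """Adam over a parameter list; lr is settable per step for schedules."""

    def __init__(self, params: list[Param], lr: float = 2e-4, beta1: float = 0.5,
                 beta2: float = 0.99, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self, lr: float | None = None) -> None:
        if lr is not None:
            self.lr = lr
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.value -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(F32)

    def state_dict(self) -> dict:
        return {
            "t": self.t,
            "m": [m.copy() for m in self.m],
            "v": [v.copy() for v in self.v],
        }

    def load_state_dict(self, state: dict) -> None:
        self.t = state["t"]
        for m, src in zip(self.m, state["m"]):
            m[...] = src
        for v, src in zip(self.v, state["v"]):
            v[...] = src
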