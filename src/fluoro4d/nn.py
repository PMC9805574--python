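"""Minimal numpy neural-network layers with manual backpropagation.

Only what the reslicing GAN needs: 3D convolution (stride 1, configurable
per-axis kernel, 'same' padding), instance normalization, leaky rectifier,
tanh, XY average pooling / nearest-neighbour upsampling, an Adam optimizer
and seeded truncated-normal initialization.

Convolutions are evaluated as im2col + GEMM, chunked along the first spatial
axis so the unfolded column matrix stays within a fixed memory budget; this
keeps paper-scale (256 x 256 x 16) frames tractable on one CPU.  Layers cache
their forward inputs per call and accumulate parameter gradients in-place, so
one set of weights can be applied to many frames per step (the generator
shares encoder weights across all t-frames / z-slices) with gradients summed
over applications.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

#: cap on the im2col scratch buffer (bytes)
_CHUNK_BYTES = 96 * 2**20


def truncated_normal(rng: np.random.Generator, shape, std: float = 0.02) -> np.ndarray:
    """Normal(0, std) samples redrawn while outside +-2 std (seeded)."""
    x = rng.normal(0.0, std, size=shape)
    for _ in range(8):
        bad = np.abs(x) > 2 * std
        if not bad.any():
            break
        x[bad] = rng.normal(0.0, std, size=int(bad.sum()))
    return np.clip(x, -2 * std, 2 * std).astype(np.float32)


def conv_init(rng: np.random.Generator, shape) -> np.ndarray:
    """Fan-in-scaled truncated-normal kernel init (He-style for leaky units).

    A fixed small sigma leaves the un-normalized stem and skip paths orders
    of magnitude under-scaled relative to the normalized trunk, which costs
    hundreds of optimizer steps just to grow the weights; scaling by
    1/sqrt(fan_in) starts every path at unit signal variance.
    """
    fan_in = int(np.prod(shape[1:]))
    return truncated_normal(rng, shape, std=1.4 / np.sqrt(fan_in))


# ---------------------------------------------------------------------------
# raw conv3d
# ---------------------------------------------------------------------------


def _conv3d(x: np.ndarray, W: np.ndarray, pads) -> np.ndarray:
    """Correlate ``x`` (C_in, D1, D2, D3) with ``W`` (C_out, C_in, k1, k2, k3).

    ``pads`` is ((l1, r1), (l2, r2), (l3, r3)); stride is always 1.
    """
    C_in, D1, D2, D3 = x.shape
    C_out, _, k1, k2, k3 = W.shape
    xp = np.pad(x, ((0, 0),) + tuple(pads))
    O1 = xp.shape[1] - k1 + 1
    O2 = xp.shape[2] - k2 + 1
    O3 = xp.shape[3] - k3 + 1
    Wm = W.reshape(C_out, -1)
    dtype = np.result_type(x.dtype, W.dtype)
    out = np.empty((C_out, O1, O2, O3), dtype=dtype)
    row_bytes = C_in * k1 * k2 * k3 * O2 * O3 * xp.itemsize
    chunk = max(1, _CHUNK_BYTES // max(row_bytes, 1))
    for i0 in range(0, O1, chunk):
        i1 = min(O1, i0 + chunk)
        win = sliding_window_view(xp[:, i0 : i1 + k1 - 1], (k1, k2, k3), axis=(1, 2, 3))
        cols = np.ascontiguousarray(win.transpose(1, 2, 3, 0, 4, 5, 6)).reshape(
            (i1 - i0) * O2 * O3, -1
        )
        out[:, i0:i1] = (cols @ Wm.T).T.reshape(C_out, i1 - i0, O2, O3)
    return out


def _conv3d_wgrad(x: np.ndarray, gy: np.ndarray, ksize, pads) -> np.ndarray:
    """Gradient of the correlation w.r.t. the kernel."""
    C_in = x.shape[0]
    C_out = gy.shape[0]
    k1, k2, k3 = ksize
    xp = np.pad(x, ((0, 0),) + tuple(pads))
    O1, O2, O3 = gy.shape[1:]
    gW = np.zeros((C_out, C_in * k1 * k2 * k3), dtype=np.result_type(x.dtype, gy.dtype))
    row_bytes = C_in * k1 * k2 * k3 * O2 * O3 * xp.itemsize
    chunk = max(1, _CHUNK_BYTES // max(row_bytes, 1))
    for i0 in range(0, O1, chunk):
        i1 = min(O1, i0 + chunk)
        win = sliding_window_view(xp[:, i0 : i1 + k1 - 1], (k1, k2, k3), axis=(1, 2, 3))
        cols = np.ascontiguousarray(win.transpose(1, 2, 3, 0, 4, 5, 6)).reshape(
            (i1 - i0) * O2 * O3, -1
        )
        gm = gy[:, i0:i1].reshape(C_out, -1)
        gW += gm @ cols
    return gW.reshape(C_out, C_in, k1, k2, k3)


def _conv3d_xgrad(gy: np.ndarray, W: np.ndarray, pads) -> np.ndarray:
    """Gradient of the correlation w.r.t. the input (full correlation with
    the flipped, channel-transposed kernel and swapped padding)."""
    Wt = np.ascontiguousarray(W.transpose(1, 0, 2, 3, 4)[:, :, ::-1, ::-1, ::-1])
    swapped = tuple((r, l) for (l, r) in pads)
    return _conv3d(gy, Wt, swapped)


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------


class Layer:
    """Base layer: forward returns (y, cache); backward consumes the cache,
    accumulates parameter gradients in-place and returns grad w.r.t. input."""

    def params(self):
        return []

    def grads(self):
        return []

    def zero_grads(self):
        for g in self.grads():
            g[...] = 0.0

    def forward(self, x):
        raise NotImplementedError

    def backward(self, gy, cache):
        raise NotImplementedError


class Conv3d(Layer):
    """3D correlation, stride 1, 'same' padding (asymmetric for even kernels)."""

    def __init__(self, c_in, c_out, kernel=(3, 3, 3), rng=None):
        rng = rng or np.random.default_rng(0)
        self.W = conv_init(rng, (c_out, c_in, *kernel))
        self.b = np.zeros(c_out, dtype=np.float32)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self.pads = tuple(((k - 1) // 2, k // 2) for k in kernel)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.gW, self.gb]

    def forward(self, x):
        y = _conv3d(x, self.W, self.pads) + self.b[:, None, None, None]
        return y, x

    def backward(self, gy, cache):
        x = cache
        self.gb += gy.sum(axis=(1, 2, 3))
        self.gW += _conv3d_wgrad(x, gy, self.W.shape[2:], self.pads)
        return _conv3d_xgrad(gy, self.W, self.pads)


class InstanceNorm(Layer):
    """Per-channel normalization over the spatial axes, with affine params."""

    def __init__(self, c, eps=1e-5):
        self.gamma = np.ones(c, dtype=np.float32)
        self.beta = np.zeros(c, dtype=np.float32)
        self.ggamma = np.zeros_like(self.gamma)
        self.gbeta = np.zeros_like(self.beta)
        self.eps = eps

    def params(self):
        return [self.gamma, self.beta]

    def grads(self):
        return [self.ggamma, self.gbeta]

    def forward(self, x):
        ax = (1, 2, 3)
        mu = x.mean(axis=ax, keepdims=True)
        var = x.var(axis=ax, keepdims=True)
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv_std
        y = self.gamma[:, None, None, None] * xhat + self.beta[:, None, None, None]
        return y, (xhat, inv_std)

    def backward(self, gy, cache):
        xhat, inv_std = cache
        ax = (1, 2, 3)
        n = xhat[0].size
        self.ggamma += (gy * xhat).sum(axis=ax)
        self.gbeta += gy.sum(axis=ax)
        gxh = gy * self.gamma[:, None, None, None]
        gx = (
            inv_std
            / n
            * (n * gxh - gxh.sum(axis=ax, keepdims=True) - xhat * (gxh * xhat).sum(axis=ax, keepdims=True))
        )
        return gx


class LeakyReLU(Layer):
    def __init__(self, alpha=0.2):
        self.alpha = alpha

    def forward(self, x):
        y = np.where(x >= 0, x, self.alpha * x)
        return y, x >= 0

    def backward(self, gy, cache):
        return np.where(cache, gy, self.alpha * gy)


class Tanh(Layer):
    def forward(self, x):
        y = np.tanh(x)
        return y, y

    def backward(self, gy, cache):
        return gy * (1.0 - cache * cache)


class AvgPool(Layer):
    """Average pooling by integer factors per spatial axis (extents must divide)."""

    def __init__(self, factors=(2, 2, 1)):
        self.factors = factors

    def forward(self, x):
        C, D1, D2, D3 = x.shape
        f1, f2, f3 = self.factors
        if D1 % f1 or D2 % f2 or D3 % f3:
            raise ValueError(f"extents {x.shape[1:]} not divisible by pool factors {self.factors}")
        y = x.reshape(C, D1 // f1, f1, D2 // f2, f2, D3 // f3, f3).mean(axis=(2, 4, 6))
        return y, x.shape

    def backward(self, gy, cache):
        f1, f2, f3 = self.factors
        scale = 1.0 / (f1 * f2 * f3)
        g = gy * scale
        g = np.repeat(g, f1, axis=1)
        g = np.repeat(g, f2, axis=2)
        g = np.repeat(g, f3, axis=3)
        return g


class NearestUpsample(Layer):
    """Nearest-neighbour upsampling by integer factors per spatial axis."""

    def __init__(self, factors=(2, 2, 1)):
        self.factors = factors

    def forward(self, x):
        f1, f2, f3 = self.factors
        y = np.repeat(np.repeat(np.repeat(x, f1, axis=1), f2, axis=2), f3, axis=3)
        return y, x.shape

    def backward(self, gy, cache):
        C, D1, D2, D3 = cache
        f1, f2, f3 = self.factors
        g = gy.reshape(C, D1, f1, D2, f2, D3, f3).sum(axis=(2, 4, 6))
        return g


class Chain(Layer):
    """Sequential composition of layers."""

    def __init__(self, layers):
        self.layers = list(layers)

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def grads(self):
        return [g for l in self.layers for g in l.grads()]

    def forward(self, x):
        caches = []
        for l in self.layers:
            x, c = l.forward(x)
            caches.append(c)
        return x, caches

    def backward(self, gy, caches):
        for l, c in zip(reversed(self.layers), reversed(caches)):
            gy = l.backward(gy, c)
        return gy


class Adam:
    """Adam over an explicit (params, grads) pairing; updates in-place."""

    def __init__(self, params, grads, lr=2e-4, betas=(0.5, 0.999), eps=1e-8):
        self.params = params
        self.grads = grads
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def n_parameters(layer: Layer) -> int:
    return int(sum(p.size for p in layer.params()))
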