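"""Minimal NumPy neural-network primitives with explicit backpropagation.

Only what the reconstruction networks need: N-dimensional convolutions
(stride 1, zero padding to preserve the grid), channelwise (FiLM-style)
feature modulation, Tanh / leaky-ReLU activations, dense layers, and an
Adam optimizer.  Convolutions are evaluated as a sum of tensordots over
kernel offsets, which keeps the same code path for 2D and 3D kernels and
hands the inner products to BLAS.

All forward functions return (output, cache); the matching backward
functions take the upstream gradient plus the cache and return input and
parameter gradients.  Everything is float64 and deterministic given the
seeded initializer.
"""

from __future__ import annotations

import itertools

import numpy as np

__all__ = [
    "conv_init", "conv_forward", "conv_backward",
    "dense_init", "dense_forward", "dense_backward",
    "film_forward", "film_backward",
    "tanh_forward", "tanh_backward",
    "leaky_relu_forward", "leaky_relu_backward",
    "Adam",
]


# ---------------------------------------------------------------- conv --

def conv_init(rng: np.random.Generator, c_out: int, c_in: int, kernel: int,
              ndim: int) -> tuple[np.ndarray, np.ndarray]:
    """He-style initialization for an ndim-D conv weight plus zero bias."""
    shape = (c_out, c_in) + (kernel,) * ndim
    fan_in = c_in * kernel ** ndim
    w = rng.normal(scale=np.sqrt(2.0 / fan_in), size=shape)
    return w, np.zeros(c_out)


def _pad_spatial(x: np.ndarray, pad: int) -> np.ndarray:
    width = [(0, 0)] + [(pad, pad)] * (x.ndim - 1)
    return np.pad(x, width)


def conv_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray):
    """Same-size convolution (cross-correlation); x is (C_in, *spatial)."""
    k = w.shape[2]
    ndim = w.ndim - 2
    pad = (k - 1) // 2
    spatial = x.shape[1:]
    xp = _pad_spatial(x, pad)
    out = np.zeros((w.shape[0],) + spatial)
    for off in itertools.product(range(k), repeat=ndim):
        sl = (slice(None),) + tuple(slice(o, o + s) for o, s in zip(off, spatial))
        out += np.tensordot(w[(slice(None), slice(None)) + off], xp[sl], axes=(1, 0))
    out += b.reshape((-1,) + (1,) * ndim)
    return out, (xp, w)


def conv_backward(gout: np.ndarray, cache):
    xp, w = cache
    k = w.shape[2]
    ndim = w.ndim - 2
    pad = (k - 1) // 2
    spatial = gout.shape[1:]
    gw = np.zeros_like(w)
    gxp = np.zeros_like(xp)
    for off in itertools.product(range(k), repeat=ndim):
        sl = (slice(None),) + tuple(slice(o, o + s) for o, s in zip(off, spatial))
        patch = xp[sl]
        # gw[co, ci, off] = sum_space gout[co] * xp[ci, shifted]
        gw[(slice(None), slice(None)) + off] = np.tensordot(
            gout, patch, axes=(list(range(1, 1 + ndim)), list(range(1, 1 + ndim))))
        gxp[sl] += np.tensordot(w[(slice(None), slice(None)) + off], gout,
                                axes=(0, 0))
    gb = gout.reshape(gout.shape[0], -1).sum(axis=1)
    if pad:
        core = (slice(None),) + tuple(slice(pad, pad + s) for s in spatial)
        gx = gxp[core]
    else:
        gx = gxp
    return gx, gw, gb


# --------------------------------------------------------------- dense --

def dense_init(rng: np.random.Generator, n_out: int, n_in: int):
    w = rng.normal(scale=np.sqrt(2.0 / max(n_in, 1)), size=(n_out, n_in))
    return w, np.zeros(n_out)


def dense_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray):
    return w @ x + b, (x, w)


def dense_backward(gout: np.ndarray, cache):
    x, w = cache
    return w.T @ gout, np.outer(gout, x), gout.copy()


# ---------------------------------------------------------- film/gains --

def film_forward(x: np.ndarray, gains: np.ndarray):
    """Channelwise multiplication of feature maps by a gain vector."""
    g = gains.reshape((-1,) + (1,) * (x.ndim - 1))
    return x * g, (x, gains)


def film_backward(gout: np.ndarray, cache):
    x, gains = cache
    g = gains.reshape((-1,) + (1,) * (x.ndim - 1))
    ggains = (gout * x).reshape(x.shape[0], -1).sum(axis=1)
    return gout * g, ggains


# ----------------------------------------------------------- activation --

def tanh_forward(x: np.ndarray):
    y = np.tanh(x)
    return y, y


def tanh_backward(gout: np.ndarray, y: np.ndarray):
    return gout * (1.0 - y * y)


def leaky_relu_forward(x: np.ndarray, slope: float):
    mask = x >= 0
    return np.where(mask, x, slope * x), (mask, slope)


def leaky_relu_backward(gout: np.ndarray, cache):
    mask, slope = cache
    return np.where(mask, gout, slope * gout)


# ---------------------------------------------------------------- adam --

class Adam:
    """Adam with the standard default moments (0.9, 0.999, eps 1e-8)."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8,
                 lr_scales: dict[str, float] | None = None):
        self.params = params
        self.lr = lr
        self.lr_scales = lr_scales or {}
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, p in self.params.items():
            g = grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            p -= self.lr * self.lr_scales.get(k, 1.0) * mhat / (np.sqrt(vhat) + self.eps)
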