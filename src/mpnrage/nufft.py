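"""Non-uniform FFT by Kaiser-Bessel gridding.

Implements the type-2 (image -> nonuniform samples) transform

    s(k) = sum_p x[p] * exp(-2*pi*i * k . p),   p = n - N//2,

with k in Nyquist-normalized cycles/pixel, |k| <= 0.5, and its exact
adjoint.  The pipeline is the standard one: deapodize, zero-pad to an
oversampled grid, FFT, and interpolate onto the sample locations with a
separable Kaiser-Bessel kernel.  The interpolation is precomputed as
flat gather indices plus weights, so forward is a gather-multiply-sum
and the adjoint is the corresponding scatter (bincount) — the two are
transposes of each other by construction, which makes the operator pair
adjoint to machine precision independent of kernel accuracy.

Defaults (oversampling 2.0, kernel width 7, Beatty beta) give a max
pointwise error around 1e-6 of the peak against the direct discrete
Fourier sum on small grids.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy.special import i0

__all__ = ["NufftPlan", "direct_nudft", "direct_nudft_adjoint"]


def _kb_beta(width: int, osf: float) -> float:
    """Beatty et al. optimal Kaiser-Bessel shape parameter."""
    return np.pi * np.sqrt((width / osf) ** 2 * (osf - 0.5) ** 2 - 0.8)


def _kb_kernel(t: np.ndarray, width: int, beta: float) -> np.ndarray:
    """Kaiser-Bessel kernel on |t| <= width/2 (t in oversampled-grid units)."""
    arg = 1.0 - (2.0 * t / width) ** 2
    out = np.zeros_like(t, dtype=float)
    ok = arg >= 0
    out[ok] = i0(beta * np.sqrt(arg[ok])) / i0(beta)
    return out


@lru_cache(maxsize=64)
def _deapodization(n_os: int, n: int, width: int, beta: float) -> np.ndarray:
    """Fourier transform of the gridding kernel at image pixel offsets.

    Computed by dense numerical quadrature of the continuous kernel,
    which is robust for any (width, beta); cached per configuration.
    """
    t = np.linspace(-width / 2, width / 2, 4001)
    c = _kb_kernel(t, width, beta)
    p = np.arange(n) - n // 2
    nu = p / n_os  # cycles per oversampled sample
    # c is even -> cosine transform
    ft = np.trapezoid(c[None, :] * np.cos(2 * np.pi * nu[:, None] * t[None, :]),
                      t, axis=1)
    return ft


class NufftPlan:
    """Precomputed gridding NUFFT for a fixed grid and coordinate set.

    Parameters
    ----------
    grid_shape : image dimensions (2D or 3D).
    coords : (M, d) sample locations in cycles/pixel, within [-0.5, 0.5].
    oversamp : k-space oversampling factor (default 2.0).
    width : kernel width in oversampled-grid samples (default 7).
    """

    def __init__(self, grid_shape, coords, oversamp: float = 2.0, width: int = 7):
        self.grid_shape = tuple(int(n) for n in grid_shape)
        coords = np.ascontiguousarray(np.asarray(coords, float))
        if coords.ndim != 2 or coords.shape[1] != len(self.grid_shape):
            raise ValueError("coords must be (M, d) matching grid dimensionality")
        if np.abs(coords).max(initial=0.0) > 0.5 + 1e-9:
            raise ValueError("coords must lie within the Nyquist box [-0.5, 0.5]")
        self.coords = coords
        self.ndim = len(self.grid_shape)
        self.n_samples = coords.shape[0]
        self.width = int(width)
        self.os_shape = tuple(2 * ((int(np.ceil(n * oversamp)) + 1) // 2)
                              for n in self.grid_shape)
        self.beta = _kb_beta(self.width, oversamp)
        self._build_interpolator()
        self._build_deapod()

    def _build_interpolator(self) -> None:
        W = self.width
        offsets = np.arange(W)
        idx_nd = []
        wts = np.ones((self.n_samples, 1))
        for d, G in enumerate(self.os_shape):
            g = self.coords[:, d] * G                     # position in os-grid units
            j0 = np.ceil(g - W / 2.0).astype(np.int64)    # leftmost neighbor
            j = j0[:, None] + offsets[None, :]            # (M, W)
            w = _kb_kernel(g[:, None] - j, W, self.beta)
            idx_nd.append((j + G // 2) % G)               # wrap, shift DC to center
            wts = (wts[:, :, None] * w[:, None, :]).reshape(self.n_samples, -1)
        flat = idx_nd[0]
        for d in range(1, self.ndim):
            G = self.os_shape[d]
            flat = (flat[:, :, None] * G + idx_nd[d][:, None, :]).reshape(
                self.n_samples, -1)
        self._flat_idx = np.ascontiguousarray(flat.astype(np.int64))
        self._weights = np.ascontiguousarray(wts)
        self._os_size = int(np.prod(self.os_shape))

    def _build_deapod(self) -> None:
        apod = np.ones(self.grid_shape)
        for d, (n, G) in enumerate(zip(self.grid_shape, self.os_shape)):
            ft = _deapodization(G, n, self.width, self.beta)
            shape = [1] * self.ndim
            shape[d] = n
            apod = apod * ft.reshape(shape)
        self._deapod = 1.0 / apod

    # -- core transforms ------------------------------------------------

    def _pad_slices(self):
        return tuple(slice(G // 2 - n // 2, G // 2 - n // 2 + n)
                     for n, G in zip(self.grid_shape, self.os_shape))

    def forward(self, image: np.ndarray) -> np.ndarray:
        """Image -> complex samples at the plan's coordinates."""
        if image.shape != self.grid_shape:
            raise ValueError(f"image shape {image.shape} != {self.grid_shape}")
        xpad = np.zeros(self.os_shape, dtype=complex)
        xpad[self._pad_slices()] = image * self._deapod
        spec = np.fft.fftshift(np.fft.fftn(np.fft.ifftshift(xpad)))
        return (spec.ravel()[self._flat_idx] * self._weights).sum(axis=1)

    def adjoint(self, samples: np.ndarray) -> np.ndarray:
        """Exact adjoint: samples -> image grid."""
        samples = np.asarray(samples)
        if samples.shape != (self.n_samples,):
            raise ValueError("samples shape mismatch")
        contrib = samples[:, None] * self._weights
        idx = self._flat_idx.ravel()
        spec = (np.bincount(idx, weights=contrib.real.ravel(), minlength=self._os_size)
                + 1j * np.bincount(idx, weights=contrib.imag.ravel(),
                                   minlength=self._os_size))
        spec = spec.reshape(self.os_shape)
        xpad = np.fft.fftshift(np.fft.ifftn(np.fft.ifftshift(spec))) * self._os_size
        return xpad[self._pad_slices()] * self._deapod

    def toeplitz_normal(self, image: np.ndarray) -> np.ndarray:
        """adjoint(forward(image)) — the normal operator."""
        return self.adjoint(self.forward(image))


def direct_nudft(image: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Brute-force non-uniform discrete Fourier sum (oracle; O(M*N))."""
    grid_shape = image.shape
    pos = np.meshgrid(*[np.arange(n) - n // 2 for n in grid_shape], indexing="ij")
    pos = np.stack([p.ravel() for p in pos], axis=1)        # (N, d)
    phase = np.exp(-2j * np.pi * (coords @ pos.T))          # (M, N)
    return phase @ image.ravel()


def direct_nudft_adjoint(samples: np.ndarray, coords: np.ndarray,
                         grid_shape) -> np.ndarray:
    """Brute-force adjoint of :func:`direct_nudft`."""
    pos = np.meshgrid(*[np.arange(n) - n // 2 for n in grid_shape], indexing="ij")
    pos = np.stack([p.ravel() for p in pos], axis=1)
    phase = np.exp(2j * np.pi * (pos @ coords.T))           # (N, M)
    return (phase @ samples).reshape(grid_shape)
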