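"""Radial trajectory generation and view ordering.

The acquisition collects one radial spoke per RF excitation; the view
ordering decides which spoke direction is played at view ``v`` of
inversion block ``b``.  Two orderings are provided:

* golden-angle — each successive excitation advances the spoke angle by
  111.24611 deg (2D) or follows a spiral-phyllotaxis increment (3D);
* pseudorandom interleaved — a bit-reversed interleave over blocks on a
  uniform base spoke set, constructed so that both cumulative-uniformity
  conditions hold: (a) the union of all views of the first m blocks is
  approximately uniform in angle, and (b) for a fixed view (inversion
  time), the spokes of the first m blocks are approximately uniform.
  Retrospective undersampling by keeping the first m blocks therefore
  stays well distributed both per contrast and overall.

Coordinates are Nyquist-normalized cycles per pixel in [-0.5, 0.5);
every spoke passes through k = 0.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "RadialTrajectory",
    "ViewOrder",
    "TIBinning",
    "GOLDEN_ANGLE_DEG",
    "golden_angle_order",
    "pseudorandom_interleaved_order",
    "bin_by_ti",
    "angular_gap_statistic",
    "density_compensation",
    "subsample_blocks",
]

GOLDEN_ANGLE_DEG = 111.24611
# 2D golden means of the spiral-phyllotaxis 3D ordering
_PHI1 = 0.4656
_PHI2 = 0.6823


@dataclass
class ViewOrder:
    """Map from (block, view) to an index into the full spoke set."""

    assignment: np.ndarray  # (n_blocks, n_views) int
    scheme: str = "golden"

    @property
    def n_blocks(self) -> int:
        return self.assignment.shape[0]

    @property
    def n_views(self) -> int:
        return self.assignment.shape[1]


@dataclass
class RadialTrajectory:
    """Sampled k-space coordinates of every (block, view) spoke."""

    coords: np.ndarray       # (n_blocks, n_views, n_samples, d)
    spoke_dirs: np.ndarray   # (n_blocks, n_views, d) unit directions

    @property
    def ndim_k(self) -> int:
        return self.coords.shape[-1]

    @property
    def n_samples_per_spoke(self) -> int:
        return self.coords.shape[2]


def _spoke_samples(dirs: np.ndarray, n_samples: int) -> np.ndarray:
    """Sample each unit direction along a full diameter through k=0."""
    radii = -0.5 + np.arange(n_samples) / n_samples  # includes 0 for even n
    return dirs[..., None, :] * radii[:, None]


def _dirs_2d(angles_rad: np.ndarray) -> np.ndarray:
    return np.stack([np.cos(angles_rad), np.sin(angles_rad)], axis=-1)


def golden_angle_order(n_blocks: int, n_views: int, dim: int = 2,
                       n_samples: int | None = None,
                       grid_size: int = 64) -> tuple[RadialTrajectory, ViewOrder]:
    """Golden-angle view ordering over the sequential excitation index."""
    if dim not in (2, 3):
        raise ValueError("dim must be 2 or 3")
    if n_samples is None:
        n_samples = 2 * grid_size
    total = n_blocks * n_views
    m = np.arange(total)
    if dim == 2:
        angles = np.deg2rad((m * GOLDEN_ANGLE_DEG) % 180.0)
        dirs = _dirs_2d(angles)
    else:
        # spiral phyllotaxis on the half sphere via two golden means
        z = ((m + 0.5) * _PHI1) % 1.0            # uniform in [0,1)
        phi = 2 * np.pi * ((m * _PHI2) % 1.0)
        st = np.sqrt(1.0 - z ** 2)
        dirs = np.stack([st * np.cos(phi), st * np.sin(phi), z], axis=-1)
    dirs = dirs.reshape(n_blocks, n_views, dim)
    coords = _spoke_samples(dirs, n_samples)
    order = ViewOrder(assignment=m.reshape(n_blocks, n_views), scheme="golden")
    return RadialTrajectory(coords=coords, spoke_dirs=dirs), order


def _bit_reverse_permutation(n: int) -> np.ndarray:
    bits = n.bit_length() - 1
    idx = np.arange(n)
    rev = np.zeros(n, dtype=int)
    for b in range(bits):
        rev |= ((idx >> b) & 1) << (bits - 1 - b)
    return rev


def _block_permutation(n_blocks: int) -> np.ndarray:
    if n_blocks >= 2 and n_blocks & (n_blocks - 1) == 0:
        return _bit_reverse_permutation(n_blocks)
    if n_blocks > 2:
        warnings.warn(
            f"n_blocks={n_blocks} is not a power of two; falling back to a "
            "coprime-stride block permutation", stacklevel=3)
        target = 0.5 * (math.sqrt(5) - 1) * n_blocks
        stride = max(1, int(round(target)))
        while math.gcd(stride, n_blocks) != 1:
            stride += 1
        return (np.arange(n_blocks) * stride) % n_blocks
    return np.arange(n_blocks)


def pseudorandom_interleaved_order(n_blocks: int, n_views: int, dim: int = 2,
                                   n_samples: int | None = None,
                                   grid_size: int = 64
                                   ) -> tuple[RadialTrajectory, ViewOrder]:
    """Bit-reversed block interleave on a uniform base spoke set.

    The full set of ``n_blocks * n_views`` spoke angles is the uniform
    comb ``i * 180 / N``.  View ``v`` of block ``b`` plays spoke index
    ``(v * n_blocks + sigma(b) * n_views) mod N`` with ``sigma`` the
    bit-reversed block permutation: for fixed v the block sequence walks
    a full-circle comb in bit-reversed (prefix-uniform) order, and when
    ``gcd(n_views, n_blocks) = 1`` the map is a bijection onto the full
    spoke set.
    """
    if dim not in (2, 3):
        raise ValueError("dim must be 2 or 3")
    if n_samples is None:
        n_samples = 2 * grid_size
    if math.gcd(n_views, n_blocks) != 1:
        warnings.warn(
            f"gcd(n_views={n_views}, n_blocks={n_blocks}) != 1; the interleave "
            "is not a bijection onto the full spoke set", stacklevel=2)
    total = n_blocks * n_views
    sigma = _block_permutation(n_blocks)
    b_idx, v_idx = np.meshgrid(np.arange(n_blocks), np.arange(n_views), indexing="ij")
    assignment = (v_idx * n_blocks + sigma[b_idx] * n_views) % total
    if dim == 2:
        angles = np.deg2rad(assignment * 180.0 / total)
        dirs = _dirs_2d(angles)
    else:
        z = ((assignment + 0.5) * _PHI1) % 1.0
        phi = 2 * np.pi * ((assignment * _PHI2) % 1.0)
        st = np.sqrt(1.0 - z ** 2)
        dirs = np.stack([st * np.cos(phi), st * np.sin(phi), z], axis=-1)
    coords = _spoke_samples(dirs, n_samples)
    order = ViewOrder(assignment=assignment, scheme="pseudorandom")
    return RadialTrajectory(coords=coords, spoke_dirs=dirs), order


def angular_gap_statistic(angles_deg: np.ndarray) -> float:
    """Max gap / mean gap of spoke angles folded onto [0, 180).

    Equals 1 for a perfectly uniform comb; larger means more clustered.
    """
    a = np.sort(np.asarray(angles_deg, float) % 180.0)
    if a.size < 2:
        return 1.0
    gaps = np.diff(np.concatenate([a, [a[0] + 180.0]]))
    return float(gaps.max() / gaps.mean())


@dataclass(frozen=True)
class TIBinning:
    """Contiguous, balanced grouping of inversion-time indices."""

    n_contrasts: int
    n_bins: int
    bin_of: np.ndarray  # (n_contrasts,) int

    def members(self, b: int) -> np.ndarray:
        return np.nonzero(self.bin_of == b)[0]

    def central_contrast(self, b: int) -> int:
        m = self.members(b)
        return int(m[len(m) // 2])


def bin_by_ti(n_contrasts: int, n_bins: int) -> TIBinning:
    """Partition TI indices into ``n_bins`` contiguous near-equal bins."""
    if not 1 <= n_bins <= n_contrasts:
        raise ValueError("need 1 <= n_bins <= n_contrasts")
    base, extra = divmod(n_contrasts, n_bins)
    sizes = np.full(n_bins, base, dtype=int)
    sizes[:extra] += 1
    bin_of = np.repeat(np.arange(n_bins), sizes)
    return TIBinning(n_contrasts=n_contrasts, n_bins=n_bins, bin_of=bin_of)


def density_compensation(coords: np.ndarray, grid_shape: tuple[int, ...] | None = None,
                         calibrate: bool = True, nufft_kwargs: dict | None = None
                         ) -> np.ndarray:
    """Ramp density-compensation weights for radial sampling.

    Each sample is weighted by the annular (2D) or shell (3D) volume
    element it represents: ``|k|^(d-1)``.  The k-space center, sampled
    once per spoke, gets the small positive floor corresponding to the
    central disk/sphere of radius half the radial spacing shared among
    the spokes (dr/8 in 2D, dr^2/24 in 3D) — without this the duplicated
    DC samples dominate and broad objects come out too bright.  With
    ``calibrate`` the weights are scaled so the density-compensated
    adjoint of the forward model of a centered point source reproduces a
    unit peak (unit DC gain of the gridding reconstruction).
    """
    coords = np.asarray(coords, float)
    d = coords.shape[-1]
    flat = coords.reshape(-1, d)
    radii = np.linalg.norm(flat, axis=-1)
    # radial sample spacing from the most finely sampled spoke
    pos = radii[radii > 0]
    if pos.size == 0:
        raise ValueError("all samples at k=0: not a radial trajectory")
    dr = pos.min()
    floor = dr / 8.0 if d == 2 else dr ** 2 / 24.0
    w = np.maximum(radii ** (d - 1), floor)
    if calibrate:
        if grid_shape is None:
            raise ValueError("grid_shape required for calibration")
        from .nufft import NufftPlan
        plan = NufftPlan(grid_shape, flat, **(nufft_kwargs or {}))
        delta = np.zeros(grid_shape, dtype=complex)
        center = tuple(n // 2 for n in grid_shape)
        delta[center] = 1.0
        psf = plan.adjoint(w * plan.forward(delta))
        dc_gain = float(np.sum(psf).real)  # in-band transfer at k=0
        if dc_gain <= 0:
            raise ValueError("density calibration failed (non-positive DC gain)")
        w = w / dc_gain
    return w.reshape(coords.shape[:-1])


def subsample_blocks(obj, m_blocks: int):
    """Retain the first ``m_blocks`` inversion blocks of a trajectory,
    view order, or k-space container (anything with a leading block axis).

    Retrospective acceleration: keeping the first quarter of the blocks
    is a 4x shorter scan.
    """
    if m_blocks <= 0:
        raise ValueError("m_blocks must be positive")
    if isinstance(obj, RadialTrajectory):
        _check_blocks(obj.coords.shape[0], m_blocks)
        return RadialTrajectory(coords=obj.coords[:m_blocks],
                                spoke_dirs=obj.spoke_dirs[:m_blocks])
    if isinstance(obj, ViewOrder):
        _check_blocks(obj.assignment.shape[0], m_blocks)
        return ViewOrder(assignment=obj.assignment[:m_blocks], scheme=obj.scheme)
    # duck-typed: k-space containers implement their own slicing
    if hasattr(obj, "subsample_blocks"):
        return obj.subsample_blocks(m_blocks)
    raise TypeError(f"cannot subsample object of type {type(obj)!r}")


def _check_blocks(n: int, m: int) -> None:
    if m > n:
        raise ValueError(f"m_blocks={m} exceeds available blocks {n}")
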