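"""Multicoil non-uniform Fourier forward model and gridding reconstructions.

The acquisition model per contrast tau is

    y_tau = A_tau(eta_tau) + n_tau,

where ``A_tau`` maps the image at inversion time tau through each coil
sensitivity and the NUFFT restricted to the radial views acquired at
that inversion time (one view per inversion block).  This module houses
the k-space container, the forward/adjoint operators per TI subgroup,
the density-compensated zero-filled (gridding) reconstruction used both
as the network input and as a baseline, the composite-image
normalization convention, and PCA coil compression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .nufft import NufftPlan
from .trajectory import RadialTrajectory, TIBinning, bin_by_ti

__all__ = [
    "KSpaceData",
    "CoilMaps",
    "ImageSeries",
    "forward_model",
    "gather_measurements",
    "gridding_recon",
    "composite_image",
    "normalize_kspace",
    "coil_compress_pca",
    "PlanCache",
]


@dataclass
class CoilMaps:
    """Complex receive sensitivities, root-sum-of-squares 1 on support."""

    maps: np.ndarray     # (n_coils, *grid)
    support: np.ndarray  # (*grid,) bool

    @property
    def n_coils(self) -> int:
        return self.maps.shape[0]

    @property
    def grid_shape(self) -> tuple[int, ...]:
        return self.maps.shape[1:]

    def combine(self, coil_images: np.ndarray) -> np.ndarray:
        """Conjugate-sensitivity (SENSE) combination of per-coil images."""
        return np.sum(np.conj(self.maps) * coil_images, axis=0)


@dataclass
class ImageSeries:
    """Complex image volumes over inversion-time contrasts (Casorati matrix)."""

    volumes: np.ndarray  # (n_contrasts, *grid)

    @property
    def n_contrasts(self) -> int:
        return self.volumes.shape[0]

    @property
    def grid_shape(self) -> tuple[int, ...]:
        return self.volumes.shape[1:]

    def casorati(self) -> np.ndarray:
        """(n_voxels, n_contrasts) space-time matrix."""
        return self.volumes.reshape(self.n_contrasts, -1).T


@dataclass
class KSpaceData:
    """Multicoil radial samples indexed by (block, view, sample, coil)."""

    samples: np.ndarray          # (B, V, S, C) complex
    traj: RadialTrajectory       # coords (B, V, S, d)
    ti_index: np.ndarray         # (V,) contrast index per view
    dcf: np.ndarray | None = None       # (B, V, S) raw ramp weights
    noise_sigma: float | None = None
    meta: dict | None = None

    def __post_init__(self):
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("k-space samples must be finite")
        self.ti_index = np.asarray(self.ti_index, dtype=int)
        if self.ti_index.shape != (self.samples.shape[1],):
            raise ValueError("ti_index must have one entry per view")

    @property
    def n_blocks(self) -> int:
        return self.samples.shape[0]

    @property
    def n_views(self) -> int:
        return self.samples.shape[1]

    @property
    def n_samples_per_spoke(self) -> int:
        return self.samples.shape[2]

    @property
    def n_coils(self) -> int:
        return self.samples.shape[3]

    @property
    def n_contrasts(self) -> int:
        return int(self.ti_index.max()) + 1

    def views_for_contrast(self, tau: int) -> np.ndarray:
        return np.nonzero(self.ti_index == tau)[0]

    def coords_for_contrasts(self, contrasts) -> np.ndarray:
        """Flattened (M, d) coordinates of all views in the given contrasts."""
        views = np.nonzero(np.isin(self.ti_index, contrasts))[0]
        return self.traj.coords[:, views].reshape(-1, self.traj.coords.shape[-1])

    def data_for_contrasts(self, contrasts) -> np.ndarray:
        """Flattened (M, C) measured samples matching coords_for_contrasts."""
        views = np.nonzero(np.isin(self.ti_index, contrasts))[0]
        return self.samples[:, views].reshape(-1, self.n_coils)

    def dcf_for_contrasts(self, contrasts) -> np.ndarray | None:
        if self.dcf is None:
            return None
        views = np.nonzero(np.isin(self.ti_index, contrasts))[0]
        return self.dcf[:, views].reshape(-1)

    def subsample_blocks(self, m_blocks: int) -> "KSpaceData":
        """Retain the first ``m_blocks`` inversion blocks (shorter scan)."""
        if not 1 <= m_blocks <= self.n_blocks:
            raise ValueError("m_blocks out of range")
        return replace(
            self,
            samples=self.samples[:m_blocks],
            traj=RadialTrajectory(coords=self.traj.coords[:m_blocks],
                                  spoke_dirs=self.traj.spoke_dirs[:m_blocks]),
            dcf=None if self.dcf is None else self.dcf[:m_blocks],
        )


class PlanCache:
    """NUFFT plans per (grid, contrast subset), built lazily and reused."""

    def __init__(self, ksp: KSpaceData, grid_shape, **nufft_kwargs):
        self.ksp = ksp
        self.grid_shape = tuple(grid_shape)
        self.nufft_kwargs = nufft_kwargs
        self._plans: dict[tuple, NufftPlan] = {}
        self._dc_scale: dict[tuple, float] = {}

    def plan(self, contrasts) -> NufftPlan:
        key = tuple(int(t) for t in np.atleast_1d(contrasts))
        if key not in self._plans:
            coords = self.ksp.coords_for_contrasts(list(key))
            self._plans[key] = NufftPlan(self.grid_shape, coords, **self.nufft_kwargs)
        return self._plans[key]

    def dc_scale(self, contrasts, weights: np.ndarray) -> float:
        """Scale making the density-compensated adjoint unit-gain at DC."""
        key = tuple(int(t) for t in np.atleast_1d(contrasts))
        if key not in self._dc_scale:
            plan = self.plan(key)
            delta = np.zeros(self.grid_shape, dtype=complex)
            center = tuple(n // 2 for n in self.grid_shape)
            delta[center] = 1.0
            psf = plan.adjoint(weights * plan.forward(delta))
            self._dc_scale[key] = 1.0 / float(np.sum(psf).real)
        return self._dc_scale[key]


def forward_model(series: ImageSeries, maps: CoilMaps, ksp: KSpaceData,
                  contrasts=None, plans: PlanCache | None = None) -> np.ndarray:
    """Apply the multicoil forward model over the given contrasts.

    Returns samples shaped (n_contrasts_requested, M_per_contrast, n_coils)
    matching the layout of :meth:`KSpaceData.data_for_contrasts` per
    contrast.  Each contrast must be sampled by the same number of views.
    """
    if contrasts is None:
        contrasts = np.arange(series.n_contrasts)
    contrasts = np.atleast_1d(contrasts)
    if plans is None:
        plans = PlanCache(ksp, series.grid_shape)
    out = []
    for tau in contrasts:
        plan = plans.plan([tau])
        img = series.volumes[int(tau)]
        out.append(np.stack([plan.forward(img * maps.maps[c])
                             for c in range(maps.n_coils)], axis=-1))
    return np.stack(out, axis=0)


def gather_measurements(ksp: KSpaceData, contrasts) -> np.ndarray:
    """Measured samples in the layout produced by :func:`forward_model`."""
    return np.stack([ksp.data_for_contrasts([int(t)]) for t in np.atleast_1d(contrasts)])


def _ramp_dcf(ksp: KSpaceData) -> np.ndarray:
    from .trajectory import density_compensation
    return density_compensation(ksp.traj.coords, calibrate=False)


def gridding_recon(ksp: KSpaceData, binning: TIBinning | None,
                   maps: CoilMaps | None = None,
                   grid_shape=None, plans: PlanCache | None = None) -> ImageSeries:
    """Density-compensated adjoint (zero-filled) reconstruction per TI bin.

    Each bin's views (across all blocks) are gridded with calibrated ramp
    density weights; coils are combined with conjugate sensitivities when
    maps are given, else root-sum-of-squares.  ``binning=None`` grids all
    data into one composite volume.
    """
    if grid_shape is None:
        if maps is None:
            raise ValueError("grid_shape or maps required")
        grid_shape = maps.grid_shape
    if binning is None:
        binning = bin_by_ti(ksp.n_contrasts, 1)
    if plans is None:
        plans = PlanCache(ksp, grid_shape)
    dcf = ksp.dcf if ksp.dcf is not None else _ramp_dcf(ksp)
    volumes = np.zeros((binning.n_bins,) + tuple(grid_shape), dtype=complex)
    for b in range(binning.n_bins):
        members = binning.members(b)
        members = members[np.isin(members, ksp.ti_index)]
        if members.size == 0:
            warnings.warn(f"TI bin {b} contains no acquired views; zero volume")
            continue
        plan = plans.plan(members)
        views = np.nonzero(np.isin(ksp.ti_index, members))[0]
        w = dcf[:, views].reshape(-1) * plans.dc_scale(members, dcf[:, views].reshape(-1))
        data = ksp.samples[:, views].reshape(-1, ksp.n_coils)
        coil_imgs = np.stack([plan.adjoint(w * data[:, c])
                              for c in range(ksp.n_coils)])
        if maps is not None:
            volumes[b] = maps.combine(coil_imgs)
        else:
            volumes[b] = np.sqrt(np.sum(np.abs(coil_imgs) ** 2, axis=0))
    return ImageSeries(volumes=volumes)


def composite_image(ksp: KSpaceData, maps: CoilMaps | None = None,
                    grid_shape=None) -> np.ndarray:
    """Gridding of ALL views as a single bin (the composite image)."""
    return gridding_recon(ksp, None, maps=maps, grid_shape=grid_shape).volumes[0]


def normalize_kspace(ksp: KSpaceData, maps: CoilMaps | None = None,
                     grid_shape=None) -> tuple[KSpaceData, float]:
    """Scale the data so the composite gridded image has unit peak.

    Returns the scaled container and the applied scale factor.
    """
    comp = composite_image(ksp, maps=maps, grid_shape=grid_shape)
    peak = np.abs(comp).max()
    if peak == 0:
        raise ValueError("all-zero k-space cannot be normalized")
    scale = 1.0 / peak
    return replace(ksp, samples=ksp.samples * scale), scale


def coil_compress_pca(ksp: KSpaceData, n_virtual: int = 4,
                      maps: CoilMaps | None = None
                      ) -> tuple[KSpaceData, CoilMaps | None, float]:
    """Compress physical coils to ``n_virtual`` virtual coils by PCA.

    The sample matrix (samples x coils) is projected onto its top
    principal components; sensitivities, when provided, are projected
    with the same components so the forward model stays consistent.
    Returns (compressed data, compressed maps, retained energy fraction).
    """
    if not 1 <= n_virtual <= ksp.n_coils:
        raise ValueError("n_virtual must be in [1, n_coils]")
    mat = ksp.samples.reshape(-1, ksp.n_coils)
    cov = mat.conj().T @ mat
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    comp = evecs[:, :n_virtual]              # (C, n_virtual)
    energy = float(evals[:n_virtual].sum() / evals.sum())
    new_samples = mat @ comp         # y'_v = sum_c y_c P[c,v]
    new_samples = new_samples.reshape(ksp.samples.shape[:-1] + (n_virtual,))
    new_maps = None
    if maps is not None:
        # virtual map v is sum_c P[c,v] m_c, so A(m'_v x) = sum_c P[c,v] y_c
        m = maps.maps.reshape(maps.n_coils, -1)
        new_maps = CoilMaps(maps=(comp.T @ m).reshape((n_virtual,) + maps.grid_shape),
                            support=maps.support)
    return replace(ksp, samples=new_samples), new_maps, energy
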