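"""Digital phantoms and simulated MPnRAGE acquisitions.

Emulates a NIST-style T1 vial phantom: a circular water bath containing
six small vials whose T1 values are log-spaced over 300-2000 ms, imaged
with smooth synthetic multicoil sensitivities.  The simulator composes
the Bloch steady-state signal model with the multicoil radial forward
operator and complex Gaussian noise, and returns the ground-truth image
series and parameter maps for evaluation, so the entire reconstruction
and fitting pipeline can be exercised without any acquired data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .operators import CoilMaps, ImageSeries, KSpaceData
from .sequence import SequenceParams, TissueParams, simulate_signal_bank
from .trajectory import RadialTrajectory, ViewOrder, density_compensation

__all__ = [
    "DigitalPhantom",
    "ParamMaps",
    "make_vial_phantom",
    "make_brain_phantom",
    "make_coil_maps",
    "ground_truth_series",
    "simulate_acquisition",
    "retained_trajectory",
    "standard_desk_acquisition",
    "roi_stats",
    "roi_mask_union",
]

DEFAULT_VIAL_T1S = np.geomspace(300.0, 2000.0, 6)


@dataclass
class DigitalPhantom:
    """Piecewise-constant phantom: label map plus per-label tissue parameters."""

    label_map: np.ndarray                  # int grid, 0 = background
    tissues: list[TissueParams | None]     # index = label; [0] is None
    voxel_size_mm: float = 4.0
    vial_centers: list[tuple] = field(default_factory=list)   # labels of vials, in order
    vial_labels: list[int] = field(default_factory=list)

    @property
    def grid_shape(self) -> tuple[int, ...]:
        return self.label_map.shape

    @property
    def n_labels(self) -> int:
        return len(self.tissues)

    def support(self) -> np.ndarray:
        return self.label_map > 0

    def truth_maps(self) -> "ParamMaps":
        shape = self.grid_shape
        t1 = np.zeros(shape)
        b1 = np.zeros(shape)
        eff = np.zeros(shape)
        m0 = np.zeros(shape, dtype=complex)
        for lab, tis in enumerate(self.tissues):
            if tis is None:
                continue
            sel = self.label_map == lab
            t1[sel], b1[sel], eff[sel], m0[sel] = tis.t1_ms, tis.b1, tis.eff, tis.m0
        return ParamMaps(t1_ms=t1, b1=b1, eff=eff, m0=m0,
                         fit_residual=np.zeros(shape))


@dataclass
class ParamMaps:
    """Voxelwise T1, B1 scale, inversion efficiency, complex scale."""

    t1_ms: np.ndarray
    b1: np.ndarray
    eff: np.ndarray
    m0: np.ndarray
    fit_residual: np.ndarray


def _disk(shape, center, radius) -> np.ndarray:
    grids = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    r2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return r2 <= radius ** 2


def make_vial_phantom(grid_size: int = 64,
                      vial_t1s=DEFAULT_VIAL_T1S,
                      vial_radius_vox: float | None = None,
                      bath_t1_ms: float = 2800.0,
                      voxel_size_mm: float = 4.0,
                      eff: float = 0.96,
                      dim: int = 2) -> DigitalPhantom:
    """Circular bath with vials on a ring, log-spaced T1 by default.

    Label 0 is background (zero proton density), label 1 the bath, and
    labels 2.. the vials in T1 order.
    """
    vial_t1s = np.atleast_1d(np.asarray(vial_t1s, float))
    if vial_radius_vox is None:
        vial_radius_vox = 5.0 * grid_size / 64  # scale with the grid
    shape = (grid_size,) * dim
    center = tuple(n / 2 - 0.5 for n in shape)
    bath_radius = 0.45 * grid_size
    label = np.zeros(shape, dtype=int)
    label[_disk(shape, center, bath_radius)] = 1
    tissues: list[TissueParams | None] = [
        None, TissueParams(t1_ms=bath_t1_ms, m0=0.7 + 0.0j, eff=eff)]
    centers, vial_labels = [], []
    n_vials = len(vial_t1s)
    ring = 0.28 * grid_size
    for i, t1 in enumerate(vial_t1s):
        ang = 2 * np.pi * i / max(n_vials, 1)
        c = list(center)
        c[0] = center[0] + ring * np.cos(ang)
        c[1] = center[1] + ring * np.sin(ang)
        mask = _disk(shape, c, vial_radius_vox)
        if np.any(label[mask] > 1):
            raise ValueError("vials overlap; reduce radius or count")
        lab = 2 + i
        label[mask] = lab
        tissues.append(TissueParams(t1_ms=float(t1), m0=1.0 + 0.0j, eff=eff))
        centers.append(tuple(c))
        vial_labels.append(lab)
    if n_vials and not (2 * (vial_radius_vox + 1) < grid_size):
        raise ValueError("vials do not fit in the grid")
    return DigitalPhantom(label_map=label, tissues=tissues,
                          voxel_size_mm=voxel_size_mm,
                          vial_centers=centers, vial_labels=vial_labels)


def make_brain_phantom(grid_size: int = 64, voxel_size_mm: float = 4.0,
                       eff: float = 0.96) -> DigitalPhantom:
    """Brain-like elliptical phantom with WM/GM/CSF-style compartments.

    T1 = 800 / 1400 / 4000 ms are conventional 3T white-matter,
    gray-matter and CSF values used for in-vivo-style tests.
    """
    shape = (grid_size, grid_size)
    c = grid_size / 2 - 0.5
    yy, xx = np.meshgrid(*[np.arange(grid_size) - c] * 2, indexing="ij")
    label = np.zeros(shape, dtype=int)
    outer = (yy / (0.45 * grid_size)) ** 2 + (xx / (0.38 * grid_size)) ** 2 <= 1
    inner = (yy / (0.33 * grid_size)) ** 2 + (xx / (0.26 * grid_size)) ** 2 <= 1
    vent = (yy / (0.10 * grid_size)) ** 2 + ((xx) / (0.06 * grid_size)) ** 2 <= 1
    label[outer] = 2    # gray matter rim
    label[inner] = 1    # white matter
    label[vent] = 3     # CSF ventricle
    tissues = [None,
               TissueParams(t1_ms=800.0, m0=0.9 + 0.0j, eff=eff),
               TissueParams(t1_ms=1400.0, m0=1.0 + 0.0j, eff=eff),
               TissueParams(t1_ms=4000.0, m0=1.0 + 0.0j, eff=eff)]
    return DigitalPhantom(label_map=label, tissues=tissues,
                          voxel_size_mm=voxel_size_mm)


def make_coil_maps(grid_shape, n_coils: int = 8, profile_width: float = 0.8,
                   support: np.ndarray | None = None, seed: int = 0) -> CoilMaps:
    """Smooth complex Gaussian-lobe sensitivities, RSS-normalized on support.

    Coil centers sit on a circle just outside the FOV; a slowly varying
    phase mimics real receive fields.  ``profile_width`` is the Gaussian
    sigma as a fraction of the FOV.
    """
    grid_shape = tuple(grid_shape)
    if n_coils < 1:
        raise ValueError("n_coils must be >= 1")
    if support is None:
        support = np.ones(grid_shape, dtype=bool)
    if n_coils == 1:
        maps = np.ones((1,) + grid_shape, dtype=complex)
        maps[0, ~support] = 0
        return CoilMaps(maps=maps, support=support)
    rng = np.random.default_rng(seed)
    n = grid_shape[0]
    grids = np.meshgrid(*[np.arange(m) / n for m in grid_shape], indexing="ij")
    maps = np.empty((n_coils,) + grid_shape, dtype=complex)
    sigma = profile_width
    for c in range(n_coils):
        ang = 2 * np.pi * c / n_coils
        center = [0.5 + 0.65 * np.cos(ang), 0.5 + 0.65 * np.sin(ang)]
        center += [0.5] * (len(grid_shape) - 2)
        r2 = sum((g - cc) ** 2 for g, cc in zip(grids, center))
        mag = np.exp(-r2 / (2 * sigma ** 2))
        phase = (rng.uniform(-np.pi, np.pi)
                 + 2.0 * (grids[0] - 0.5) * rng.uniform(-1, 1)
                 + 2.0 * (grids[1] - 0.5) * rng.uniform(-1, 1))
        maps[c] = mag * np.exp(1j * phase)
    rss = np.sqrt(np.sum(np.abs(maps) ** 2, axis=0))
    rss[rss == 0] = 1.0
    maps = maps / rss
    maps[:, ~support] = 0
    return CoilMaps(maps=maps, support=support)


def ground_truth_series(phantom: DigitalPhantom, seq: SequenceParams) -> ImageSeries:
    """Per-contrast images from per-label Bloch signals (piecewise constant)."""
    labels = [lab for lab, t in enumerate(phantom.tissues) if t is not None]
    t1s = np.array([phantom.tissues[lab].t1_ms for lab in labels])
    b1s = np.array([phantom.tissues[lab].b1 for lab in labels])
    effs = np.array([phantom.tissues[lab].eff for lab in labels])
    m0s = np.array([phantom.tissues[lab].m0 for lab in labels])
    sig = simulate_signal_bank(seq, t1s, b1s, effs) * m0s  # (T, n_labels)
    vols = np.zeros((seq.n_contrasts,) + phantom.grid_shape, dtype=complex)
    for i, lab in enumerate(labels):
        vols[:, phantom.label_map == lab] = sig[:, i][:, None]
    return ImageSeries(volumes=vols)


def simulate_acquisition(phantom: DigitalPhantom, seq: SequenceParams,
                         traj: RadialTrajectory, order: ViewOrder,
                         maps: CoilMaps, noise_sigma: float = 0.0,
                         seed: int = 0
                         ) -> tuple[KSpaceData, ImageSeries, ParamMaps]:
    """Simulate a full multicoil radial MPnRAGE acquisition.

    The trajectory's view axis must match the number of retained
    contrasts (view v of every block samples contrast v).  Returns the
    noisy k-space container plus the noiseless ground-truth image series
    and parameter maps for evaluation only.
    """
    from .operators import PlanCache, forward_model

    n_contrasts = seq.n_contrasts
    if traj.coords.shape[1] != n_contrasts:
        raise ValueError(
            f"trajectory has {traj.coords.shape[1]} views/block; sequence "
            f"retains {n_contrasts} contrasts")
    if maps.grid_shape != phantom.grid_shape:
        raise ValueError("coil maps and phantom grids differ")
    truth = ground_truth_series(phantom, seq)
    ti_index = np.arange(n_contrasts)
    samples = np.zeros(traj.coords.shape[:3] + (maps.n_coils,), dtype=complex)
    ksp = KSpaceData(samples=samples, traj=traj, ti_index=ti_index,
                     noise_sigma=noise_sigma, meta={"seed": seed})
    plans = PlanCache(ksp, phantom.grid_shape)
    B, V, S = traj.coords.shape[:3]
    for tau in range(n_contrasts):
        y = forward_model(truth, maps, ksp, contrasts=[tau], plans=plans)[0]
        samples[:, tau] = y.reshape(B, S, maps.n_coils)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        noise = rng.normal(scale=noise_sigma, size=samples.shape + (2,))
        samples += noise[..., 0] + 1j * noise[..., 1]
    ksp.dcf = density_compensation(traj.coords, calibrate=False)
    return ksp, truth, phantom.truth_maps()


def retained_trajectory(traj: RadialTrajectory, seq: SequenceParams) -> RadialTrajectory:
    """Drop the trajectory views whose readouts are excluded by the sequence.

    View ordering is defined over the full excitation train; when the
    first readout of each block is discarded, its spokes are discarded
    with it, so the trajectory's view axis matches the contrasts.
    """
    keep = seq.retained_views
    return RadialTrajectory(coords=traj.coords[:, keep],
                            spoke_dirs=traj.spoke_dirs[:, keep])


def standard_desk_acquisition(grid_size: int = 64, n_views: int = 49,
                              n_blocks: int = 128, n_coils: int = 8,
                              n_virtual: int = 4, noise_rel: float = 0.005,
                              ordering: str = "pseudorandom", seed: int = 0,
                              phantom: DigitalPhantom | None = None):
    """The canonical 2D desk-scale vial-phantom experiment.

    Shortened view train (49 views -> 48 contrasts, TR stretched to keep
    the ~1.9 s recovery window), 128 inversion blocks with pseudorandom
    interleaved ordering (fully sampled per contrast at 64x64), 8
    physical coils compressed to 4 virtual coils by PCA, and complex
    Gaussian noise with standard deviation ``noise_rel`` times the peak
    k-space magnitude.  Returns a dict with the sequence, phantom, maps,
    k-space, ground-truth series and parameter maps.
    """
    from .operators import coil_compress_pca
    from .trajectory import golden_angle_order, pseudorandom_interleaved_order

    seq = SequenceParams.desk_scale(n_views_per_block=n_views, n_blocks=n_blocks)
    if phantom is None:
        phantom = make_vial_phantom(grid_size=grid_size)
    order_fn = {"pseudorandom": pseudorandom_interleaved_order,
                "golden": golden_angle_order}[ordering]
    traj_full, order = order_fn(n_blocks, n_views, dim=2, grid_size=grid_size)
    traj = retained_trajectory(traj_full, seq)
    maps = make_coil_maps(phantom.grid_shape, n_coils=n_coils, seed=seed)
    ksp, truth, truth_maps = simulate_acquisition(
        phantom, seq, traj, order, maps, noise_sigma=0.0, seed=seed)
    if noise_rel > 0:
        sigma = noise_rel * float(np.abs(ksp.samples).max())
        rng = np.random.default_rng(seed + 1)
        noise = rng.normal(scale=sigma, size=ksp.samples.shape + (2,))
        ksp.samples = ksp.samples + noise[..., 0] + 1j * noise[..., 1]
        ksp.noise_sigma = sigma
    if n_virtual < n_coils:
        ksp, maps, energy = coil_compress_pca(ksp, n_virtual, maps=maps)
    else:
        energy = 1.0
    return {"seq": seq, "phantom": phantom, "maps": maps, "ksp": ksp,
            "truth": truth, "truth_maps": truth_maps, "order": order,
            "coil_energy": energy}


def roi_stats(t1_map: np.ndarray, phantom: DigitalPhantom,
              mask_radius_mm: float = 6.0) -> dict:
    """Per-vial mean/std T1 and percent error inside centered circular masks.

    The mask is a disk of ``mask_radius_mm`` around each vial center (at
    least the center voxel), mirroring how vials are read out from a
    physical T1 phantom.
    """
    if t1_map.shape != phantom.grid_shape:
        raise ValueError("map and phantom grids differ")
    radius_vox = mask_radius_mm / phantom.voxel_size_mm
    out = {"vial": [], "truth_t1_ms": [], "mean_t1_ms": [], "std_t1_ms": [],
           "percent_error": [], "n_voxels": []}
    for i, (center, lab) in enumerate(zip(phantom.vial_centers, phantom.vial_labels)):
        mask = _disk(phantom.grid_shape, center, max(radius_vox, 0.5))
        if not np.any(mask):
            raise ValueError(f"empty ROI mask for vial {i}")
        vals = t1_map[mask]
        truth = phantom.tissues[lab].t1_ms
        mean = float(np.mean(vals))
        out["vial"].append(i)
        out["truth_t1_ms"].append(truth)
        out["mean_t1_ms"].append(mean)
        out["std_t1_ms"].append(float(np.std(vals)))
        out["percent_error"].append(100.0 * (mean - truth) / truth)
        out["n_voxels"].append(int(mask.sum()))
    return out


def roi_mask_union(phantom: DigitalPhantom, mask_radius_mm: float = 6.0) -> np.ndarray:
    """Union of the per-vial ROI disks (the voxels the T1 analysis uses)."""
    radius_vox = max(mask_radius_mm / phantom.voxel_size_mm, 0.5)
    mask = np.zeros(phantom.grid_shape, dtype=bool)
    for center in phantom.vial_centers:
        mask |= _disk(phantom.grid_shape, center, radius_vox)
    return mask
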