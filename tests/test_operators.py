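"""NUFFT correctness, the multicoil forward model, gridding, normalization,
and coil compression."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from mpnrage.nufft import NufftPlan, direct_nudft
from mpnrage.operators import (CoilMaps, ImageSeries, PlanCache,
                               coil_compress_pca, composite_image,
                               forward_model, gather_measurements,
                               gridding_recon, normalize_kspace)
from mpnrage.trajectory import bin_by_ti, density_compensation
from mpnrage.metrics import psnr


def _random_coords(rng, m, d=2):
    return rng.uniform(-0.5, 0.5, (m, d))


class TestNufft:
    def test_zero_image_zero_samples(self, rng):
        plan = NufftPlan((8, 8), _random_coords(rng, 20))
        assert np.all(plan.forward(np.zeros((8, 8), complex)) == 0)

    def test_center_impulse_constant_magnitude(self, rng):
        plan = NufftPlan((8, 8), _random_coords(rng, 50))
        d = np.zeros((8, 8), complex)
        d[4, 4] = 1.0
        s = plan.forward(d)
        np.testing.assert_allclose(np.abs(s), 1.0, atol=1e-4)

    @pytest.mark.parametrize("shape", [(8, 8), (16, 16), (6, 6, 6)])
    def test_matches_direct_dft(self, shape, rng):
        coords = _random_coords(rng, 40, d=len(shape))
        img = rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
        plan = NufftPlan(shape, coords)
        s = plan.forward(img)
        s0 = direct_nudft(img, coords)
        assert np.max(np.abs(s - s0)) / np.max(np.abs(s0)) < 1e-5

    @pytest.mark.parametrize("shape,m", [((8, 8), 30), ((16, 16), 100),
                                         ((6, 6, 6), 40)])
    def test_adjoint_pair(self, shape, m, rng):
        """<A x, y> == <x, A^H y> to 1e-6 relative on random inputs."""
        coords = _random_coords(rng, m, d=len(shape))
        plan = NufftPlan(shape, coords)
        x = rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
        y = rng.standard_normal(m) + 1j * rng.standard_normal(m)
        lhs = np.vdot(y, plan.forward(x))
        rhs = np.vdot(plan.adjoint(y), x)
        assert abs(lhs - rhs) / abs(lhs) < 1e-6

    def test_linearity(self, rng):
        coords = _random_coords(rng, 25)
        plan = NufftPlan((8, 8), coords)
        x = rng.standard_normal((8, 8)) + 1j * rng.standard_normal((8, 8))
        y = rng.standard_normal((8, 8)) + 1j * rng.standard_normal((8, 8))
        a, b = 2.0 - 1.0j, -0.3 + 0.7j
        lhs = plan.forward(a * x + b * y)
        rhs = a * plan.forward(x) + b * plan.forward(y)
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    def test_normal_operator_energy_bounded(self, rng):
        """Power-iteration operator-norm estimate bounds ||A^H A x||."""
        coords = _random_coords(rng, 60)
        plan = NufftPlan((8, 8), coords)
        z = rng.standard_normal((8, 8)) + 1j * rng.standard_normal((8, 8))
        z /= np.linalg.norm(z)
        lmax = 0.0
        for _ in range(30):
            w = plan.toeplitz_normal(z)
            lmax = np.linalg.norm(w)
            z = w / lmax
        x = rng.standard_normal((8, 8)) + 1j * rng.standard_normal((8, 8))
        assert np.linalg.norm(plan.toeplitz_normal(x)) <= 1.01 * lmax * np.linalg.norm(x)

    def test_rejects_out_of_band_coords(self):
        with pytest.raises(ValueError):
            NufftPlan((8, 8), np.array([[0.7, 0.0]]))


class TestForwardModel:
    def test_single_uniform_coil_reduces_to_nufft(self, tiny_acq):
        ksp, truth = tiny_acq["ksp"], tiny_acq["truth"]
        grid = truth.grid_shape
        maps1 = CoilMaps(maps=np.ones((1,) + grid, complex),
                         support=np.ones(grid, bool))
        y = forward_model(truth, maps1, ksp, contrasts=[2])[0][:, 0]
        plan = NufftPlan(grid, ksp.coords_for_contrasts([2]))
        np.testing.assert_allclose(y, plan.forward(truth.volumes[2]), atol=1e-12)

    def test_identical_contrasts_partition_views(self, tiny_acq):
        """Two contrasts holding the same image with disjoint view sets give
        the same samples as one contrast over the union of views."""
        ksp, maps = tiny_acq["ksp"], tiny_acq["maps"]
        grid = maps.grid_shape
        img = tiny_acq["truth"].volumes[3]
        series = ImageSeries(volumes=np.stack([img, img]))
        pair = forward_model(series, maps, ksp, contrasts=[0, 1])
        plan = NufftPlan(grid, ksp.coords_for_contrasts([0, 1]))
        union = np.stack([plan.forward(img * maps.maps[c])
                          for c in range(maps.n_coils)], axis=-1)
        B, S, C = ksp.n_blocks, ksp.n_samples_per_spoke, maps.n_coils
        union = union.reshape(B, 2, S, C)  # (block, view-of-union, sample)
        np.testing.assert_allclose(pair[0].reshape(B, S, C), union[:, 0], atol=1e-10)
        np.testing.assert_allclose(pair[1].reshape(B, S, C), union[:, 1], atol=1e-10)

    def test_roundtrip_against_simulated_kspace(self, tiny_acq):
        """Forward of the ground-truth series reproduces the simulated
        noiseless k-space to 1e-5 relative."""
        ksp, maps, truth = tiny_acq["ksp"], tiny_acq["maps"], tiny_acq["truth"]
        taus = [0, 5, 11]
        y = forward_model(truth, maps, ksp, contrasts=taus)
        y0 = gather_measurements(ksp, taus)
        assert np.max(np.abs(y - y0)) / np.max(np.abs(y0)) < 1e-5


class TestGridding:
    def test_zero_kspace_zero_volumes(self, tiny_acq):
        import dataclasses
        ksp = dataclasses.replace(tiny_acq["ksp"],
                                  samples=np.zeros_like(tiny_acq["ksp"].samples))
        out = gridding_recon(ksp, bin_by_ti(12, 4), maps=tiny_acq["maps"])
        assert np.all(out.volumes == 0)

    def test_eight_bins_return_eight_volumes(self, tiny_acq):
        out = gridding_recon(tiny_acq["ksp"], bin_by_ti(12, 8),
                             maps=tiny_acq["maps"])
        assert out.volumes.shape[0] == 8

    def test_fully_sampled_static_object_psnr(self):
        """Gridding a fully sampled single-contrast object reconstructs it
        above 30 dB at 64^2 (band-limited object, Nyquist spokes)."""
        N, nsp, S = 64, 128, 128
        from mpnrage.phantom import make_vial_phantom
        ph = make_vial_phantom(grid_size=N)
        img = np.zeros((N, N), complex)
        for lab, t in enumerate(ph.tissues):
            if t is not None:
                img[ph.label_map == lab] = t.m0
        img = gaussian_filter(img.real, 0.8) + 0j  # partial-volume edges
        ang = np.arange(nsp) * np.pi / nsp
        dirs = np.stack([np.cos(ang), np.sin(ang)], -1)
        radii = -0.5 + np.arange(S) / S
        coords = (dirs[:, None, :] * radii[:, None]).reshape(-1, 2)
        plan = NufftPlan((N, N), coords)
        w = density_compensation(coords, grid_shape=(N, N))
        rec = plan.adjoint(w * plan.forward(img))
        assert psnr(np.abs(rec), np.abs(img)) > 30.0

    def test_empty_bin_warns_and_zero_fills(self, tiny_acq):
        import dataclasses
        ksp = tiny_acq["ksp"]
        # restrict acquired TIs to 0..5, then ask for bins over 12
        keep = ksp.ti_index < 6
        ksp2 = dataclasses.replace(
            ksp, samples=ksp.samples[:, keep],
            traj=dataclasses.replace(ksp.traj, coords=ksp.traj.coords[:, keep],
                                     spoke_dirs=ksp.traj.spoke_dirs[:, keep]),
            ti_index=ksp.ti_index[keep],
            dcf=None if ksp.dcf is None else ksp.dcf[:, keep])
        with pytest.warns(UserWarning, match="no acquired views"):
            out = gridding_recon(ksp2, bin_by_ti(12, 12), maps=tiny_acq["maps"])
        assert np.all(out.volumes[-1] == 0)
        assert np.any(out.volumes[0] != 0)


class TestNormalization:
    def test_unit_composite_peak(self, tiny_acq):
        kn, scale = normalize_kspace(tiny_acq["ksp"], maps=tiny_acq["maps"])
        comp = composite_image(kn, maps=tiny_acq["maps"])
        assert np.abs(comp).max() == pytest.approx(1.0, abs=1e-6)

    def test_idempotent_and_homogeneous(self, tiny_acq):
        import dataclasses
        kn, scale1 = normalize_kspace(tiny_acq["ksp"], maps=tiny_acq["maps"])
        _, scale2 = normalize_kspace(kn, maps=tiny_acq["maps"])
        assert scale2 == pytest.approx(1.0, rel=1e-9)
        k10 = dataclasses.replace(tiny_acq["ksp"],
                                  samples=tiny_acq["ksp"].samples * 10)
        kn10, scale10 = normalize_kspace(k10, maps=tiny_acq["maps"])
        assert scale10 == pytest.approx(scale1 / 10, rel=1e-9)
        np.testing.assert_allclose(kn10.samples, kn.samples, atol=1e-12)

    def test_zero_data_rejected(self, tiny_acq):
        import dataclasses
        k0 = dataclasses.replace(tiny_acq["ksp"],
                                 samples=np.zeros_like(tiny_acq["ksp"].samples))
        with pytest.raises(ValueError):
            normalize_kspace(k0, maps=tiny_acq["maps"])


class TestCoilCompression:
    def test_identity_compression_keeps_all_energy(self, tiny_acq):
        _, _, energy = coil_compress_pca(tiny_acq["ksp"], 2,
                                         maps=tiny_acq["maps"])
        assert energy == pytest.approx(1.0, abs=1e-10)

    def test_rank2_data_compresses_losslessly(self, tiny_acq, rng):
        """Synthetic 6-coil data that is an exact rank-2 mixture keeps all
        its energy in 2 virtual coils."""
        import dataclasses
        base = tiny_acq["ksp"].samples[..., :2]
        mix = rng.standard_normal((2, 6)) + 1j * rng.standard_normal((2, 6))
        six = np.tensordot(base, mix, axes=(3, 0))
        ksp6 = dataclasses.replace(tiny_acq["ksp"], samples=six)
        _, _, energy = coil_compress_pca(ksp6, 2)
        assert energy == pytest.approx(1.0, abs=1e-8)

    def test_compressed_forward_model_stays_consistent(self, tiny_acq):
        """Projecting data and maps with the same components preserves the
        forward-model relation exactly."""
        kc, mc, _ = coil_compress_pca(tiny_acq["ksp"], 2, maps=tiny_acq["maps"])
        y = forward_model(tiny_acq["truth"], mc, kc, contrasts=[4])
        y0 = gather_measurements(kc, [4])
        assert np.max(np.abs(y - y0)) / np.max(np.abs(y0)) < 1e-10

    def test_rejects_bad_counts(self, tiny_acq):
        with pytest.raises(ValueError):
            coil_compress_pca(tiny_acq["ksp"], 0)
        with pytest.raises(ValueError):
            coil_compress_pca(tiny_acq["ksp"], 5)
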