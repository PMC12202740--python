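"""Subspace baselines: DIP factors, CG, wavelet-FISTA, zero-filled."""

import numpy as np
import pytest

from mpnrage.baselines import (method1_dip_subspace, method1_param_count,
                               method2_cg_quadratic, method3_wavelet_l1,
                               method4_zero_filled_subspace, soft_threshold,
                               zero_filled_factors, _dip_init, _dip_forward)
from mpnrage.nufft import direct_nudft
from mpnrage.operators import PlanCache, gridding_recon, normalize_kspace
from mpnrage.sequence import TemporalBasis, build_dictionary, compute_temporal_basis
from mpnrage.trajectory import bin_by_ti
from mpnrage.metrics import psnr


@pytest.fixture(scope="module")
def tiny_norm(tiny_acq):
    kn, _ = normalize_kspace(tiny_acq["ksp"], maps=tiny_acq["maps"])
    return kn


@pytest.fixture(scope="module")
def tiny_basis(tiny_dictionary):
    return compute_temporal_basis(tiny_dictionary, rank=4)


@pytest.fixture(scope="module")
def micro():
    """Overdetermined 8x8 / rank-2 / single-coil instance with data exactly
    in the range of the subspace forward model (unique LS solution)."""
    from mpnrage.nufft import NufftPlan
    from mpnrage.operators import CoilMaps, KSpaceData
    from mpnrage.trajectory import golden_angle_order
    from scipy.ndimage import gaussian_filter

    N, T, B = 8, 6, 16
    rng = np.random.default_rng(7)
    v, _ = np.linalg.qr(rng.standard_normal((T, 2)))
    basis = TemporalBasis(v=v.T, singular_values=np.ones(2))
    u_true = np.stack([gaussian_filter(rng.standard_normal((N, N)), 1.0)
                       + 1j * gaussian_filter(rng.standard_normal((N, N)), 1.0)
                       for _ in range(2)])
    series = np.tensordot(basis.v.T, u_true, axes=(1, 0))
    traj, _ = golden_angle_order(B, T, grid_size=N, n_samples=16)
    maps = CoilMaps(maps=np.ones((1, N, N), complex),
                    support=np.ones((N, N), bool))
    samples = np.zeros(traj.coords.shape[:3] + (1,), complex)
    for t in range(T):
        plan = NufftPlan((N, N), traj.coords[:, t].reshape(-1, 2))
        samples[:, t, :, 0] = plan.forward(series[t]).reshape(B, -1)
    ksp = KSpaceData(samples=samples, traj=traj, ti_index=np.arange(T))
    return {"ksp": ksp, "maps": maps, "basis": basis, "u_true": u_true}


def _dense_subspace_operator(ksp, maps, basis):
    """Explicit matrix for A_V: built from the brute-force DFT oracle."""
    grid = maps.grid_shape
    nvox = int(np.prod(grid))
    K = basis.rank
    blocks = []
    for tau in range(ksp.n_contrasts):
        coords = ksp.coords_for_contrasts([tau])
        pos = np.meshgrid(*[np.arange(n) - n // 2 for n in grid], indexing="ij")
        pos = np.stack([p.ravel() for p in pos], axis=1)
        F = np.exp(-2j * np.pi * (coords @ pos.T))             # (M, nvox)
        rows = []
        for c in range(maps.n_coils):
            Ac = F * maps.maps[c].ravel()[None, :]             # (M, nvox)
            rows.append(np.concatenate(
                [basis.v[k, tau] * Ac for k in range(K)], axis=1))
        blocks.append(np.concatenate(rows, axis=0))
    return np.concatenate(blocks, axis=0)                      # (all samples, K*nvox)


def _gather_b(ksp):
    return np.concatenate([ksp.data_for_contrasts([t]).T.ravel()
                           for t in range(ksp.n_contrasts)])


class TestMethod2:
    def test_matches_dense_normal_equation_oracle(self, micro):
        """CG on the subspace normal equations must match an explicit
        dense solve (DFT-oracle matrix) to 1e-5 relative."""
        ksp, maps, basis = micro["ksp"], micro["maps"], micro["basis"]
        lam = 1e-3
        A = _dense_subspace_operator(ksp, maps, basis)
        b = _gather_b(ksp)
        u_dense = np.linalg.solve(A.conj().T @ A + lam * np.eye(A.shape[1]),
                                  A.conj().T @ b)
        u_dense = u_dense.reshape((basis.rank,) + maps.grid_shape)
        _, factors = method2_cg_quadratic(ksp, maps, basis, lam=lam,
                                          n_iter=150, tol=0.0)
        err = np.linalg.norm(factors.u - u_dense) / np.linalg.norm(u_dense)
        assert err < 1e-5

    def test_huge_lambda_shrinks_solution_to_zero(self, micro):
        _, huge = method2_cg_quadratic(micro["ksp"], micro["maps"],
                                       micro["basis"], lam=1e9, n_iter=10)
        _, small = method2_cg_quadratic(micro["ksp"], micro["maps"],
                                        micro["basis"], lam=1e-3, n_iter=30)
        assert np.linalg.norm(huge.u) < 1e-4 * np.linalg.norm(small.u)

    def test_residual_nonincreasing_over_iterations(self, tiny_norm, tiny_acq,
                                                    tiny_basis):
        from mpnrage.baselines import _data_residual_norm
        ksp = tiny_norm.subsample_blocks(4)
        maps = tiny_acq["maps"]
        plans = PlanCache(ksp, maps.grid_shape)
        prev = np.inf
        for n_iter in (2, 5, 12, 30):
            _, factors = method2_cg_quadratic(ksp, maps, tiny_basis,
                                              lam=1e-6, n_iter=n_iter)
            resid = _data_residual_norm(factors.u, ksp, maps, tiny_basis, plans)
            assert resid <= prev * (1 + 1e-9)
            prev = resid


class TestMethod3:
    def test_soft_threshold_closed_form(self, rng):
        c = rng.standard_normal(100) + 1j * rng.standard_normal(100)
        t = 0.7
        out = soft_threshold(c, t)
        mag = np.abs(c)
        expected = np.where(mag > t, c * (mag - t) / np.where(mag > 0, mag, 1), 0)
        np.testing.assert_allclose(out, expected, atol=1e-12)
        assert np.all(np.abs(out) <= np.maximum(mag - t, 0) + 1e-12)

    def test_lambda_zero_matches_unregularized_cg(self, micro):
        """At lambda = 0 both objectives reduce to the same (unique,
        overdetermined) least-squares problem."""
        ksp, maps, basis = micro["ksp"], micro["maps"], micro["basis"]
        _, f_cg = method2_cg_quadratic(ksp, maps, basis, lam=0.0, n_iter=200,
                                       tol=0.0)
        _, f_w, _ = method3_wavelet_l1(ksp, maps, basis, lam=0.0, n_iter=1200)
        err = np.linalg.norm(f_w.u - f_cg.u) / np.linalg.norm(f_cg.u)
        assert err < 1e-4

    def test_objective_nonincreasing(self, tiny_norm, tiny_acq, tiny_basis):
        ksp = tiny_norm.subsample_blocks(4)
        _, _, info = method3_wavelet_l1(ksp, tiny_acq["maps"], tiny_basis,
                                        lam=2e-4, n_iter=25)
        obj = np.array(info["objective"])
        assert np.all(np.diff(obj) <= 1e-9 * obj[0])

    def test_non_dyadic_grid_reduces_level(self, tiny_basis):
        from mpnrage.baselines import _wavelet_level
        assert _wavelet_level((64, 64)) == 3
        assert _wavelet_level((24, 24)) == 3
        assert _wavelet_level((20, 20)) == 2
        assert _wavelet_level((9, 9)) == 0


class TestMethod1:
    def test_reference_parameter_count(self):
        assert method1_param_count(rank=16, width=32, kernel=3, ndim=3) == 83040

    def test_zero_network_loss_equals_data_energy(self, tiny_norm, tiny_acq,
                                                  tiny_basis):
        """With all-zero CNN parameters the rendered series is zero, so the
        data-consistency loss is exactly ||b||^2 (construction check)."""
        ksp = tiny_norm.subsample_blocks(2)
        p = _dip_init(tiny_basis.rank, 8, 3, 2, seed=0)
        for k in p:
            p[k][...] = 0.0
        out = _dip_forward(np.zeros((2 * tiny_basis.rank, 8, 8)), p)
        assert np.all(out == 0)

    def test_fixed_seed_reproducible(self, tiny_norm, tiny_acq, tiny_basis):
        ksp = tiny_norm.subsample_blocks(2)
        maps = tiny_acq["maps"]
        kw = dict(width=8, n_epochs=(2, 1), subgroups=(3, 6), lrs=(1e-3, 5e-4))
        _, info1 = method1_dip_subspace(ksp, maps, tiny_basis, seed=4, **kw)
        _, info2 = method1_dip_subspace(ksp, maps, tiny_basis, seed=4, **kw)
        assert ([e["loss"] for e in info1["loss_log"]]
                == [e["loss"] for e in info2["loss_log"]])

    def test_training_reduces_loss(self, tiny_norm, tiny_acq, tiny_basis):
        ksp = tiny_norm.subsample_blocks(4)
        _, info = method1_dip_subspace(ksp, tiny_acq["maps"], tiny_basis,
                                       seed=0, width=16, n_epochs=(6, 2),
                                       subgroups=(3, 12), lrs=(5e-3, 2e-3))
        losses = [e["loss"] for e in info["loss_log"]]
        assert losses[-1] < losses[0]
        assert info["n_params"] == method1_param_count(rank=tiny_basis.rank,
                                                       width=16, ndim=2)


class TestMethod4:
    def test_zero_data_gives_zero_factors(self, tiny_acq, tiny_basis):
        import dataclasses
        k0 = dataclasses.replace(tiny_acq["ksp"],
                                 samples=np.zeros_like(tiny_acq["ksp"].samples))
        _, factors = method4_zero_filled_subspace(k0, tiny_acq["maps"],
                                                  tiny_basis)
        assert np.all(factors.u == 0)

    def test_full_rank_basis_reproduces_per_ti_gridding(self, tiny_norm,
                                                        tiny_acq):
        """With K = n_contrasts and an orthonormal complete basis the
        back-projection UV equals the per-TI gridding series exactly."""
        T = tiny_norm.n_contrasts
        maps = tiny_acq["maps"]
        eye_basis = TemporalBasis(v=np.eye(T), singular_values=np.ones(T))
        series, _ = method4_zero_filled_subspace(tiny_norm, maps, eye_basis)
        ref = gridding_recon(tiny_norm, bin_by_ti(T, T), maps=maps)
        np.testing.assert_allclose(series.volumes, ref.volumes, atol=1e-10)

    def test_span_membership_recovery(self, tiny_seq):
        """Noiseless fully sampled data whose signals lie exactly in
        span(V): the back-projected series matches the (smoothed) truth
        within gridding error."""
        from scipy.ndimage import gaussian_filter
        from mpnrage.nufft import NufftPlan
        from mpnrage.operators import KSpaceData, CoilMaps
        from mpnrage.phantom import (make_vial_phantom, ground_truth_series,
                                     retained_trajectory)
        from mpnrage.trajectory import pseudorandom_interleaved_order
        import mpnrage.trajectory as traj_mod

        N = 64
        ph = make_vial_phantom(grid_size=N)
        seq = tiny_seq
        truth = ground_truth_series(ph, seq).volumes
        # partial-volume edges; spatial smoothing preserves span membership
        sm = np.stack([gaussian_filter(v.real, 0.8) + 0j for v in truth])
        labels = [lab for lab, t in enumerate(ph.tissues) if t is not None]
        d = build_dictionary(seq, t1_grid=[ph.tissues[lab].t1_ms for lab in labels],
                             b1_grid=[1.0], eff_grid=[0.96])
        basis = compute_temporal_basis(d, rank=len(labels))
        traj_full, _ = pseudorandom_interleaved_order(
            128, seq.n_views_per_block, grid_size=N)
        traj = retained_trajectory(traj_full, seq)
        maps = CoilMaps(maps=np.ones((1, N, N), complex),
                        support=np.ones((N, N), bool))
        samples = np.zeros(traj.coords.shape[:3] + (1,), complex)
        for t in range(seq.n_contrasts):
            plan = NufftPlan((N, N), traj.coords[:, t].reshape(-1, 2))
            samples[:, t, :, 0] = plan.forward(sm[t]).reshape(128, -1)
        ksp = KSpaceData(samples=samples, traj=traj,
                         ti_index=np.arange(seq.n_contrasts),
                         dcf=traj_mod.density_compensation(traj.coords,
                                                           calibrate=False))
        series, _ = method4_zero_filled_subspace(ksp, maps, basis)
        ps = [psnr(np.abs(series.volumes[t]), np.abs(sm[t]))
              for t in range(seq.n_contrasts)]
        assert np.mean(ps) > 30.0
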