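"""Virtual microscope and PDE solvers: propagators, bleaching, noise."""

import numpy as np
import pytest

import liftfrap as lf
from liftfrap.exceptions import StabilityError, ValidationError
from liftfrap.frap_sim import _axis_tensor, _fd_step


def make_single_mode_field(n=32, length=10.0, q=0.1):
    h = length / n
    x = (np.arange(n) + 0.5) * h
    field = np.cos(2 * np.pi * q * x)[None, None, :] * np.ones((n, n, 1))
    return field, (h, h, h)


class TestSpectralPropagate:
    def test_zero_dt_is_identity(self):
        rng = np.random.default_rng(0)
        f = rng.random((8, 8, 8))
        out = lf.spectral_propagate(f, lf.DiffusionTensor3D(3, 2, 1), 0.0,
                                    (1.0, 1.0, 1.0))
        np.testing.assert_array_equal(out, f)

    def test_single_mode_decays_at_analytic_rate(self):
        # mode q = (0.1, 0, 0) /um under Dxx = 10 um^2/s for 1 s:
        # amplitude factor exp(-4 pi^2 * 0.1^2 * 10) = exp(-4 pi^2 * 0.1)
        field, spacing = make_single_mode_field(q=0.1)
        out = lf.spectral_propagate(field, lf.DiffusionTensor3D(10, 0, 0),
                                    1.0, spacing)
        expected = np.exp(-4 * np.pi**2 * 0.1)
        ratio = out / field
        np.testing.assert_allclose(ratio, expected, rtol=1e-10)

    def test_spatial_mean_conserved_and_output_real(self):
        rng = np.random.default_rng(1)
        f = rng.random((16, 12, 20))
        t = lf.DiffusionTensor3D(5, 3, 1, dxy=0.5, dyz=-0.2)
        out = lf.spectral_propagate(f, t, 0.7, (1.0, 1.5, 0.5))
        assert out.dtype.kind == "f"
        assert out.mean() == pytest.approx(f.mean(), abs=1e-12)

    def test_non_finite_field_rejected(self):
        f = np.full((8, 8, 8), np.nan)
        with pytest.raises(ValidationError):
            lf.spectral_propagate(f, lf.DiffusionTensor3D(1, 1, 1), 0.1,
                                  (1, 1, 1))


class TestFiniteDifference:
    def test_zero_flux_conserves_total_concentration(self):
        rng = np.random.default_rng(2)
        spec = lf.PDEDomainSpec(
            grid=(12, 12, 12), spacing_um=(1.0, 1.0, 1.0),
            tensor=lf.DiffusionTensor3D(3, 2, 1, dxy=0.8, dxz=-0.3, dyz=0.4),
            initial_field=rng.random((12, 12, 12)),
        )
        dt = 0.5 * lf.max_stable_dt(spec)
        out = lf.fd_diffuse(spec, duration_s=1000 * dt, dt_s=dt)
        rel = abs(out.sum() - spec.initial_field.sum()) / spec.initial_field.sum()
        assert rel < 1e-6

    def test_isotropic_bump_matches_free_space_gaussian_variance(self):
        # Var(t) = Var(0) + 2 D t while the bump is far from the walls
        n, h, d = 32, 1.0, 1.0
        x = np.arange(n) - (n - 1) / 2
        g = np.exp(-x**2 / (2 * 2.0**2))
        field0 = g[:, None, None] * g[None, :, None] * g[None, None, :]
        spec = lf.PDEDomainSpec(
            grid=(n, n, n), spacing_um=(h, h, h),
            tensor=lf.DiffusionTensor3D(d, d, d), initial_field=field0,
        )
        duration = 4.0
        out = lf.fd_diffuse(spec, duration_s=duration, dt_s=0.05)

        def axis_var(f, axis):
            w = f.sum(axis=tuple(a for a in range(3) if a != axis))
            mu = np.sum(x * w) / w.sum()
            return np.sum((x - mu) ** 2 * w) / w.sum()

        expected = 2.0**2 + 2 * d * duration
        for axis in range(3):
            assert axis_var(out, axis) == pytest.approx(expected, rel=0.02)

    def test_constant_source_gives_monotone_fill(self):
        mask = np.zeros((10, 10, 10), dtype=bool)
        mask[4:6, 4:6, 4:6] = True
        spec = lf.PDEDomainSpec(
            grid=(10, 10, 10), spacing_um=(1, 1, 1),
            tensor=lf.DiffusionTensor3D(2, 1, 0.5), source_mask=mask,
        )
        dt = 0.5 * lf.max_stable_dt(spec)
        _, snaps = lf.fd_diffuse(spec, duration_s=300 * dt, dt_s=dt,
                                 snapshot_every=50)
        for (_, a), (_, b) in zip(snaps[:-1], snaps[1:]):
            assert np.all(b >= a - 1e-12)

    def test_unstable_dt_raises_naming_the_bound(self):
        spec = lf.PDEDomainSpec(
            grid=(8, 8, 8), spacing_um=(1, 1, 1),
            tensor=lf.DiffusionTensor3D(10, 10, 10),
            initial_field=np.zeros((8, 8, 8)),
        )
        bound = lf.max_stable_dt(spec)
        with pytest.raises(StabilityError, match="maximum stable dt"):
            lf.fd_diffuse(spec, duration_s=1.0, dt_s=2.0 * bound)

    def test_periodic_mode_decay_matches_analytic_rate(self):
        """Low-frequency DFT modes of a finite-difference run decay at
        4 pi^2 q^T D q within 2% (the spectral/FD cross-validation)."""
        rng = np.random.default_rng(3)
        n, length = 32, 32.0
        h = length / n
        truth = lf.random_spd_tensor(rng, (2.0, 15.0))
        f0 = lf.apply_bleach(
            np.ones((n, n, n)),
            lf.BleachSpec(extent_um=(10, 10, 10), edge_sigma_um=1.5),
            (h, h, h), (length, length, length),
        )
        spec = lf.PDEDomainSpec(
            grid=(n, n, n), spacing_um=(h, h, h), tensor=truth,
            boundary="periodic", initial_field=f0,
        )
        dt = 0.2 * lf.max_stable_dt(spec)
        harmonics = [(1, 0, 0), (0, 1, 0), (0, 0, 1), (1, 1, 0), (1, -1, 0),
                     (1, 0, 1), (0, 1, 1)]
        from conftest import fd_mode_rates

        rates = fd_mode_rates(spec, dt, harmonics, duration=2.0)
        for (hx, hy, hz), k_fit in rates.items():
            q = (hx / length, hy / length, hz / length)
            k_true = lf.theoretical_rate(q, truth)
            assert k_fit == pytest.approx(k_true, rel=0.02)


@pytest.fixture(scope="module")
def source_fields():
    n = 24
    mask = np.zeros((n, n, n), dtype=bool)
    mask[n // 2, n // 2, n // 2] = True
    out = {}
    for name, tensor in [
        ("iso", lf.DiffusionTensor3D(10, 10, 10)),
        ("aniso", lf.DiffusionTensor3D(19.0, 5.5, 5.5)),
    ]:
        spec = lf.PDEDomainSpec(
            grid=(n, n, n), spacing_um=(1, 1, 1), tensor=tensor,
            source_mask=mask,
        )
        dt = 0.5 * lf.max_stable_dt(spec)
        out[name] = lf.fd_diffuse(spec, duration_s=400 * dt, dt_s=dt)
    return out


class TestConcentrationProfiles:
    def test_isotropic_profiles_identical(self, source_fields):
        profs = lf.concentration_profiles(source_fields["iso"], (1, 1, 1),
                                          (12, 12, 12))
        px, py, pz = (profs[a][1][:10] for a in "xyz")
        np.testing.assert_allclose(px, py, rtol=0.01)
        np.testing.assert_allclose(px, pz, rtol=0.01)

    def test_fast_axis_profile_dominates(self, source_fields):
        profs = lf.concentration_profiles(source_fields["aniso"], (1, 1, 1),
                                          (12, 12, 12))
        px, py, pz = (profs[a][1] for a in "xyz")
        # strictly above at equal radius where the field is non-negligible
        assert np.all(px[1:8] > py[1:8])
        assert np.all(px[1:8] > pz[1:8])

    def test_origin_normalized_to_one(self, source_fields):
        profs = lf.concentration_profiles(source_fields["iso"], (1, 1, 1),
                                          (12, 12, 12))
        for axis in "xyz":
            assert profs[axis][1][0] == 1.0

    def test_zero_origin_value_rejected(self):
        with pytest.raises(ValidationError):
            lf.concentration_profiles(np.zeros((8, 8, 8)), (1, 1, 1), (4, 4, 4))


class TestApplyBleach:
    def test_zero_depth_identity(self):
        f = np.ones((16, 16, 16))
        with pytest.raises(ValidationError):
            lf.BleachSpec(depth=0.0)  # depth must be in (0, 1]
        out = lf.apply_bleach(f, lf.BleachSpec(depth=1e-12,
                                               extent_um=(4, 4, 4)),
                              (1, 1, 1))
        np.testing.assert_allclose(out, f, atol=1e-11)

    def test_sharp_full_depth_zeroes_the_box(self):
        n = 16
        f = np.ones((n, n, n))
        spec = lf.BleachSpec(depth=1.0, edge_sigma_um=0.0, extent_um=(6, 6, 6))
        out = lf.apply_bleach(f, spec, (1, 1, 1))
        x = np.arange(n) + 0.5
        inside = (np.abs(x - n / 2) <= 3.0)
        box = inside[:, None, None] & inside[None, :, None] & inside[None, None, :]
        assert np.all(out[box] == 0.0)
        assert np.all(out[~box] == 1.0)

    def test_total_removal_matches_box_volume(self):
        n, h = 48, 1.0
        f = np.ones((n, n, n))
        spec = lf.BleachSpec(depth=0.7, edge_sigma_um=1.5,
                             extent_um=(10, 10, 10))
        out = lf.apply_bleach(f, spec, (h, h, h))
        removed = (f - out).sum() * h**3
        assert removed == pytest.approx(0.7 * 10**3, rel=0.02)


class TestSimulateLiftfrap:
    def test_no_bleach_no_noise_gives_static_volumes(self):
        cfg = lf.SimulationConfig.test_default(
            lf.DiffusionTensor3D(10, 10, 10), noise=lf.NoiseSpec.off(),
            bleach=lf.BleachSpec(depth=1e-9), n_postbleach=6,
        )
        s = lf.simulate_liftfrap(cfg)
        for vol in s.data[1:]:
            np.testing.assert_allclose(vol, s.data[0], atol=1e-7)

    def test_total_fluorescence_conserved_after_bleach(self):
        cfg = lf.SimulationConfig.test_default(
            lf.DiffusionTensor3D(25, 10, 5, dxy=2.0), noise=lf.NoiseSpec.off(),
            n_postbleach=30,
        )
        s = lf.simulate_liftfrap(cfg)
        post = s.data[s.n_prebleach:]
        totals = post.reshape(post.shape[0], -1).sum(axis=1)
        np.testing.assert_allclose(totals, totals[0], rtol=1e-6)

    def test_bit_identical_reproduction_from_seed(self):
        cfg = lf.SimulationConfig.test_default(
            lf.DiffusionTensor3D(10, 5, 2), seed=42,
            n_prebleach=3, n_postbleach=6,
        )
        a = lf.simulate_liftfrap(cfg)
        b = lf.simulate_liftfrap(cfg)
        np.testing.assert_array_equal(a.data, b.data)

    def test_matches_finite_difference_oracle(self):
        """Noiseless volumes agree voxelwise with an independent periodic
        finite-difference integration of the same bleach protocol (<1%)."""
        truth = lf.DiffusionTensor3D(12, 6, 3, dxy=1.5, dyz=-1.0)
        grid, fov = (32, 32, 32), (76.0, 76.0, 76.0)
        bl = lf.BleachSpec(extent_um=(10, 10, 10), edge_sigma_um=3.0)
        cfg = lf.SimulationConfig(
            tensor=truth, grid=grid, fov_um=fov, n_prebleach=1,
            n_postbleach=20, noise=lf.NoiseSpec.off(), bleach=bl,
        )
        s = lf.simulate_liftfrap(cfg)
        h = cfg.voxel_um
        spec = lf.PDEDomainSpec(grid=grid, spacing_um=h, tensor=truth,
                                boundary="periodic",
                                initial_field=np.ones(grid))
        dt = 0.1 * lf.max_stable_dt(spec)
        d = _axis_tensor(truth)

        def fd_prop(f, total):
            steps = max(1, int(np.ceil(total / dt)))
            dte = total / steps
            for _ in range(steps):
                f = _fd_step(f, d, h, dte, periodic=True)
            return f

        conc = np.ones(grid)
        dt_sub = cfg.bleach_duration_s / cfg.n_bleach_substeps
        for _ in range(cfg.n_bleach_substeps):
            conc = lf.apply_bleach(conc, bl, h, fov,
                                   fraction=1.0 / cfg.n_bleach_substeps)
            conc = fd_prop(conc, dt_sub)
        worst = 0.0
        for i in range(cfg.n_postbleach):
            vol = s.data[1 + i]
            worst = max(worst, np.max(np.abs(vol - conc)) / np.max(np.abs(conc)))
            conc = fd_prop(conc, 1.0 / cfg.volume_rate_hz)
        assert worst < 0.01

    def test_noise_variance_follows_camera_model(self):
        """Prebleach per-voxel variance ~ mean/photon_scale + read_sigma^2
        (within 5% over >= 1e5 voxels)."""
        ns = lf.NoiseSpec(photon_scale=2000.0, read_sigma=0.01)
        cfg = lf.SimulationConfig.test_default(
            lf.DiffusionTensor3D(5, 5, 5), seed=3, noise=ns,
            n_prebleach=6, n_postbleach=4,
        )
        s = lf.simulate_liftfrap(cfg)
        pre = s.data[:6].astype(np.float64)
        assert pre[0].size >= 1e5
        var = pre.var(axis=0, ddof=1).mean()
        predicted = 1.0 / ns.photon_scale + ns.read_sigma**2
        assert var == pytest.approx(predicted, rel=0.05)

    def test_seed_required_for_stochastic_run(self):
        with pytest.raises(ValidationError, match="seed"):
            lf.SimulationConfig.test_default(lf.DiffusionTensor3D(1, 1, 1))

    def test_bleach_outside_fov_rejected(self):
        cfg = lf.SimulationConfig.test_default(
            lf.DiffusionTensor3D(1, 1, 1), noise=lf.NoiseSpec.off(),
            bleach=lf.BleachSpec(center_um=(2.0, 38.0, 38.0)),
        )
        with pytest.raises(ValidationError, match="outside"):
            lf.simulate_liftfrap(cfg)
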