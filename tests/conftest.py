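"""Shared fixtures: small simulated datasets reused across test modules."""

import numpy as np
import pytest

import liftfrap as lf


@pytest.fixture(scope="session")
def noiseless_fit_20_10_5():
    """Noiseless virtual experiment with D = diag(20, 10, 5) um^2/s at the
    reduced grid (32x64x64, 8 Hz, 60 postbleach volumes) plus its fit."""
    truth = lf.DiffusionTensor3D(20.0, 10.0, 5.0)
    cfg = lf.SimulationConfig.test_default(truth, noise=lf.NoiseSpec.off())
    series = lf.simulate_liftfrap(cfg)
    fit = lf.analyze(series)
    return truth, series, fit


@pytest.fixture(scope="session")
def anisotropic_noiseless_series():
    """Noiseless series with a full (off-diagonal) tensor, reduced grid."""
    truth = lf.DiffusionTensor3D(12.0, 6.0, 3.0, dxy=1.5, dxz=0.5, dyz=-1.0)
    cfg = lf.SimulationConfig.test_default(truth, noise=lf.NoiseSpec.off())
    return truth, lf.simulate_liftfrap(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)


def fd_mode_rates(spec, dt, harmonics, duration, n_snap=20):
    """Fit log-linear decay rates of selected DFT modes of a
    finite-difference run (shared by solver and acceptance tests)."""
    import scipy.fft

    from liftfrap.frap_sim import _axis_tensor, _fd_step

    field = spec.initial_field.copy()
    d = _axis_tensor(spec.tensor)
    n = spec.grid[0]
    steps_per = max(1, int(round(duration / n_snap / dt)))
    dt_eff = duration / n_snap / steps_per
    periodic = spec.boundary == "periodic"
    times = [0.0]
    coefs = {m: [] for m in harmonics}

    def sample(f):
        spec_f = scipy.fft.fftn(f) / f.size
        for hx, hy, hz in harmonics:
            coefs[(hx, hy, hz)].append(spec_f[hz % n, hy % n, hx % n])

    sample(field)
    for s in range(n_snap):
        for _ in range(steps_per):
            field = _fd_step(field, d, spec.spacing_um, dt_eff, periodic)
        times.append((s + 1) * steps_per * dt_eff)
        sample(field)
    t = np.array(times)
    return {
        m: -np.polyfit(t, np.log(np.abs(np.array(c))), 1)[0]
        for m, c in coefs.items()
    }
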