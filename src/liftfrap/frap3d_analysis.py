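"""3D spatial-Fourier FRAP analysis: from a volume time series to a tensor.

The estimator implements the frequency-domain route to the diffusion
tensor.  After photobleaching, the normalized concentration perturbation
``c(x, t)`` relaxes by free anisotropic diffusion, so each spatial-frequency
mode ``q = (u, v, w)`` (cycles per micrometre) decays independently:

    C~(q, t) / C~(q, 0) = exp(-4 pi^2 q^T D q t)

The pipeline is therefore:

1. ``normalize_series``   — divide each postbleach volume by the averaged
   prebleach volume (homogenizes illumination and staining);
2. ``select_frequencies`` — choose low-|q| axis and diagonal-plane modes
   that are strongly excited by the bleach spectrum;
3. ``extract_mode_series``— 3D DFT of (normalized volume - 1); per-mode
   magnitude time series normalized to the first postbleach volume;
4. ``fit_mode_decay``     — per-mode exponential fit, giving a decay rate
   ``k`` (s^-1) with a standard error;
5. ``assemble_tensor``    — weighted linear least squares on
   ``k(q) = 4 pi^2 (Dxx u^2 + Dyy v^2 + Dzz w^2 + 2 Dxy uv + 2 Dxz uw
   + 2 Dyz vw)`` over all usable modes;
6. ``analyze``            — the full pipeline, adding the eigen-system,
   fractional anisotropy and diagnostics.

Axis conventions: arrays are ``(t, z, y, x)``; frequency vectors are
``(u, v, w) = (qx, qy, qz)``, i.e. ``u`` varies along the last array axis.
Time origin: t = 0 at the first postbleach volume, which makes the
estimator insensitive to diffusion occurring during the bleach itself.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.fft
import scipy.ndimage
from scipy.optimize import curve_fit

from .exceptions import AnalysisError, ValidationError
from .tensor_core import (
    DiffusionTensor3D,
    EigenSystem,
    eigendecompose,
    fractional_anisotropy,
    mean_diffusivity,
    warn_if_not_spd,
)

__all__ = [
    "VolumeSeries",
    "FrequencyMode",
    "FitResult",
    "AnalysisConfig",
    "normalize_series",
    "select_frequencies",
    "extract_mode_series",
    "fit_mode_decay",
    "assemble_tensor",
    "analyze",
    "theoretical_rate",
]

log = logging.getLogger(__name__)

FOUR_PI_SQ = 4.0 * math.pi**2


def theoretical_rate(q, tensor: DiffusionTensor3D) -> float:
    """Analytic decay rate 4 pi^2 q^T D q (s^-1) of mode q (cycles/um)."""
    u, v, w = (float(x) for x in q)
    return FOUR_PI_SQ * (
        tensor.dxx * u * u + tensor.dyy * v * v + tensor.dzz * w * w
        + 2.0 * tensor.dxy * u * v
        + 2.0 * tensor.dxz * u * w
        + 2.0 * tensor.dyz * v * w
    )


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------

@dataclass
class VolumeSeries:
    """Time series of 3D fluorescence volumes with physical calibration.

    Parameters
    ----------
    data : ndarray, shape (t, z, y, x)
        Intensity volumes; prebleach volumes first.
    voxel_um : (dz, dy, dx)
        Voxel size in micrometres, ordered like the array axes.
    frame_interval_s : float
        Time between consecutive volumes (uniform grid assumed).
    n_prebleach : int
        Number of leading prebleach volumes.
    bleach_duration_s : float
        Duration of the bleaching pulse between pre- and postbleach blocks.
    metadata : dict
        Free-form; the simulator stores the ground-truth tensor here.
    """

    data: np.ndarray
    voxel_um: tuple[float, float, float]
    frame_interval_s: float
    n_prebleach: int
    bleach_duration_s: float = 0.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValidationError("VolumeSeries.data must be 4D (t, z, y, x)")
        if len(self.voxel_um) != 3 or any(v <= 0 for v in self.voxel_um):
            raise ValidationError("voxel_um must be three positive sizes")
        if self.frame_interval_s <= 0:
            raise ValidationError("frame_interval_s must be > 0")
        if not 0 <= self.n_prebleach <= self.data.shape[0]:
            raise ValidationError("n_prebleach out of range")
        if self.bleach_duration_s < 0:
            raise ValidationError("bleach_duration_s must be >= 0")

    @property
    def n_postbleach(self) -> int:
        return self.data.shape[0] - self.n_prebleach

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        return self.data.shape[1:]

    @property
    def extent_um(self) -> tuple[float, float, float]:
        """Physical field of view (Lz, Ly, Lx) in micrometres."""
        nz, ny, nx = self.shape_zyx
        dz, dy, dx = self.voxel_um
        return (nz * dz, ny * dy, nx * dx)


@dataclass
class FrequencyMode:
    """One spatial-frequency mode q = (u, v, w) and its decay fit.

    ``coeffs`` holds |C~(q, t)| / |C~(q, 0)| over the postbleach volumes
    (equal to 1 at t=0 by construction); ``raw_mag`` the unnormalized DFT
    magnitudes used for noise-floor truncation.
    """

    q: tuple[float, float, float]
    coeffs: np.ndarray
    raw_mag: np.ndarray
    k: float = np.nan
    k_se: float = np.nan
    r2: float = np.nan
    n_used: int = 0
    used: bool = False
    note: str = ""


@dataclass
class FitResult:
    """Output of the full 3D analysis pipeline."""

    tensor: DiffusionTensor3D
    eigensystem: EigenSystem
    fa: float
    mean_diffusivity: float
    modes: list[FrequencyMode]
    covariance: np.ndarray
    config: "AnalysisConfig"
    diagnostics: dict = field(default_factory=dict)

    def mode_table(self) -> pd.DataFrame:
        rows = []
        for m in self.modes:
            u, v, w = m.q
            rows.append(
                dict(u=u, v=v, w=w, k=m.k, k_se=m.k_se, r2=m.r2,
                     n_used=m.n_used, used=m.used, note=m.note)
            )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable knobs of the 3D estimator.

    n_harm : highest harmonic index per axis (modes n/L, n=1..n_harm).
    q_max_cycles_um : |q| cutoff; default 0.6 / bleach extent keeps modes
        inside the high-power part of the bleach box spectrum.
    bleach_extent_um : nominal bleach box size used for the default cutoff.
    noise_floor_factor : floor = factor x RMS high-|q| magnitude at t=0.
    min_points : minimum usable time points for a mode fit.
    prebleach_floor_frac : prebleach voxels below this fraction of the
        median are masked and in-filled before division.
    fit_offset : include an additive constant in the per-mode decay model.
    """

    n_harm: int = 4
    q_max_cycles_um: float | None = None
    bleach_extent_um: float = 10.0
    noise_floor_factor: float = 5.0
    min_points: int = 4
    prebleach_floor_frac: float = 0.01
    fit_offset: bool = False

    def q_max(self) -> float:
        if self.q_max_cycles_um is not None:
            return self.q_max_cycles_um
        return 0.6 / self.bleach_extent_um


# --------------------------------------------------------------------------
# pipeline stages
# --------------------------------------------------------------------------

def normalize_series(series: VolumeSeries) -> VolumeSeries:
    """Divide each postbleach volume by the time-averaged prebleach volume.

    Division removes multiplicative inhomogeneity (illumination pattern,
    staining variation), leaving a field ~1 away from the bleach.  Voxels
    whose prebleach intensity falls below ``prebleach_floor_frac`` of the
    median (default 1%) are masked and in-filled with a local median before
    dividing, so isolated dark voxels cannot blow up the quotient.
    """
    if series.n_prebleach < 1:
        raise ValidationError("normalize_series requires >= 1 prebleach volume")
    if series.n_postbleach < 4:
        raise ValidationError("normalize_series requires >= 4 postbleach volumes")
    pre = series.data[: series.n_prebleach].mean(axis=0)
    med = float(np.median(pre))
    if med <= 0:
        raise ValidationError("prebleach volumes are all dark (median <= 0)")
    floor = AnalysisConfig().prebleach_floor_frac * med
    low = pre < floor
    if low.mean() > 0.01:
        raise ValidationError(
            f"{low.mean():.1%} of prebleach voxels below the intensity floor; "
            "cannot normalize"
        )
    if low.any():
        filled = scipy.ndimage.median_filter(pre, size=3)
        pre = np.where(low, np.maximum(filled, floor), pre)
    post = series.data[series.n_prebleach:] / pre[None]
    return VolumeSeries(
        data=post,
        voxel_um=series.voxel_um,
        frame_interval_s=series.frame_interval_s,
        n_prebleach=0,
        bleach_duration_s=series.bleach_duration_s,
        metadata={**series.metadata, "normalized": True},
    )


def select_frequencies(
    shape_zyx: tuple[int, int, int],
    voxel_um: tuple[float, float, float],
    config: AnalysisConfig = AnalysisConfig(),
) -> list[tuple[float, float, float]]:
    """Choose the DFT modes used for tensor estimation.

    Returns axis modes ``(n/Lx, 0, 0)``, ``(0, n/Ly, 0)``, ``(0, 0, n/Lz)``
    and signed diagonal-plane modes ``(n/Lx, +-m/Ly, 0)`` (and the two
    other planes) for harmonic indices n, m in [1, n_harm], excluding q = 0
    and modes with ``|q| > q_max``.  Both signs of the diagonal modes are
    kept: their rates differ through the off-diagonal tensor components,
    which improves the conditioning of the assembly step.
    """
    nz, ny, nx = shape_zyx
    dz, dy, dx = voxel_um
    lx, ly, lz = nx * dx, ny * dy, nz * dz
    qmax = config.q_max()
    nh = config.n_harm
    if nh < 1:
        raise ValidationError("n_harm must be >= 1")

    modes: list[tuple[float, float, float]] = []

    def keep(q):
        if math.sqrt(q[0] ** 2 + q[1] ** 2 + q[2] ** 2) <= qmax:
            modes.append(q)

    for n in range(1, nh + 1):
        keep((n / lx, 0.0, 0.0))
        keep((0.0, n / ly, 0.0))
        keep((0.0, 0.0, n / lz))
    for n in range(1, nh + 1):
        for m in range(1, nh + 1):
            for s in (+1, -1):
                keep((n / lx, s * m / ly, 0.0))
                keep((n / lx, 0.0, s * m / lz))
                keep((0.0, n / ly, s * m / lz))

    if _design_rank(modes) < 6:
        raise AnalysisError(
            "fewer than 6 independent quadratic directions after frequency "
            f"filtering (q_max={qmax:.4g} /um); enlarge q_max or n_harm"
        )
    return modes


def _design_row(q) -> list[float]:
    u, v, w = q
    return [u * u, v * v, w * w, 2 * u * v, 2 * u * w, 2 * v * w]


def _design_rank(modes) -> int:
    if not modes:
        return 0
    a = np.array([_design_row(q) for q in modes])
    return int(np.linalg.matrix_rank(a))


def _mode_index(q, shape_zyx, voxel_um) -> tuple[int, int, int]:
    """DFT bin (iz, iy, ix) of mode q; q must sit on the DFT grid."""
    nz, ny, nx = shape_zyx
    dz, dy, dx = voxel_um
    idx = []
    for qc, n, d in ((q[2], nz, dz), (q[1], ny, dy), (q[0], nx, dx)):
        k = qc * n * d  # harmonic index, may be negative
        ki = int(round(k))
        if abs(k - ki) > 1e-6:
            raise ValidationError(
                f"frequency {qc:.6g} /um does not sit on the DFT grid"
            )
        idx.append(ki % n)
    return tuple(idx)


def extract_mode_series(
    normalized: VolumeSeries,
    qs: list[tuple[float, float, float]],
    config: AnalysisConfig = AnalysisConfig(),
) -> list[FrequencyMode]:
    """DFT the normalized perturbation and collect per-mode time series.

    Each postbleach volume contributes one 3D DFT of the perturbation
    ``(volume - 1)`` (coefficients divided by the voxel count so
    amplitudes are intensity fractions); the constant offset only touches
    the q = 0 bin, which is excluded by contract, so the transform is
    taken on the volume directly.  Mode magnitudes are normalized to the
    first postbleach volume, so every series starts at 1.  Modes whose
    initial magnitude is below the noise floor (estimated from
    coefficients with ``|q| > 2 q_max`` in the first volume) are flagged
    unusable.
    """
    data = normalized.data
    if normalized.n_prebleach != 0:
        data = data[normalized.n_prebleach:]
    nt = data.shape[0]
    shape = data.shape[1:]
    nvox = int(np.prod(shape))
    voxel = normalized.voxel_um

    # real-input transform: all selected modes live at u >= 0 (a mode with
    # u < 0 maps to its conjugate at -q, with identical magnitude)
    spectra = scipy.fft.rfftn(data, axes=(1, 2, 3), workers=-1) / nvox

    floor = _noise_floor(spectra[0], shape, voxel, config)

    modes: list[FrequencyMode] = []
    for q in qs:
        qq = q if q[0] >= 0 else (-q[0], -q[1], -q[2])
        iz, iy, ix = _mode_index(qq, shape, voxel)
        series = np.abs(spectra[:, iz, iy, ix])
        c0 = series[0]
        usable = c0 > floor
        coeffs = series / c0 if c0 > 0 else np.full(nt, np.nan)
        modes.append(
            FrequencyMode(
                q=tuple(q), coeffs=coeffs, raw_mag=series,
                used=bool(usable),
                note="" if usable else "initial coefficient below noise floor",
            )
        )
    # stash the floor for the fit stage
    for m in modes:
        m.__dict__["noise_floor"] = floor
    return modes


def _noise_floor(spectrum0, shape_zyx, voxel_um, config: AnalysisConfig) -> float:
    """RMS magnitude of high-|q| coefficients at t=0, times a safety factor."""
    nz, ny, nx = shape_zyx
    dz, dy, dx = voxel_um
    qz = np.fft.fftfreq(nz, d=dz)[:, None, None]
    qy = np.fft.fftfreq(ny, d=dy)[None, :, None]
    qx = np.fft.rfftfreq(nx, d=dx)[None, None, :]
    q2 = qx**2 + qy**2 + qz**2
    high = q2 > (2.0 * config.q_max()) ** 2
    if not high.any():
        return 0.0
    rms = float(np.sqrt(np.mean(np.abs(spectrum0[high]) ** 2)))
    return config.noise_floor_factor * rms


def fit_mode_decay(
    mode: FrequencyMode,
    frame_interval_s: float,
    config: AnalysisConfig = AnalysisConfig(),
) -> FrequencyMode:
    """Fit ``C~/C~0 = A exp(-k t)`` to one mode's magnitude series.

    The series is truncated at the first time its unnormalized magnitude
    drops below the per-mode noise floor; at least ``min_points`` points
    must survive.  ``A`` is free near 1 to absorb the small bias that the
    magnitude of a noisy complex coefficient carries.  Non-convergence
    flags the mode unusable instead of raising.
    """
    if not mode.used:
        return mode
    floor = mode.__dict__.get("noise_floor", 0.0)
    mags = mode.raw_mag
    below = np.nonzero(mags < floor)[0]
    stop = int(below[0]) if below.size else len(mags)
    stop = max(stop, 0)
    t = np.arange(stop) * frame_interval_s
    y = mode.coeffs[:stop]
    if stop < config.min_points:
        mode.used = False
        mode.n_used = stop
        mode.note = "fewer than min_points usable time points"
        return mode

    # log-linear seed for the nonlinear fit
    with np.errstate(divide="ignore"):
        ylog = np.log(np.clip(y, 1e-12, None))
    slope = np.polyfit(t, ylog, 1)[0] if stop >= 2 else 0.0
    k0 = max(-slope, 0.0)

    if config.fit_offset:
        def model(tt, a, k, c):
            return a * np.exp(-k * tt) + c
        p0 = [1.0, k0, 0.0]
        bounds = ([0.1, 0.0, -0.5], [2.0, np.inf, 0.5])
    else:
        def model(tt, a, k):
            return a * np.exp(-k * tt)
        p0 = [1.0, k0]
        bounds = ([0.1, 0.0], [2.0, np.inf])

    try:
        popt, pcov = curve_fit(model, t, y, p0=p0, bounds=bounds, maxfev=2000)
    except (RuntimeError, ValueError):
        mode.used = False
        mode.n_used = stop
        mode.note = "decay fit did not converge"
        return mode

    k = float(popt[1])
    k_var = float(pcov[1, 1]) if np.isfinite(pcov[1, 1]) else np.inf
    resid = y - model(t, *popt)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    mode.k = k
    mode.k_se = math.sqrt(k_var) if k_var >= 0 else np.inf
    mode.r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    mode.n_used = stop
    return mode


def assemble_tensor(
    modes: list[FrequencyMode],
) -> tuple[DiffusionTensor3D, np.ndarray]:
    """Weighted linear least squares from mode rates to tensor components.

    Solves ``k(q) = 4 pi^2 (Dxx u^2 + Dyy v^2 + Dzz w^2 + 2 Dxy uv
    + 2 Dxz uw + 2 Dyz vw)`` over all usable modes, weighting each row by
    ``1/k_se^2`` (unweighted fallback when any standard error is
    degenerate).  Returns the tensor and the 6x6 parameter covariance in
    component order (dxx, dyy, dzz, dxy, dxz, dyz).
    """
    good = [m for m in modes if m.used and np.isfinite(m.k)]
    if len(good) < 6:
        raise AnalysisError(
            f"only {len(good)} usable modes; >= 6 independent directions "
            "are required to determine the tensor"
        )
    a = np.array([_design_row(m.q) for m in good]) * FOUR_PI_SQ
    k = np.array([m.k for m in good])
    if np.linalg.matrix_rank(a) < 6:
        missing = _missing_directions(good)
        raise AnalysisError(
            "mode set is rank deficient for tensor assembly; missing "
            f"directions: {missing}"
        )
    se = np.array([m.k_se for m in good])
    if np.all(np.isfinite(se)) and np.all(se > 0):
        w = 1.0 / se**2
    else:
        w = np.ones_like(k)
    sw = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(a * sw[:, None], k * sw, rcond=None)
    ata = (a * w[:, None]).T @ a
    cov = np.linalg.inv(ata)
    # diagonal components can come out microscopically negative in pure
    # round-off situations; treat tiny negatives as zero
    scale = max(float(np.max(np.abs(coef))), 1e-30)
    diag = np.where(np.abs(coef[:3]) < 1e-12 * scale, 0.0, coef[:3])
    diag = np.where((diag < 0) & (diag > -1e-9 * scale), 0.0, diag)
    tensor = DiffusionTensor3D(
        dxx=float(diag[0]), dyy=float(diag[1]), dzz=float(diag[2]),
        dxy=float(coef[3]), dxz=float(coef[4]), dyz=float(coef[5]),
    )
    return tensor, cov


def _missing_directions(modes) -> str:
    labels = ["u^2", "v^2", "w^2", "uv", "uw", "vw"]
    a = np.array([_design_row(m.q) for m in modes])
    absent = [lab for j, lab in enumerate(labels) if np.allclose(a[:, j], 0)]
    return ", ".join(absent) if absent else "(degenerate combination)"


def analyze(
    series: VolumeSeries,
    config: AnalysisConfig = AnalysisConfig(),
) -> FitResult:
    """Run the full 3D FRAP pipeline on a volume series.

    normalize -> select modes -> extract -> fit decays -> assemble tensor
    -> eigendecompose -> FA.  Raises :class:`AnalysisError` with the stage
    name on failure; raises a "diffusion too fast for frame rate"
    diagnostic when even the slowest selected mode decays below the noise
    floor within the first few volumes.
    """
    log.info("normalize: %d prebleach, %d postbleach volumes",
             series.n_prebleach, series.n_postbleach)
    normalized = normalize_series(series)

    qs = select_frequencies(series.shape_zyx, series.voxel_um, config)
    log.info("selected %d modes (q_max=%.4g /um)", len(qs), config.q_max())

    modes = extract_mode_series(normalized, qs, config)
    for m in modes:
        fit_mode_decay(m, series.frame_interval_s, config)

    q_norms = [math.sqrt(sum(c * c for c in m.q)) for m in modes]
    lowest_q = modes[int(np.argmin(q_norms))]
    if not lowest_q.used or lowest_q.n_used < config.min_points:
        raise AnalysisError(
            "diffusion too fast for frame rate: the slowest selected mode "
            f"(|q|={min(q_norms):.4g} /um) decays below the noise floor "
            f"within {lowest_q.n_used} volumes; increase the volume rate or "
            "the field of view"
        )

    tensor, cov = assemble_tensor(modes)
    warn_if_not_spd(tensor, context=" (3D analysis)")
    es = eigendecompose(tensor)
    fa = fractional_anisotropy(*es.eigenvalues, clip_negative=True)
    md = mean_diffusivity(tensor)

    n_used = sum(m.used for m in modes)
    diagnostics = {
        "n_modes_selected": len(modes),
        "n_modes_used": n_used,
        "noise_floor": modes[0].__dict__.get("noise_floor", 0.0) if modes else 0.0,
        "median_r2": float(np.nanmedian([m.r2 for m in modes if m.used]))
        if n_used else np.nan,
        "is_spd": tensor.is_spd,
    }
    log.info("assembled tensor from %d/%d modes; MD=%.3g um^2/s, FA=%.3f",
             n_used, len(modes), md, fa)
    return FitResult(
        tensor=tensor, eigensystem=es, fa=fa, mean_diffusivity=md,
        modes=modes, covariance=cov, config=config, diagnostics=diagnostics,
    )
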