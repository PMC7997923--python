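"""2D spatial-Fourier FRAP analysis of single-plane image series.

Conventional FRAP images one plane, so it can only measure the in-plane
2x2 diffusion tensor.  This module implements that analysis — including
the convention differences from the 3D pipeline that are intentional
(prebleach average is SUBTRACTED from the postbleach frames, not divided;
the bleach region defaults to a centered square with side 1/8 of the
image) — plus the 2D -> 3D anisotropy proxy ``fa_from_2d``, which
evaluates the fractional anisotropy on ``(lambda1, lambda2, lambda2)``,
i.e. assumes the unmeasured out-of-plane diffusivity equals the larger
in-plane principal diffusivity.

A single plane of a thick sample does NOT obey 2D diffusion: fluorescence
also recovers from above and below the plane, so the apparent in-plane
rates are biased.  :func:`extract_plane` pulls a plane out of a 3D
simulation so that this bias can be quantified against known ground
truth; the spectral 2D simulator :func:`simulate_frap_2d` provides
genuinely 2D data for which the estimator is exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.fft

from .exceptions import AnalysisError, ValidationError
from .frap3d_analysis import AnalysisConfig, FrequencyMode, VolumeSeries, fit_mode_decay
from .tensor_core import DiffusionTensor2D, fractional_anisotropy

__all__ = [
    "ImageSeries2D",
    "Fit2DResult",
    "analyze_2d",
    "fa_from_2d",
    "simulate_frap_2d",
    "extract_plane",
]

FOUR_PI_SQ = 4.0 * math.pi**2


@dataclass
class ImageSeries2D:
    """Time series of single-plane images (t, y, x) with calibration."""

    data: np.ndarray
    pixel_um: float
    frame_interval_s: float
    n_prebleach: int
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValidationError("ImageSeries2D.data must be 3D (t, y, x)")
        if self.pixel_um <= 0 or self.frame_interval_s <= 0:
            raise ValidationError("calibration must be positive")
        if not 0 <= self.n_prebleach <= self.data.shape[0]:
            raise ValidationError("n_prebleach out of range")

    @property
    def n_postbleach(self) -> int:
        return self.data.shape[0] - self.n_prebleach

    @property
    def extent_um(self) -> tuple[float, float]:
        ny, nx = self.data.shape[1:]
        return (ny * self.pixel_um, nx * self.pixel_um)


@dataclass
class Fit2DResult:
    tensor: DiffusionTensor2D
    lambda1: float  # smaller principal diffusivity
    lambda2: float  # larger principal diffusivity
    modes: list[FrequencyMode]
    diagnostics: dict = field(default_factory=dict)

    @property
    def fa_proxy(self) -> float:
        return fa_from_2d(max(self.lambda1, 0.0), max(self.lambda2, 0.0))


def _select_frequencies_2d(shape_yx, pixel_um, config: AnalysisConfig):
    ny, nx = shape_yx
    lx, ly = nx * pixel_um, ny * pixel_um
    qmax = config.q_max()
    modes = []

    def keep(u, v):
        if math.hypot(u, v) <= qmax:
            modes.append((u, v))

    for n in range(1, config.n_harm + 1):
        keep(n / lx, 0.0)
        keep(0.0, n / ly)
    for n in range(1, config.n_harm + 1):
        for m in range(1, config.n_harm + 1):
            keep(n / lx, m / ly)
            keep(n / lx, -m / ly)
    a = np.array([[u * u, v * v, 2 * u * v] for u, v in modes])
    if len(modes) < 3 or np.linalg.matrix_rank(a) < 3:
        raise AnalysisError(
            "fewer than 3 independent quadratic directions after 2D "
            "frequency filtering"
        )
    return modes


def analyze_2d(
    series: ImageSeries2D,
    config: AnalysisConfig | None = None,
) -> Fit2DResult:
    """Estimate the in-plane diffusion tensor from a 2D FRAP series.

    The averaged prebleach image is subtracted from each postbleach frame;
    the difference field is Fourier transformed, per-mode magnitude decays
    are fitted as in the 3D pipeline, and the rates are solved for
    ``(Dxx, Dyy, Dxy)`` through ``k(q) = 4 pi^2 (Dxx u^2 + Dyy v^2
    + 2 Dxy uv)``.  Principal diffusivities are returned sorted ascending
    (lambda1 <= lambda2).
    """
    if config is None:
        # default q_max keyed to the conventional bleach square
        # (side = 1/8 of the image)
        side = series.data.shape[2] * series.pixel_um / 8.0
        config = AnalysisConfig(bleach_extent_um=side)
    if series.n_prebleach < 1:
        raise ValidationError("analyze_2d requires >= 1 prebleach image")
    if series.n_postbleach < 4:
        raise ValidationError("analyze_2d requires >= 4 postbleach images")

    pre = series.data[: series.n_prebleach].mean(axis=0)
    diff = series.data[series.n_prebleach:] - pre[None]
    ny, nx = diff.shape[1:]
    spectra = scipy.fft.fftn(diff, axes=(1, 2), workers=-1) / (ny * nx)

    # noise floor from high-|q| coefficients of the first postbleach frame
    qy = np.fft.fftfreq(ny, d=series.pixel_um)[:, None]
    qx = np.fft.fftfreq(nx, d=series.pixel_um)[None, :]
    high = qx**2 + qy**2 > (2.0 * config.q_max()) ** 2
    floor = 0.0
    if high.any():
        floor = config.noise_floor_factor * float(
            np.sqrt(np.mean(np.abs(spectra[0][high]) ** 2))
        )

    qs = _select_frequencies_2d((ny, nx), series.pixel_um, config)
    modes: list[FrequencyMode] = []
    for u, v in qs:
        iy = int(round(v * ny * series.pixel_um)) % ny
        ix = int(round(u * nx * series.pixel_um)) % nx
        mags = np.abs(spectra[:, iy, ix])
        c0 = mags[0]
        usable = c0 > floor
        m = FrequencyMode(
            q=(u, v, 0.0),
            coeffs=mags / c0 if c0 > 0 else np.full(len(mags), np.nan),
            raw_mag=mags,
            used=bool(usable),
            note="" if usable else "initial coefficient below noise floor",
        )
        m.__dict__["noise_floor"] = floor
        modes.append(m)

    for m in modes:
        fit_mode_decay(m, series.frame_interval_s, config)

    good = [m for m in modes if m.used and np.isfinite(m.k)]
    if len(good) < 3:
        raise AnalysisError(
            f"only {len(good)} usable 2D modes; >= 3 independent directions "
            "are required"
        )
    a = np.array(
        [[m.q[0] ** 2, m.q[1] ** 2, 2 * m.q[0] * m.q[1]] for m in good]
    ) * FOUR_PI_SQ
    k = np.array([m.k for m in good])
    se = np.array([m.k_se for m in good])
    if np.all(np.isfinite(se)) and np.all(se > 0):
        w = 1.0 / se**2
    else:
        w = np.ones_like(k)
    sw = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(a * sw[:, None], k * sw, rcond=None)
    scale = max(float(np.max(np.abs(coef))), 1e-30)
    dxx, dyy = (0.0 if (abs(c) < 1e-12 * scale or (-1e-9 * scale < c < 0))
                else float(c) for c in coef[:2])
    tensor = DiffusionTensor2D(dxx=dxx, dyy=dyy, dxy=float(coef[2]))
    l1, l2 = tensor.principal_diffusivities()
    return Fit2DResult(
        tensor=tensor, lambda1=l1, lambda2=l2, modes=modes,
        diagnostics={"n_modes_used": len(good), "noise_floor": floor},
    )


def fa_from_2d(lambda1: float, lambda2: float) -> float:
    """Anisotropy proxy from a 2D measurement.

    The out-of-plane principal diffusivity is assumed identical to
    ``lambda2``, the larger in-plane principal diffusivity, and the 3D
    fractional anisotropy is evaluated on ``(lambda1, lambda2, lambda2)``.
    Requires ``0 <= lambda1 <= lambda2``, not both zero.
    """
    if lambda1 < 0 or lambda2 < 0:
        raise ValidationError("fa_from_2d: diffusivities must be >= 0")
    if lambda1 > lambda2:
        raise ValidationError("fa_from_2d expects lambda1 <= lambda2")
    return fractional_anisotropy(lambda1, lambda2, lambda2)


# --------------------------------------------------------------------------
# 2D synthetic data
# --------------------------------------------------------------------------

def simulate_frap_2d(
    tensor2d: DiffusionTensor2D,
    image_px: int = 128,
    pixel_um: float = 2.0,
    frame_interval_s: float = 0.355,
    n_prebleach: int = 5,
    n_postbleach: int = 200,
    bleach_depth: float = 0.8,
    edge_sigma_um: float = 2.0,
    noise_sigma: float = 0.0,
    seed: int | None = None,
) -> ImageSeries2D:
    """Spectral simulation of a genuinely 2D FRAP experiment.

    A centered square with side 1/8 of the image is bleached instantly,
    then each Fourier mode decays at ``4 pi^2 q^T D2 q``.  Defaults follow
    a confocal 2D FRAP protocol: 128x128 px, 5 prebleach and 200
    postbleach frames.  Optional additive Gaussian noise (``noise_sigma``)
    requires a seed.
    """
    l1, l2 = tensor2d.principal_diffusivities()
    if l1 < -1e-12:
        raise ValidationError("simulate_frap_2d requires a PSD tensor")
    if noise_sigma > 0 and seed is None:
        raise ValidationError("a seed is mandatory for a stochastic run")
    n = image_px
    lside = n * pixel_um
    side = lside / 8.0
    x = (np.arange(n) + 0.5) * pixel_um
    c = lside / 2.0
    if edge_sigma_um > 0:
        from scipy.special import erf

        s = edge_sigma_um * math.sqrt(2.0)
        prof = 0.5 * (erf((x - (c - side / 2)) / s)
                      - erf((x - (c + side / 2)) / s))
    else:
        prof = ((x >= c - side / 2) & (x <= c + side / 2)).astype(float)
    b = prof[:, None] * prof[None, :]
    conc = 1.0 - bleach_depth * b

    qy = np.fft.fftfreq(n, d=pixel_um)[:, None]
    qx = np.fft.fftfreq(n, d=pixel_um)[None, :]
    rate = FOUR_PI_SQ * (tensor2d.dxx * qx**2 + tensor2d.dyy * qy**2
                         + 2.0 * tensor2d.dxy * qx * qy)
    decay = np.exp(-rate * frame_interval_s)

    rng = np.random.default_rng(seed) if noise_sigma > 0 else None
    frames = np.empty((n_prebleach + n_postbleach, n, n))
    for i in range(n_prebleach):
        frames[i] = 1.0
    spec = scipy.fft.fftn(conc)
    for i in range(n_postbleach):
        frames[n_prebleach + i] = scipy.fft.ifftn(spec).real
        spec = spec * decay
    if rng is not None:
        frames += rng.normal(0.0, noise_sigma, size=frames.shape)
    return ImageSeries2D(
        data=frames, pixel_um=pixel_um, frame_interval_s=frame_interval_s,
        n_prebleach=n_prebleach,
        metadata={"ground_truth_tensor_2d": {
            "dxx": tensor2d.dxx, "dyy": tensor2d.dyy, "dxy": tensor2d.dxy}},
    )


def extract_plane(series: VolumeSeries, z_index: int | None = None) -> ImageSeries2D:
    """Pull one z-plane out of a 3D volume series.

    Emulates what an invasive single-plane measurement sees: the plane's
    recovery includes axial refill, so a 2D analysis of it is biased
    relative to the 3D ground truth.  Requires (near-)isotropic in-plane
    voxels since the 2D container carries a single pixel size.
    """
    dz, dy, dx = series.voxel_um
    if abs(dy - dx) > 1e-9 * max(dy, dx):
        raise ValidationError("extract_plane requires square in-plane voxels")
    if z_index is None:
        z_index = series.data.shape[1] // 2
    if not 0 <= z_index < series.data.shape[1]:
        raise ValidationError("z_index outside the volume")
    return ImageSeries2D(
        data=series.data[:, z_index],
        pixel_um=dx,
        frame_interval_s=series.frame_interval_s,
        n_prebleach=series.n_prebleach,
        metadata={**series.metadata, "extracted_z_index": z_index},
    )
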