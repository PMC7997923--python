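"""Auxiliary metrics: Stokes-Einstein predictions, structure-tensor
coherency of fiber images, and gravimetric water content."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage.feature import structure_tensor

from .exceptions import UndefinedInputError, ValidationError

__all__ = [
    "StokesEinsteinInput",
    "stokes_einstein",
    "structure_coherency",
    "water_content",
    "BOLTZMANN_J_PER_K",
]

#: Boltzmann constant, exact 2019 SI value (J/K)
BOLTZMANN_J_PER_K = 1.380649e-23


@dataclass(frozen=True)
class StokesEinsteinInput:
    """Inputs for the Stokes-Einstein diffusivity of a spherical solute."""

    temperature_K: float
    viscosity_Pa_s: float
    hydrodynamic_radius_m: float

    def __post_init__(self) -> None:
        if (self.temperature_K <= 0 or self.viscosity_Pa_s <= 0
                or self.hydrodynamic_radius_m <= 0):
            raise ValidationError("Stokes-Einstein inputs must be > 0")


def stokes_einstein(inp: StokesEinsteinInput) -> float:
    """Free-solution diffusivity D = k_B T / (6 pi eta r), in um^2 s^-1.

    The theoretical reference for solution measurements: diffusivity is set
    by temperature, solvent viscosity and the solute's hydrodynamic radius.
    """
    d_m2_s = BOLTZMANN_J_PER_K * inp.temperature_K / (
        6.0 * math.pi * inp.viscosity_Pa_s * inp.hydrodynamic_radius_m
    )
    return d_m2_s * 1e12  # m^2/s -> um^2/s


def structure_coherency(image: np.ndarray, window_sigma_px: float = 8.0) -> float:
    """Mean structure-tensor coherency of a grayscale fiber image.

    The Gaussian-windowed structure tensor of the image gradients is
    averaged over the whole image (a gradient-energy-weighted mean, the
    region semantics of fiber-orientation plugins) and the coherency of
    that mean tensor is returned:
    ``(lmax - lmin) / (lmax + lmin)``.  The result is in [0, 1]: ~0 for
    randomly oriented texture (local orientations cancel in the mean),
    ~1 for fibers aligned along a single direction.  It is invariant to
    affine intensity rescaling and to 90-degree rotations.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or min(image.shape) < 16:
        raise ValidationError("structure_coherency expects a 2D image >= 16x16")
    if window_sigma_px <= 0:
        raise ValidationError("window_sigma_px must be > 0")
    ptp = float(image.max() - image.min())
    if ptp == 0:
        raise UndefinedInputError(
            "constant image: fiber orientation is undefined"
        )
    img = (image - image.min()) / ptp  # affine-invariant by construction

    arr, arc, acc = structure_tensor(img, sigma=window_sigma_px, order="rc")
    mrr, mrc, mcc = arr.mean(), arc.mean(), acc.mean()
    trace = mrr + mcc
    if trace <= 0:
        raise UndefinedInputError("image has no gradient energy")
    disc = math.sqrt(max((mrr - mcc) ** 2 + 4.0 * mrc**2, 0.0))
    return min(disc / trace, 1.0)


def water_content(w_wet: float, w_dry: float) -> float:
    """Gravimetric water content (w_wet - w_dry) / w_wet x 100, percent."""
    if w_dry <= 0 or w_wet <= 0:
        raise ValidationError("weights must be > 0")
    if w_dry > w_wet:
        raise ValidationError("dry weight exceeds wet weight")
    return (w_wet - w_dry) / w_wet * 100.0
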