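"""Symmetric diffusion tensors and derived anisotropy scalars.

A single FRAP experiment on an anisotropic medium yields one 3x3 symmetric
diffusion tensor **D** (units um^2 s^-1): diagonal components are the
diffusivities along the lab axes, off-diagonal components couple the axes.
This module provides the tensor containers, the eigendecomposition into
principal diffusivities ``lambda1 >= lambda2 >= lambda3`` with principal
directions, rotation into another coordinate frame (e.g. a sample/tissue
frame), and the scalar summaries used throughout the package:

* mean diffusivity  MD = (Dxx + Dyy + Dzz) / 3
* diffusion fractional anisotropy

  FA = sqrt((l1-l2)^2 + (l1-l3)^2 + (l2-l3)^2) / sqrt(2 (l1^2+l2^2+l3^2))

  a dimensionless scalar in [0, 1]: 0 for isotropic diffusion, 1 for pure
  unidirectional diffusion.

Conventions (documented, since the field has no universal ones):

* eigenvalues are sorted in DESCENDING order;
* each eigenvector's sign is fixed so its largest-magnitude entry is
  positive, making the decomposition deterministic;
* tensors whose smallest eigenvalue is slightly negative (a possibility for
  noisy fits) are preserved as-is and flagged ``is_spd=False``; an optional
  ``clip_spd`` clips negative eigenvalues to zero where a nonnegative
  spectrum is required (e.g. FA).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import UndefinedInputError, ValidationError

__all__ = [
    "DiffusionTensor3D",
    "DiffusionTensor2D",
    "EigenSystem",
    "eigendecompose",
    "fractional_anisotropy",
    "rotate_tensor",
    "mean_diffusivity",
    "random_rotation",
    "random_spd_tensor",
]

#: relative tolerance (vs. trace) below which a negative eigenvalue is
#: attributed to round-off rather than a genuinely indefinite tensor
_SPD_RTOL = 1e-9


def _check_finite(name: str, *values: float) -> None:
    if not all(math.isfinite(v) for v in values):
        raise ValidationError(f"{name}: all components must be finite")


@dataclass(frozen=True)
class DiffusionTensor3D:
    """Symmetric 3x3 diffusion tensor, um^2 s^-1.

    Only the six unique components are stored, so symmetry is structural:
    :meth:`as_matrix` always returns a matrix equal to its transpose.
    """

    dxx: float
    dyy: float
    dzz: float
    dxy: float = 0.0
    dxz: float = 0.0
    dyz: float = 0.0

    def __post_init__(self) -> None:
        _check_finite(
            "DiffusionTensor3D", self.dxx, self.dyy, self.dzz,
            self.dxy, self.dxz, self.dyz,
        )
        if self.dxx < 0 or self.dyy < 0 or self.dzz < 0:
            raise ValidationError(
                "DiffusionTensor3D: diagonal components must be >= 0"
            )

    def as_matrix(self) -> np.ndarray:
        return np.array(
            [
                [self.dxx, self.dxy, self.dxz],
                [self.dxy, self.dyy, self.dyz],
                [self.dxz, self.dyz, self.dzz],
            ],
            dtype=float,
        )

    @classmethod
    def from_matrix(cls, m: np.ndarray, atol: float = 1e-8) -> "DiffusionTensor3D":
        m = np.asarray(m, dtype=float)
        if m.shape != (3, 3):
            raise ValidationError("from_matrix expects a 3x3 array")
        if not np.allclose(m, m.T, atol=atol):
            raise ValidationError("from_matrix expects a symmetric matrix")
        s = 0.5 * (m + m.T)  # fold numerical asymmetry
        return cls(
            dxx=s[0, 0], dyy=s[1, 1], dzz=s[2, 2],
            dxy=s[0, 1], dxz=s[0, 2], dyz=s[1, 2],
        )

    @property
    def trace(self) -> float:
        return self.dxx + self.dyy + self.dzz

    @property
    def is_spd(self) -> bool:
        """True iff all eigenvalues >= -tol with tol = 1e-9 * trace."""
        lams = np.linalg.eigvalsh(self.as_matrix())
        return bool(lams.min() >= -_SPD_RTOL * max(self.trace, 0.0))

    def to_dict(self, frame: str = "lab") -> dict:
        """Flat JSON-ready serialization including derived scalars."""
        es = eigendecompose(self)
        lams = es.eigenvalues
        d = {
            "dxx": self.dxx, "dyy": self.dyy, "dzz": self.dzz,
            "dxy": self.dxy, "dxz": self.dxz, "dyz": self.dyz,
            "eigenvalues": list(lams),
            "eigenvectors": es.vectors_matrix().tolist(),
            "mean_diffusivity": mean_diffusivity(self),
            "units": "um^2/s",
            "frame": frame,
        }
        try:
            d["fa"] = fractional_anisotropy(*lams, clip_negative=True)
        except UndefinedInputError:
            d["fa"] = None
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DiffusionTensor3D":
        return cls(
            dxx=d["dxx"], dyy=d["dyy"], dzz=d["dzz"],
            dxy=d["dxy"], dxz=d["dxz"], dyz=d["dyz"],
        )


@dataclass(frozen=True)
class DiffusionTensor2D:
    """Symmetric 2x2 in-plane diffusion tensor, um^2 s^-1."""

    dxx: float
    dyy: float
    dxy: float = 0.0

    def __post_init__(self) -> None:
        _check_finite("DiffusionTensor2D", self.dxx, self.dyy, self.dxy)

    def as_matrix(self) -> np.ndarray:
        return np.array([[self.dxx, self.dxy], [self.dxy, self.dyy]], dtype=float)

    def principal_diffusivities(self) -> tuple[float, float]:
        """In-plane principal diffusivities, ascending (lambda1 <= lambda2)."""
        lams = np.linalg.eigvalsh(self.as_matrix())
        return float(lams[0]), float(lams[1])


@dataclass(frozen=True)
class EigenSystem:
    """Principal diffusivities (descending) and orthonormal directions."""

    lambda1: float
    lambda2: float
    lambda3: float
    e1: np.ndarray = field(repr=False)
    e2: np.ndarray = field(repr=False)
    e3: np.ndarray = field(repr=False)

    @property
    def eigenvalues(self) -> tuple[float, float, float]:
        return (self.lambda1, self.lambda2, self.lambda3)

    def vectors_matrix(self) -> np.ndarray:
        """Eigenvectors as columns, ordered (e1, e2, e3)."""
        return np.column_stack([self.e1, self.e2, self.e3])

    def reconstruct(self) -> np.ndarray:
        v = self.vectors_matrix()
        return v @ np.diag(self.eigenvalues) @ v.T

    @property
    def fa(self) -> float:
        return fractional_anisotropy(self.lambda1, self.lambda2, self.lambda3,
                                     clip_negative=True)


def eigendecompose(tensor: DiffusionTensor3D) -> EigenSystem:
    """Eigendecompose a 3D diffusion tensor.

    Returns eigenvalues sorted descending with orthonormal eigenvectors;
    each eigenvector's sign is fixed (largest-magnitude entry positive).
    """
    m = tensor.as_matrix()
    lams, vecs = np.linalg.eigh(m)  # ascending
    order = np.argsort(lams)[::-1]
    lams = lams[order]
    vecs = vecs[:, order]
    for j in range(3):
        k = int(np.argmax(np.abs(vecs[:, j])))
        if vecs[k, j] < 0:
            vecs[:, j] = -vecs[:, j]
    return EigenSystem(
        lambda1=float(lams[0]), lambda2=float(lams[1]), lambda3=float(lams[2]),
        e1=vecs[:, 0].copy(), e2=vecs[:, 1].copy(), e3=vecs[:, 2].copy(),
    )


def fractional_anisotropy(
    lambda1: float, lambda2: float, lambda3: float, *, clip_negative: bool = False
) -> float:
    """Diffusion fractional anisotropy of three principal diffusivities.

    FA = sqrt((l1-l2)^2 + (l1-l3)^2 + (l2-l3)^2) / sqrt(2 (l1^2+l2^2+l3^2))

    FA is in [0, 1]: 0 for isotropic diffusion (all equal), 1 for purely
    unidirectional diffusion (only one nonzero diffusivity).  Argument order
    does not matter.  Negative diffusivities are refused unless
    ``clip_negative`` is set, in which case they are clipped to zero first
    (noisy fits can produce a slightly negative smallest eigenvalue).
    """
    lams = np.array([lambda1, lambda2, lambda3], dtype=float)
    if not np.all(np.isfinite(lams)):
        raise ValidationError("fractional_anisotropy: non-finite diffusivity")
    if np.any(lams < 0):
        if clip_negative:
            lams = np.clip(lams, 0.0, None)
        else:
            raise ValidationError(
                "fractional_anisotropy: negative diffusivity "
                "(pass clip_negative=True to clip a noisy fit to the SPD cone)"
            )
    sumsq = float(np.sum(lams**2))
    if sumsq == 0.0:
        raise UndefinedInputError(
            "fractional_anisotropy undefined for an all-zero tensor"
        )
    l1, l2, l3 = lams
    num = math.sqrt((l1 - l2) ** 2 + (l1 - l3) ** 2 + (l2 - l3) ** 2)
    fa = num / math.sqrt(2.0 * sumsq)
    return min(max(fa, 0.0), 1.0)


def rotate_tensor(tensor: DiffusionTensor3D, rotation: np.ndarray) -> DiffusionTensor3D:
    """Express the tensor in a rotated coordinate frame: D' = R D R^T.

    ``rotation`` must be a proper rotation (orthonormal, det = +1 within
    1e-8); eigenvalues, FA and mean diffusivity are invariant.
    """
    r = np.asarray(rotation, dtype=float)
    if r.shape != (3, 3) or not np.all(np.isfinite(r)):
        raise ValidationError("rotation must be a finite 3x3 matrix")
    if not np.allclose(r @ r.T, np.eye(3), atol=1e-8):
        raise ValidationError("rotation matrix is not orthonormal")
    if abs(np.linalg.det(r) - 1.0) > 1e-8:
        raise ValidationError("rotation matrix must have det = +1")
    m = r @ tensor.as_matrix() @ r.T
    m = 0.5 * (m + m.T)
    # rotation can move round-off onto the diagonal; fold tiny negatives
    eps = _SPD_RTOL * max(abs(tensor.trace), 1.0)
    for i in range(3):
        if -eps < m[i, i] < 0.0:
            m[i, i] = 0.0
    return DiffusionTensor3D.from_matrix(m)


def mean_diffusivity(tensor: DiffusionTensor3D) -> float:
    """Average of the diagonal components, (Dxx + Dyy + Dzz)/3."""
    return tensor.trace / 3.0


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation (QR of a Gaussian matrix, det fixed)."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q = q * np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def random_spd_tensor(
    rng: np.random.Generator,
    eig_range: tuple[float, float] = (2.0, 51.0),
) -> DiffusionTensor3D:
    """Random symmetric positive-definite tensor with eigenvalues drawn
    uniformly from ``eig_range`` (um^2 s^-1) and a uniform random
    orientation.  Used by benchmarks and property tests."""
    lo, hi = eig_range
    if not (0 <= lo <= hi):
        raise ValidationError("eig_range must satisfy 0 <= lo <= hi")
    lams = rng.uniform(lo, hi, size=3)
    r = random_rotation(rng)
    return DiffusionTensor3D.from_matrix(r @ np.diag(lams) @ r.T)


def warn_if_not_spd(tensor: DiffusionTensor3D, context: str = "") -> None:
    """Emit a warning when a fitted tensor is not positive semidefinite."""
    if not tensor.is_spd:
        warnings.warn(
            f"fitted diffusion tensor is not positive semidefinite{context}; "
            "reported as-is (is_spd=False)",
            RuntimeWarning,
            stacklevel=2,
        )
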