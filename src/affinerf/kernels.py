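"""Affine Gaussian kernels and directional-derivative receptive-field models.

The anisotropic Gaussian is parameterized either by its covariance matrix
``Sigma`` or by the shape triple ``(sigma1, sigma2, phi)``: eigen-scales
along the kernel's principal axes plus the orientation of the first axis.
First- and second-order directional derivatives along the kernel
orientation are provided in closed form (the simple-cell models); arbitrary
orders and arbitrary derivative directions are handled by a Hermite
expansion into Cartesian partial derivatives.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial import hermite_e
from scipy.special import comb

from .errors import (
    ExtentError,
    InvalidCovarianceError,
    InvalidInputError,
    InvalidShapeError,
    OrderError,
)
from .fields import SampledField, centered_grid

__all__ = [
    "SpatialCovariance",
    "RFSpec",
    "SpatioTemporalRFSpec",
    "covariance_from_shape",
    "shape_from_covariance",
    "gaussian_value",
    "simple_cell_value",
    "general_directional_value",
    "sample_kernel",
    "spatiotemporal_value",
    "temporal_gaussian",
]


def _wrap_orientation(phi: float) -> float:
    """Wrap an orientation (period pi) into (-pi/2, pi/2]."""
    wrapped = math.remainder(phi, math.pi)
    if wrapped <= -math.pi / 2.0:
        wrapped += math.pi
    return wrapped


def _wrap_direction(theta: float) -> float:
    """Wrap a direction (period 2 pi) into (-pi, pi]."""
    wrapped = math.remainder(theta, 2.0 * math.pi)
    if wrapped <= -math.pi:
        wrapped += 2.0 * math.pi
    return wrapped


@dataclass(frozen=True)
class SpatialCovariance:
    """Symmetric positive-definite 2x2 spatial covariance matrix."""

    c11: float
    c22: float
    c12: float = 0.0

    def __post_init__(self) -> None:
        vals = (self.c11, self.c22, self.c12)
        if not all(math.isfinite(v) for v in vals):
            raise InvalidCovarianceError(f"non-finite covariance entries: {vals}")
        if not (self.c11 > 0 and self.c22 > 0 and self.det > 0):
            raise InvalidCovarianceError(
                f"covariance [[{self.c11}, {self.c12}], [{self.c12}, {self.c22}]] "
                "is not positive definite"
            )

    @property
    def det(self) -> float:
        return self.c11 * self.c22 - self.c12 * self.c12

    @property
    def matrix(self) -> np.ndarray:
        return np.array([[self.c11, self.c12], [self.c12, self.c22]])

    @classmethod
    def from_matrix(cls, matrix: np.ndarray) -> "SpatialCovariance":
        m = np.asarray(matrix, dtype=float)
        if m.shape != (2, 2):
            raise InvalidCovarianceError(f"expected 2x2 matrix, got {m.shape}")
        if abs(m[0, 1] - m[1, 0]) > 1e-12 * (abs(m[0, 1]) + abs(m[1, 0]) + 1.0):
            raise InvalidCovarianceError("matrix is not symmetric")
        off = 0.5 * (m[0, 1] + m[1, 0])
        return cls(m[0, 0], m[1, 1], off)

    @classmethod
    def isotropic(cls, sigma: float) -> "SpatialCovariance":
        return cls(sigma * sigma, sigma * sigma, 0.0)

    def inverse(self) -> np.ndarray:
        d = self.det
        return np.array([[self.c22, -self.c12], [-self.c12, self.c11]]) / d

    def max_sigma(self) -> float:
        """Standard deviation along the major principal axis."""
        tr, dt = self.c11 + self.c22, self.det
        lam_max = tr / 2.0 + math.sqrt(max(tr * tr / 4.0 - dt, 0.0))
        return math.sqrt(lam_max)


@dataclass(frozen=True)
class RFSpec:
    """Shape and derivative structure of a spatial receptive field.

    ``kernel_phi`` orients the Gaussian eigensystem (period pi);
    ``deriv_theta`` is the direction of differentiation (defaults to
    ``kernel_phi``, the classic simple-cell alignment); ``m1`` counts
    derivative orders along theta and ``m2`` along its orthogonal.
    """

    sigma1: float
    sigma2: float
    kernel_phi: float = 0.0
    deriv_theta: float | None = None
    m1: int = 0
    m2: int = 0

    def __post_init__(self) -> None:
        if not (self.sigma1 > 0 and self.sigma2 > 0):
            raise InvalidShapeError(
                f"scales must be positive, got ({self.sigma1}, {self.sigma2})"
            )
        if self.m1 < 0 or self.m2 < 0 or int(self.m1) != self.m1 or int(self.m2) != self.m2:
            raise OrderError(f"orders must be non-negative integers, got "
                             f"({self.m1}, {self.m2})")
        object.__setattr__(self, "kernel_phi", _wrap_orientation(self.kernel_phi))
        theta = self.kernel_phi if self.deriv_theta is None else _wrap_direction(self.deriv_theta)
        object.__setattr__(self, "deriv_theta", theta)

    @property
    def order(self) -> int:
        return self.m1 + self.m2

    @property
    def size_bar(self) -> float:
        """Overall receptive-field size sqrt(sigma1 sigma2)."""
        return math.sqrt(self.sigma1 * self.sigma2)

    @property
    def eccentricity(self) -> float:
        """Degree of elongation sigma2/sigma1 (1 = rotationally symmetric)."""
        return self.sigma2 / self.sigma1

    @property
    def covariance(self) -> SpatialCovariance:
        return covariance_from_shape(self.sigma1, self.sigma2, self.kernel_phi)


@dataclass(frozen=True)
class SpatioTemporalRFSpec:
    """Space-time separable receptive field with a velocity offset.

    The spatial kernel travels along ``velocity``; ``tau`` is the variance
    of the unit-mass temporal window.
    """

    sigma_matrix: SpatialCovariance
    tau: float
    velocity: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if not (math.isfinite(self.tau) and self.tau > 0):
            raise InvalidInputError(f"temporal variance must be positive, got {self.tau}")
        v = (float(self.velocity[0]), float(self.velocity[1]))
        object.__setattr__(self, "velocity", v)


def covariance_from_shape(sigma1: float, sigma2: float,
                          kernel_phi: float) -> SpatialCovariance:
    """Covariance with eigenvalues sigma1^2, sigma2^2 and first axis at phi.

    c11 = s1^2 cos^2 + s2^2 sin^2, c12 = (s1^2 - s2^2) cos sin,
    c22 = s1^2 sin^2 + s2^2 cos^2.
    """
    if not (sigma1 > 0 and sigma2 > 0):
        raise InvalidShapeError(
            f"scales must be positive, got ({sigma1}, {sigma2})"
        )
    c, s = math.cos(kernel_phi), math.sin(kernel_phi)
    v1, v2 = sigma1 * sigma1, sigma2 * sigma2
    return SpatialCovariance(
        c11=v1 * c * c + v2 * s * s,
        c22=v1 * s * s + v2 * c * c,
        c12=(v1 - v2) * c * s,
    )


def shape_from_covariance(cov: SpatialCovariance) -> tuple[float, float, float]:
    """Eigen-decomposition back to (sigma1, sigma2, kernel_phi).

    ``sigma1`` is the larger eigen-scale and ``kernel_phi`` the orientation
    of its eigenvector in (-pi/2, pi/2].  For (near-)isotropic matrices the
    orientation is conventionally 0, pairing sigma1 with the x1 axis.
    """
    evals, evecs = np.linalg.eigh(cov.matrix)  # ascending
    if evals[0] <= 0:
        raise InvalidCovarianceError("covariance is not positive definite")
    sigma1, sigma2 = math.sqrt(evals[1]), math.sqrt(evals[0])
    if (evals[1] - evals[0]) <= 1e-14 * evals[1]:
        return sigma1, sigma2, 0.0
    v = evecs[:, 1]
    return sigma1, sigma2, _wrap_orientation(math.atan2(v[1], v[0]))


def gaussian_value(x, cov: SpatialCovariance):
    """Affine Gaussian density exp(-x^T Sigma^-1 x / 2) / (2 pi sqrt(det)).

    ``x`` may be a single position or an array of positions with trailing
    dimension 2; the result has the leading shape of ``x``.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != 2:
        raise InvalidInputError(f"positions must have trailing dimension 2, "
                                f"got shape {x.shape}")
    inv = cov.inverse()
    quad = (
        inv[0, 0] * x[..., 0] ** 2
        + 2.0 * inv[0, 1] * x[..., 0] * x[..., 1]
        + inv[1, 1] * x[..., 1] ** 2
    )
    return np.exp(-quad / 2.0) / (2.0 * math.pi * math.sqrt(cov.det))


def _anisotropy_exponent(x1, x2, sigma1: float, sigma2: float, phi: float):
    """Shared exponent of the first/second order closed forms."""
    v1, v2 = sigma1 * sigma1, sigma2 * sigma2
    rsq = x1 * x1 + x2 * x2
    cross = 2.0 * x1 * x2 * math.sin(2.0 * phi) + math.cos(2.0 * phi) * (
        x1 - x2
    ) * (x1 + x2)
    return -((v1 + v2) * rsq - (v1 - v2) * cross) / (4.0 * v1 * v2)


def simple_cell_value(x, spec: RFSpec):
    """Closed-form simple-cell model: scale-normalized directional derivative
    of the affine Gaussian along the kernel orientation.

    Only orders m = 1 and m = 2 with ``deriv_theta == kernel_phi`` and
    ``m2 == 0`` have closed forms here; other configurations are served by
    :func:`general_directional_value`.
    """
    if spec.m2 != 0 or spec.m1 not in (1, 2):
        raise OrderError(
            f"closed forms cover m1 in {{1, 2}}, m2 = 0; got "
            f"(m1, m2) = ({spec.m1}, {spec.m2}); use general_directional_value"
        )
    if not math.isclose(
        math.remainder(spec.deriv_theta - spec.kernel_phi, math.pi), 0.0,
        abs_tol=1e-12,
    ):
        raise OrderError(
            "closed forms require the derivative direction aligned with the "
            "kernel orientation; use general_directional_value"
        )
    x = np.asarray(x, dtype=float)
    x1, x2 = x[..., 0], x[..., 1]
    s1, s2, phi = spec.sigma1, spec.sigma2, spec.kernel_phi
    expo = np.exp(_anisotropy_exponent(x1, x2, s1, s2, phi))
    if spec.m1 == 1:
        amp = -(x1 * math.cos(phi) + x2 * math.sin(phi)) / (
            2.0 * math.pi * s1 * s1 * s2
        )
    else:
        amp = (
            math.cos(2.0 * phi) * (x1 * x1 - x2 * x2)
            + 2.0 * x1 * x2 * math.sin(2.0 * phi)
            - 2.0 * s1 * s1
            + x1 * x1
            + x2 * x2
        ) / (4.0 * math.pi * s1 ** 3 * s2)
    return amp * expo


def _hermite_factor(order: int, arg):
    """He_n evaluated elementwise (probabilists' Hermite polynomial)."""
    coeffs = np.zeros(order + 1)
    coeffs[order] = 1.0
    return hermite_e.hermeval(arg, coeffs)


def general_directional_value(x, spec: RFSpec):
    """Scale-normalized mixed directional derivative of the affine Gaussian.

    Applies ``(cos t d1 + sin t d2)^m1 (-sin t d1 + cos t d2)^m2`` to the
    Gaussian with covariance from ``spec``, normalized by
    ``sigma1^m1 sigma2^m2``.  The derivative direction ``t = deriv_theta``
    need not coincide with the kernel orientation.

    Internally the operators are rotated into the kernel eigenframe, where
    the Gaussian separates and every pure partial derivative is a Hermite
    polynomial times the Gaussian.
    """
    x = np.asarray(x, dtype=float)
    x1, x2 = x[..., 0], x[..., 1]
    s1, s2, phi = spec.sigma1, spec.sigma2, spec.kernel_phi
    # kernel-frame coordinates
    cphi, sphi = math.cos(phi), math.sin(phi)
    u = cphi * x1 + sphi * x2
    w = -sphi * x1 + cphi * x2
    gauss = np.exp(-(u * u) / (2 * s1 * s1) - (w * w) / (2 * s2 * s2)) / (
        2.0 * math.pi * s1 * s2
    )
    if spec.order == 0:
        return gauss
    # derivative direction relative to the kernel frame
    delta = spec.deriv_theta - phi
    a, b = math.cos(delta), math.sin(delta)
    m1, m2 = spec.m1, spec.m2
    # (a du + b dw)^m1 (-b du + a dw)^m2 expanded into du^p dw^q terms
    weights: dict[tuple[int, int], float] = {}
    for i in range(m1 + 1):
        ci = comb(m1, i, exact=True) * a**i * b ** (m1 - i)
        for j in range(m2 + 1):
            cj = comb(m2, j, exact=True) * (-b) ** j * a ** (m2 - j)
            p, q = i + j, (m1 - i) + (m2 - j)
            weights[(p, q)] = weights.get((p, q), 0.0) + ci * cj
    result = np.zeros(np.broadcast(u, w).shape)
    for (p, q), wt in weights.items():
        if wt == 0.0:
            continue
        term = (
            (-1.0) ** (p + q)
            * s1 ** (-p)
            * s2 ** (-q)
            * _hermite_factor(p, u / s1)
            * _hermite_factor(q, w / s2)
        )
        result = result + wt * term
    return s1**m1 * s2**m2 * result * gauss


def sample_kernel(
    spec: RFSpec,
    size: int,
    spacing: float = 1.0,
    *,
    on_truncation: str = "raise",
    normalize: bool = False,
) -> SampledField:
    """Pointwise evaluation of a receptive-field kernel on a centred grid.

    The grid half-extent must be at least 4 times the largest eigen-scale;
    smaller grids raise :class:`ExtentError` (``on_truncation="warn"``
    downgrades to a warning).  ``normalize`` rescales a zeroth-order kernel
    to unit discrete sum (off by default, preserving analytic values).
    """
    grid = centered_grid(size, spacing)
    half_extent = (size - 1) / 2.0 * spacing
    needed = 4.0 * max(spec.sigma1, spec.sigma2)
    if half_extent < needed:
        msg = (
            f"grid half-extent {half_extent:.3g} < 4 max(sigma) = {needed:.3g}; "
            "kernel mass will be truncated"
        )
        if on_truncation == "warn":
            warnings.warn(msg, stacklevel=2)
        else:
            raise ExtentError(msg)
    x1, x2 = grid.coords()
    pts = np.stack([x1, x2], axis=-1)
    if spec.order == 0:
        values = gaussian_value(pts, spec.covariance)
    else:
        values = general_directional_value(pts, spec)
    if normalize and spec.order == 0:
        values = values / (values.sum() * spacing * spacing)
    meta = {
        "spec": {
            "sigma1": spec.sigma1,
            "sigma2": spec.sigma2,
            "kernel_phi": spec.kernel_phi,
            "deriv_theta": spec.deriv_theta,
            "m1": spec.m1,
            "m2": spec.m2,
        },
        "truncation_radius": half_extent,
    }
    return SampledField(values, spacing, grid.origin, meta)


def temporal_gaussian(t, tau: float):
    """Unit-mass Gaussian temporal window of variance tau (non-causal)."""
    t = np.asarray(t, dtype=float)
    return np.exp(-(t * t) / (2.0 * tau)) / math.sqrt(2.0 * math.pi * tau)


def spatiotemporal_value(x, t, spec: SpatioTemporalRFSpec):
    """Velocity-adapted space-time kernel g(x - v t; Sigma) h(t; tau)."""
    x = np.asarray(x, dtype=float)
    t = np.asarray(t, dtype=float)
    v = np.asarray(spec.velocity)
    shifted = x - t[..., None] * v if t.ndim else x - t * v
    return gaussian_value(shifted, spec.sigma_matrix) * temporal_gaussian(t, spec.tau)
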