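"""Closed-form canonical decomposition of 2-D affine transformation matrices.

A 2x2 linear map ``x' = A x`` is factored as

    A = R_{psi/2} R_{phi/2} diag(rho1, rho2) R_{phi/2} R_{-psi/2}

where ``rho1 >= rho2 > 0`` are the singular values of ``A``, ``phi`` is the
total in-plane rotation and ``psi/2`` is the orientation of the symmetry
axis of the non-isotropic part.  The factorization is computed in closed
form from four scalar descriptors of the matrix entries, without calling an
iterative singular-value routine.
"""

from __future__ import annotations

import csv
import io
import json
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    DegenerateMapError,
    InvalidFactorsError,
    InvalidInputError,
    OutsideApplicabilityError,
)

__all__ = [
    "AffineMap",
    "AffineDescriptors",
    "AffineFactors",
    "compute_descriptors",
    "decompose",
    "compose",
    "svd_form",
    "rotation_matrix",
]

#: relative threshold below which Q is treated as exactly zero (similarity
#: transform); numeric noise must not produce an arbitrary symmetry axis.
SIMILARITY_THRESHOLD = 1e-14

#: reconstruction tolerance, relative to the max-norm of the input matrix.
RECONSTRUCTION_TOL = 1e-10


def rotation_matrix(angle: float) -> np.ndarray:
    """Counter-clockwise rotation matrix for ``angle`` radians."""
    c, s = math.cos(angle), math.sin(angle)
    return np.array([[c, -s], [s, c]])


def _wrap_angle(angle: float) -> float:
    """Wrap to the branch (-pi, pi]."""
    wrapped = math.remainder(angle, 2.0 * math.pi)
    if wrapped <= -math.pi:
        wrapped += 2.0 * math.pi
    return wrapped


@dataclass(frozen=True)
class AffineMap:
    """A 2x2 real linear map of image coordinates."""

    a11: float
    a12: float
    a21: float
    a22: float

    def __post_init__(self) -> None:
        entries = (self.a11, self.a12, self.a21, self.a22)
        if not all(math.isfinite(v) for v in entries):
            raise InvalidInputError(f"non-finite matrix entries: {entries}")

    @property
    def matrix(self) -> np.ndarray:
        return np.array([[self.a11, self.a12], [self.a21, self.a22]])

    @classmethod
    def from_matrix(cls, matrix: np.ndarray) -> "AffineMap":
        m = np.asarray(matrix, dtype=float)
        if m.shape != (2, 2):
            raise InvalidInputError(f"expected a 2x2 matrix, got shape {m.shape}")
        return cls(m[0, 0], m[0, 1], m[1, 0], m[1, 1])

    def det(self) -> float:
        return self.a11 * self.a22 - self.a12 * self.a21

    def inverse(self) -> "AffineMap":
        from .errors import InvalidMapError

        d = self.det()
        if d == 0.0:
            raise InvalidMapError("map is singular; cannot invert")
        return AffineMap(self.a22 / d, -self.a12 / d, -self.a21 / d, self.a11 / d)

    # -- plain-text and JSON round trips ------------------------------------

    def to_json(self) -> str:
        return json.dumps(
            {"a11": self.a11, "a12": self.a12, "a21": self.a21, "a22": self.a22}
        )

    @classmethod
    def from_json(cls, text: str) -> "AffineMap":
        obj = json.loads(text)
        try:
            return cls(float(obj["a11"]), float(obj["a12"]),
                       float(obj["a21"]), float(obj["a22"]))
        except (KeyError, TypeError) as exc:
            raise InvalidInputError(f"malformed affine-map JSON: {exc}") from exc

    def to_text(self) -> str:
        """Two-line whitespace-separated representation."""
        return f"{self.a11!r} {self.a12!r}\n{self.a21!r} {self.a22!r}\n"

    @classmethod
    def from_text(cls, text: str) -> "AffineMap":
        rows = [line.split() for line in text.strip().splitlines() if line.strip()]
        if len(rows) != 2 or any(len(r) != 2 for r in rows):
            raise InvalidInputError("expected two lines with two numbers each")
        return cls(float(rows[0][0]), float(rows[0][1]),
                   float(rows[1][0]), float(rows[1][1]))


@dataclass(frozen=True)
class AffineDescriptors:
    """Scalar descriptors of a 2x2 matrix.

    ``t/a`` capture the similarity part (trace and antisymmetric half),
    ``c/s`` the deviatoric part; ``p = hypot(t, a)`` and ``q = hypot(c, s)``
    are their rotation-invariant magnitudes.  Note that ``a_descr`` and
    ``s_descr`` are scalars, distinct from the matrix ``A`` and the uniform
    scale factor also conventionally written ``S``.
    """

    t_descr: float
    a_descr: float
    c_descr: float
    s_descr: float
    p_descr: float = field(init=False)
    q_descr: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "p_descr", math.hypot(self.t_descr, self.a_descr))
        object.__setattr__(self, "q_descr", math.hypot(self.c_descr, self.s_descr))


@dataclass(frozen=True)
class AffineFactors:
    """Canonical factors (rho1, rho2, phi, psi) of an affine map.

    ``scale = sqrt(rho1 rho2)`` is the uniform scaling component and
    ``stretch = rho1/rho2`` the non-uniform stretch ratio; ``alpha`` and
    ``beta`` are the rotation angles of the equivalent plain singular value
    decomposition.  ``psi_defined`` is False for similarity transforms
    (q = 0), where any symmetry-axis orientation reproduces the map and the
    canonical choice psi = 0 is made.  ``valid`` is False only in permissive
    mode when rho2 <= 0.
    """

    rho1: float
    rho2: float
    phi: float
    psi: float
    psi_defined: bool = True
    valid: bool = True

    @property
    def scale(self) -> float:
        return math.sqrt(self.rho1 * self.rho2)

    @property
    def stretch(self) -> float:
        return self.rho1 / self.rho2

    @property
    def alpha(self) -> float:
        return (self.psi + self.phi) / 2.0

    @property
    def beta(self) -> float:
        return (self.psi - self.phi) / 2.0

    @property
    def symmetry_axis(self) -> float:
        """Orientation psi/2 of the symmetry axis, in (-pi/2, pi/2]."""
        half = self.psi / 2.0
        if half <= -math.pi / 2.0:
            half += math.pi
        elif half > math.pi / 2.0:
            half -= math.pi
        return half

    def to_json(self) -> str:
        return json.dumps(
            {
                "rho1": self.rho1,
                "rho2": self.rho2,
                "phi": self.phi,
                "psi": self.psi,
                "scale": self.scale,
                "stretch": self.stretch,
                "psi_defined": self.psi_defined,
                "valid": self.valid,
            }
        )

    def to_csv(self) -> str:
        """One-row CSV with header rho1,rho2,phi,psi,scale,stretch."""
        buf = io.StringIO()
        writer = csv.writer(buf)
        writer.writerow(["rho1", "rho2", "phi", "psi", "scale", "stretch"])
        writer.writerow(
            [self.rho1, self.rho2, self.phi, self.psi, self.scale, self.stretch]
        )
        return buf.getvalue()


def compute_descriptors(map: AffineMap) -> AffineDescriptors:
    """Scalar descriptors (t, a, c, s) and magnitudes (p, q) of a map."""
    return AffineDescriptors(
        t_descr=(map.a11 + map.a22) / 2.0,
        a_descr=(map.a21 - map.a12) / 2.0,
        c_descr=(map.a11 - map.a22) / 2.0,
        s_descr=(map.a12 + map.a21) / 2.0,
    )


def decompose(
    map: AffineMap,
    *,
    permissive: bool = False,
    verify: bool = False,
) -> AffineFactors:
    """Closed-form factorization of ``map`` into (rho1, rho2, phi, psi).

    The singular values are ``rho1 = p + q`` and ``rho2 = p - q``; the
    angles are quadrant-aware arctangents of the descriptor pairs, so the
    full branch (-pi, pi] is handled (the plain ratio forms tan(phi) = a/t
    and tan(psi) = s/c are sign-ambiguous).

    Parameters
    ----------
    map:
        The 2x2 linear map to factor.
    permissive:
        If True, a non-positive ``rho2`` yields factors flagged
        ``valid=False`` instead of raising.
    verify:
        If True, re-compose the factors and check reconstruction against
        the input to a relative tolerance of 1e-10.

    Raises
    ------
    DegenerateMapError
        If p = 0 (e.g. pure skew-symmetric maps): phi is undefined.
    OutsideApplicabilityError
        If rho2 <= 0 and ``permissive`` is False.
    """
    d = compute_descriptors(map)
    if d.p_descr == 0.0:
        raise DegenerateMapError(
            "p = 0: the rotation angle is undefined for this map "
            "(e.g. a pure skew-symmetric matrix)"
        )
    rho1 = d.p_descr + d.q_descr
    rho2 = d.p_descr - d.q_descr
    valid = rho2 > 0.0
    if not valid and not permissive:
        raise OutsideApplicabilityError(
            f"smaller singular value rho2 = {rho2:.6g} <= 0; the closed-form "
            "decomposition requires maps close to a positive multiple of the "
            "identity (pass permissive=True to get flagged factors)"
        )
    phi = _wrap_angle(math.atan2(d.a_descr, d.t_descr))
    if d.q_descr < SIMILARITY_THRESHOLD * d.p_descr:
        psi, psi_defined = 0.0, False
    else:
        psi = _wrap_angle(math.atan2(d.s_descr, d.c_descr))
        psi_defined = True
    factors = AffineFactors(rho1, rho2, phi, psi, psi_defined, valid)
    if verify and valid:
        err = np.max(np.abs(compose(factors).matrix - map.matrix))
        scale = max(np.max(np.abs(map.matrix)), 1e-300)
        if err > RECONSTRUCTION_TOL * scale:
            raise InvalidInputError(
                f"reconstruction error {err:.3g} exceeds tolerance"
            )
    return factors


def compose(factors: AffineFactors) -> AffineMap:
    """Rebuild the map R_{psi/2} R_{phi/2} diag(rho1, rho2) R_{phi/2} R_{-psi/2}."""
    if not (factors.rho1 > 0.0 and factors.rho2 > 0.0):
        raise InvalidFactorsError(
            f"singular values must be positive, got "
            f"({factors.rho1}, {factors.rho2})"
        )
    r_half_psi = rotation_matrix(factors.psi / 2.0)
    r_half_phi = rotation_matrix(factors.phi / 2.0)
    d = np.diag([factors.rho1, factors.rho2])
    m = r_half_psi @ r_half_phi @ d @ r_half_phi @ r_half_psi.T
    return AffineMap.from_matrix(m)


def svd_form(factors: AffineFactors) -> tuple[float, tuple[float, float], float]:
    """Equivalent rotation-diagonal-rotation form.

    Returns ``(alpha, (rho1, rho2), beta)`` such that
    ``R_alpha @ diag(rho1, rho2) @ R_beta.T`` equals ``compose(factors)``,
    with ``alpha = (psi + phi)/2`` and ``beta = (psi - phi)/2``.
    """
    if not (factors.rho1 > 0.0 and factors.rho2 > 0.0):
        raise InvalidFactorsError(
            f"singular values must be positive, got "
            f"({factors.rho1}, {factors.rho2})"
        )
    return factors.alpha, (factors.rho1, factors.rho2), factors.beta
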