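"""Affine maps induced by monocular and binocular viewing geometry.

Coordinates are right-handed with x1 horizontal and x2 vertical; in the
monocular case the x2 axis is aligned with the tilt direction (the image
projection of the surface normal).
"""

from __future__ import annotations

import csv
import io
import math
from dataclasses import dataclass

import numpy as np

from .decomposition import AffineMap
from .errors import GrazingViewError, InvalidGeometryError, InvalidInputError

__all__ = [
    "MonocularViewGeometry",
    "BinocularViewGeometry",
    "DeformationField",
    "monocular_map",
    "binocular_map",
    "deformation_field",
    "square_grid",
]


@dataclass(frozen=True)
class MonocularViewGeometry:
    """Viewing distance and surface slant for a monocular observer.

    ``distance_lambda`` is the distance from the observer to the surface
    point; ``slant_nu`` the angle between surface normal and viewing
    direction, strictly below pi/2.
    """

    distance_lambda: float
    slant_nu: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.distance_lambda) and self.distance_lambda > 0):
            raise InvalidInputError(
                f"distance must be positive and finite, got {self.distance_lambda}"
            )
        if not (0.0 <= self.slant_nu < math.pi / 2.0):
            raise GrazingViewError(
                f"slant angle {self.slant_nu} outside [0, pi/2): the linearized "
                "projection degenerates at grazing view"
            )


@dataclass(frozen=True)
class BinocularViewGeometry:
    """Vergence/gaze configuration of a symmetric binocular observer.

    ``half_vergence_mu`` is half the angle between the two viewing
    directions, ``gaze_gamma`` the angle from the frontal direction to the
    fixation point, and ``depth_gradient`` = (Z_X, Z_Y) the slope of the
    observed surface in depth per unit image coordinate.
    """

    half_vergence_mu: float
    gaze_gamma: float
    depth_gradient: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        zx, zy = self.depth_gradient
        vals = (self.half_vergence_mu, self.gaze_gamma, zx, zy)
        if not all(math.isfinite(v) for v in vals):
            raise InvalidInputError(f"non-finite geometry parameters: {vals}")


@dataclass(frozen=True)
class DeformationField:
    """Displacement vectors dx = (A - I) x on an explicit set of positions."""

    grid: np.ndarray       # (n, 2) positions
    vectors: np.ndarray    # (n, 2) displacements

    def __post_init__(self) -> None:
        g = np.atleast_2d(np.asarray(self.grid, dtype=float))
        v = np.atleast_2d(np.asarray(self.vectors, dtype=float))
        if g.shape != v.shape or g.shape[1] != 2:
            raise InvalidInputError(
                f"grid and vectors must both be (n, 2), got {g.shape}, {v.shape}"
            )
        if not np.all(np.isfinite(v)):
            raise InvalidInputError("non-finite displacement vectors")
        object.__setattr__(self, "grid", g)
        object.__setattr__(self, "vectors", v)

    def to_csv(self) -> str:
        buf = io.StringIO()
        writer = csv.writer(buf)
        writer.writerow(["x1", "x2", "dx1", "dx2"])
        for (x1, x2), (d1, d2) in zip(self.grid, self.vectors):
            writer.writerow([x1, x2, d1, d2])
        return buf.getvalue()


def monocular_map(geom: MonocularViewGeometry) -> AffineMap:
    """Locally linearized perspective projection of a slanted surface patch.

    Returns ``(1/Lambda) diag(1, cos nu)``: a uniform scaling by the inverse
    viewing distance composed with foreshortening by cos(slant) along the
    tilt direction (the x2 axis).
    """
    inv_dist = 1.0 / geom.distance_lambda
    return AffineMap(inv_dist, 0.0, 0.0, inv_dist * math.cos(geom.slant_nu))


def binocular_map(geom: BinocularViewGeometry) -> AffineMap:
    """Disparity-gradient map from the left to the right image.

    The map has the structure ``[[1+h1, h2], [v1, 1+v2]]`` with zero
    lower-left entry for a calibrated symmetric observer; ``h`` is the
    horizontal and ``v`` the vertical disparity gradient.
    """
    mu, gamma = geom.half_vergence_mu, geom.gaze_gamma
    zx, zy = geom.depth_gradient
    denom_gaze = math.cos(gamma + mu)
    if abs(denom_gaze) < 1e-12:
        raise InvalidGeometryError(
            f"cos(gamma + mu) = 0 at gamma={gamma}, mu={mu}: the right view "
            "is degenerate"
        )
    denom_depth = math.cos(mu) - zx * math.sin(mu)
    if abs(denom_depth) < 1e-12:
        raise InvalidGeometryError(
            f"cos(mu) - Z_X sin(mu) = 0 at mu={mu}, Z_X={zx}: the surface is "
            "viewed edge-on by the left eye"
        )
    prefactor = math.cos(gamma - mu) / denom_gaze
    a11 = (math.cos(mu) + zx * math.sin(mu)) / denom_depth
    a12 = zy * math.sin(2.0 * mu) / denom_depth
    return AffineMap(prefactor * a11, prefactor * a12, 0.0, prefactor * 1.0)


def deformation_field(map: AffineMap, grid: np.ndarray) -> DeformationField:
    """Displacements dx = A x - x at each grid position."""
    g = np.atleast_2d(np.asarray(grid, dtype=float))
    if g.size == 0:
        raise InvalidInputError("grid must be non-empty")
    vectors = g @ (map.matrix - np.eye(2)).T
    return DeformationField(g, vectors)


def square_grid(density: int = 17, extent: float = 1.0) -> np.ndarray:
    """A ``density x density`` lattice of positions over [-extent, extent]^2."""
    axis = np.linspace(-extent, extent, density)
    x1, x2 = np.meshgrid(axis, axis, indexing="ij")
    return np.column_stack([x1.ravel(), x2.ravel()])
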