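"""Discretized scalar fields on regular grids.

Axis convention used throughout the package: array axis 0 corresponds to
the x1 coordinate and axis 1 to x2, with a common grid spacing along both
axes.  ``origin`` is the physical position of sample ``values[0, 0]``;
helper constructors place the origin so that the grid is centred on (0, 0),
the fixation point.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import InvalidInputError

__all__ = ["SampledField", "centered_grid"]


@dataclass(frozen=True)
class SampledField:
    """A 2-D scalar field sampled on a regular, square-spaced grid."""

    values: np.ndarray
    spacing: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise InvalidInputError(f"values must be 2-D, got ndim={v.ndim}")
        if not self.spacing > 0:
            raise InvalidInputError(f"spacing must be positive, got {self.spacing}")
        if not np.all(np.isfinite(v)):
            raise InvalidInputError("field contains non-finite values")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "origin", (float(self.origin[0]), float(self.origin[1])))

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Physical coordinate arrays (X1, X2), each with ``values.shape``."""
        n1, n2 = self.values.shape
        x1 = self.origin[0] + self.spacing * np.arange(n1)
        x2 = self.origin[1] + self.spacing * np.arange(n2)
        return np.meshgrid(x1, x2, indexing="ij")

    def center_index(self) -> tuple[float, float]:
        """Fractional index of the physical origin (0, 0)."""
        return (-self.origin[0] / self.spacing, -self.origin[1] / self.spacing)

    def with_values(self, values: np.ndarray) -> "SampledField":
        return replace(self, values=values)

    # -- text persistence ---------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Write values as whitespace-separated text plus a JSON sidecar."""
        path = Path(path)
        np.savetxt(path, self.values)
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(
            json.dumps(
                {
                    "spacing": self.spacing,
                    "origin": list(self.origin),
                    "shape": list(self.values.shape),
                    "meta": self.meta,
                }
            )
        )

    @classmethod
    def load(cls, path: str | Path) -> "SampledField":
        path = Path(path)
        values = np.loadtxt(path)
        sidecar = path.with_suffix(path.suffix + ".json")
        if sidecar.exists():
            info = json.loads(sidecar.read_text())
            return cls(values, info["spacing"], tuple(info["origin"]),
                       info.get("meta", {}))
        return cls(values)


def centered_grid(size: int, spacing: float = 1.0) -> SampledField:
    """An all-zero field of ``size x size`` samples centred on the origin.

    Sample centres sit at integer multiples of ``spacing`` shifted so the
    grid centre index ``(size-1)/2`` falls on the physical origin.
    """
    half = (size - 1) / 2.0 * spacing
    return SampledField(np.zeros((size, size)), spacing, (-half, -half))
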