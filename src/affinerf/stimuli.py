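"""Synthetic test imagery, image warping and figure-style galleries.

Images live on centred grids (the fixation point is the grid centre) with
pixel centres at integer multiples of the spacing.  Band-limited noise is
generated as a finite sum of random plane waves, which makes it a
well-defined continuous function of position: the same seed can be sampled
at any resolution, which the grid-refinement convergence checks rely on.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .decomposition import AffineMap
from .errors import InvalidMapError, ParameterError
from .fields import SampledField, centered_grid
from .kernels import RFSpec, sample_kernel

__all__ = [
    "StimulusSpec",
    "make_stimulus",
    "band_limited_noise_function",
    "warp_image",
    "render_gallery",
    "save_png",
]

_KINDS = ("grating", "band_limited_noise", "impulse", "constant")


@dataclass(frozen=True)
class StimulusSpec:
    """Parameters of a deterministic synthetic stimulus."""

    kind: str
    size: int = 64
    wavelength: float = 8.0
    orientation: float = 0.0
    phase: float = 0.0
    cutoff: float = 8.0
    seed: int = 0
    frames: int = 1
    drift_velocity: tuple[float, float] = (0.0, 0.0)
    value: float = 1.0  # constant level / impulse height

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ParameterError(f"unknown stimulus kind {self.kind!r}; "
                                 f"expected one of {_KINDS}")
        if self.size < 16:
            raise ParameterError(f"size must be >= 16, got {self.size}")
        if self.frames < 1:
            raise ParameterError(f"frames must be >= 1, got {self.frames}")
        if self.kind == "grating" and self.wavelength < 4.0:
            raise ParameterError(
                f"grating wavelength {self.wavelength} < 4 px would alias"
            )
        if self.kind == "band_limited_noise" and self.cutoff < 4.0:
            raise ParameterError(
                f"noise cutoff wavelength {self.cutoff} < 4 px would alias"
            )


def band_limited_noise_function(seed: int, cutoff: float, n_waves: int = 64):
    """A continuous zero-mean random field as a sum of random cosines.

    All constituent wavelengths lie in [cutoff, 8*cutoff], so the field is
    band-limited with shortest wavelength ``cutoff`` (in the same length
    units as the evaluation coordinates).  Returns a callable of coordinate
    arrays ``(x1, x2)``.
    """
    rng = np.random.default_rng(seed)
    wavelengths = np.exp(
        rng.uniform(math.log(cutoff), math.log(8.0 * cutoff), n_waves)
    )
    directions = rng.uniform(0.0, 2.0 * math.pi, n_waves)
    phases = rng.uniform(0.0, 2.0 * math.pi, n_waves)
    amplitudes = rng.normal(0.0, 1.0, n_waves) / math.sqrt(n_waves / 2.0)
    k = 2.0 * math.pi / wavelengths
    k1, k2 = k * np.cos(directions), k * np.sin(directions)

    def evaluate(x1, x2):
        x1 = np.asarray(x1, dtype=float)[..., None]
        x2 = np.asarray(x2, dtype=float)[..., None]
        return np.sum(amplitudes * np.cos(k1 * x1 + k2 * x2 + phases), axis=-1)

    return evaluate


def _single_frame(spec: StimulusSpec, t: float, spacing: float) -> SampledField:
    grid = centered_grid(spec.size, spacing)
    x1, x2 = grid.coords()
    if spec.kind == "constant":
        values = np.full(grid.shape, spec.value)
    elif spec.kind == "impulse":
        values = np.zeros(grid.shape)
        c = (spec.size - 1) // 2
        values[c, c] = spec.value
    elif spec.kind == "grating":
        v1, v2 = spec.drift_velocity
        u = (x1 - v1 * t) * math.cos(spec.orientation) + (
            x2 - v2 * t
        ) * math.sin(spec.orientation)
        values = np.cos(2.0 * math.pi * u / spec.wavelength + spec.phase)
    else:  # band_limited_noise
        noise = band_limited_noise_function(spec.seed, spec.cutoff)
        v1, v2 = spec.drift_velocity
        values = noise(x1 - v1 * t, x2 - v2 * t)
    return SampledField(values, spacing, grid.origin, {"kind": spec.kind, "t": t})


def make_stimulus(spec: StimulusSpec, spacing: float = 1.0):
    """Deterministic stimulus; a single field, or a list of frames."""
    if spec.frames == 1:
        return _single_frame(spec, 0.0, spacing)
    return [_single_frame(spec, float(t), spacing) for t in range(spec.frames)]


def warp_image(image: SampledField, map: AffineMap, *, order: int = 3) -> SampledField:
    """Affine warp: the output at x' carries the source value at A^-1 x'.

    Uses separable spline interpolation (cubic by default) with reflective
    boundary handling; warps about the grid centre, so 90-degree rotations
    and compatible integer scalings are grid-exact.
    """
    det = map.det()
    if det == 0.0:
        raise InvalidMapError("cannot warp by a singular map")
    if np.array_equal(map.matrix, np.eye(2)):
        return SampledField(image.values.copy(), image.spacing, image.origin,
                            dict(image.meta))
    inv = map.inverse().matrix
    n1, n2 = image.shape
    center = np.array([(n1 - 1) / 2.0, (n2 - 1) / 2.0])
    offset = center - inv @ center
    values = ndimage.affine_transform(
        image.values, inv, offset=offset, order=order, mode="reflect"
    )
    return SampledField(values, image.spacing, image.origin,
                        {**image.meta, "warped_by": map.matrix.tolist()})


def render_gallery(
    specs,
    path: str | Path,
    *,
    size: int = 41,
    spacing: float = 0.5,
    titles=None,
    ncols: int | None = None,
):
    """Render one panel per kernel spec into a single PNG/SVG figure."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    specs = list(specs)
    if not specs:
        raise ParameterError("gallery sweep must be non-empty")
    ncols = ncols or len(specs)
    nrows = math.ceil(len(specs) / ncols)
    fig, axes = plt.subplots(
        nrows, ncols, figsize=(2.0 * ncols, 2.0 * nrows), squeeze=False
    )
    for ax in axes.ravel():
        ax.axis("off")
    for idx, spec in enumerate(specs):
        fieldk = sample_kernel(spec, size, spacing, on_truncation="warn")
        ax = axes[idx // ncols][idx % ncols]
        lim = np.max(np.abs(fieldk.values)) or 1.0
        # axis 0 is x1 (horizontal): transpose for display, origin low
        ax.imshow(
            fieldk.values.T, origin="lower", cmap="RdBu_r", vmin=-lim, vmax=lim
        )
        if titles is not None:
            ax.set_title(titles[idx], fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def save_png(image: SampledField, path: str | Path) -> Path:
    """Write a 16-bit grayscale PNG plus a JSON sidecar with the rescaling.

    The affine intensity map applied for quantization is recorded so the
    PNG remains a faithful (if quantized) display format; text arrays are
    the authoritative interchange.
    """
    import imageio.v3 as iio

    path = Path(path)
    lo, hi = float(image.values.min()), float(image.values.max())
    span = (hi - lo) or 1.0
    quantized = np.round((image.values - lo) / span * 65535).astype(np.uint16)
    iio.imwrite(path, quantized.T[::-1])  # display orientation
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps(
            {
                "intensity_offset": lo,
                "intensity_scale": span / 65535.0,
                "spacing": image.spacing,
                "origin": list(image.origin),
            }
        )
    )
    return path
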