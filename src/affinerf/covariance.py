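"""Affine-covariance verification, derivative steering and cascade smoothing.

The central identity: smoothing a warped image ``f'(x') = f(A^{-1} x')``
with the transformed covariance ``Sigma' = A Sigma A^T`` reproduces, at
``x' = A x``, the smoothing of the original image with ``Sigma``.  The
verification operations realize both sides of the identity on discrete
grids and quantify the residual over an interior region unaffected by
boundary handling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal
from scipy.special import comb

from .decomposition import AffineMap, decompose
from .errors import (
    CascadeInfeasibleError,
    ConfigurationError,
    DegenerateBasisError,
    ExtentError,
    InvalidMapError,
)
from .fields import SampledField, centered_grid
from .kernels import (
    RFSpec,
    SpatialCovariance,
    SpatioTemporalRFSpec,
    gaussian_value,
    general_directional_value,
    shape_from_covariance,
    temporal_gaussian,
)
from .stimuli import warp_image

__all__ = [
    "CovarianceReport",
    "SteeringSolution",
    "transform_covariance",
    "transform_gradient",
    "smooth",
    "verify_affine_covariance",
    "verify_spatiotemporal_covariance",
    "steer_coefficients",
    "match_responses",
    "cascade_smooth",
    "directional_basis_vector",
]

#: condition-number threshold for "sufficiently different" basis directions
CONDITION_LIMIT = 1e6

#: maximum stretch ratio accepted by the verification drivers
STRETCH_LIMIT = 4.0


@dataclass(frozen=True)
class CovarianceReport:
    """Interior residual statistics of a covariance verification."""

    interior_rms_relative_error: float
    max_relative_error: float
    interior_margin: float
    n_interior: int = 0
    details: dict = field(default_factory=dict)


@dataclass(frozen=True)
class SteeringSolution:
    """Linear-combination coefficients over a directional basis."""

    coefficients: np.ndarray
    basis_angles: np.ndarray
    residual: float
    condition_estimate: float


def transform_covariance(cov: SpatialCovariance, map: AffineMap) -> SpatialCovariance:
    """Push a covariance through an affine map: Sigma' = A Sigma A^T."""
    if map.det() == 0.0:
        raise InvalidMapError("cannot transform covariance by a singular map")
    a = map.matrix
    return SpatialCovariance.from_matrix(a @ cov.matrix @ a.T)


def transform_gradient(map: AffineMap) -> AffineMap:
    """Operator mapping source-domain gradients to target-domain gradients:
    the inverse transpose A^{-T}."""
    return AffineMap.from_matrix(map.inverse().matrix.T)


def _gaussian_weights(
    cov: SpatialCovariance, spacing: float, truncation: float
) -> np.ndarray:
    radius = int(math.ceil(truncation * cov.max_sigma() / spacing))
    axis = spacing * np.arange(-radius, radius + 1)
    x1, x2 = np.meshgrid(axis, axis, indexing="ij")
    pts = np.stack([x1, x2], axis=-1)
    return gaussian_value(pts, cov) * spacing * spacing


def _convolve_reflect(values: np.ndarray, kernel: np.ndarray,
                      method: str = "auto") -> np.ndarray:
    """True 2-D convolution with half-sample-symmetric boundary extension.

    The frequency-domain path is numerically equivalent (to rounding) to
    direct accumulation with the same truncated kernel; it is selected
    automatically for large kernels.
    """
    if method == "direct" or (method == "auto" and kernel.shape[0] <= 31):
        return ndimage.convolve(values, kernel, mode="reflect")
    r1, r2 = kernel.shape[0] // 2, kernel.shape[1] // 2
    padded = np.pad(values, ((r1, r1), (r2, r2)), mode="symmetric")
    out = signal.fftconvolve(padded, kernel, mode="same")
    return out[r1:-r1 or None, r2:-r2 or None]


def smooth(
    image: SampledField,
    cov: SpatialCovariance,
    *,
    normalize: bool = True,
    truncation: float = 4.0,
    method: str = "auto",
) -> SampledField:
    """Convolve an image with the sampled affine Gaussian (reflective
    boundaries).

    The kernel is truncated at ``truncation`` standard deviations along the
    major axis; by default the discrete weights are renormalized to unit
    sum so that constant images are reproduced exactly.  ``method`` selects
    direct spatial accumulation or the equivalent frequency-domain path.
    """
    weights = _gaussian_weights(cov, image.spacing, truncation)
    if weights.shape[0] > min(image.shape):
        raise ExtentError(
            f"kernel support {weights.shape[0]} exceeds image extent "
            f"{min(image.shape)}; covariance too large for this image"
        )
    if normalize:
        weights = weights / weights.sum()
    values = _convolve_reflect(image.values, weights, method)
    return SampledField(values, image.spacing, image.origin, dict(image.meta))


def _smooth_with_kernel(image: SampledField, kernel: np.ndarray) -> np.ndarray:
    """Discrete convolution with an arbitrary (derivative) kernel; the
    kernel is assumed to already include the spacing^2 quadrature factor."""
    if kernel.shape[0] > min(image.shape):
        raise ExtentError("derivative kernel larger than image")
    return _convolve_reflect(image.values, kernel)


def _derivative_weights(
    cov: SpatialCovariance, axis: int, spacing: float, truncation: float = 4.0
) -> np.ndarray:
    """Sampled raw partial derivative d/dx_axis of the affine Gaussian."""
    sigma1, sigma2, phi = shape_from_covariance(cov)
    radius = int(math.ceil(truncation * max(sigma1, sigma2) / spacing))
    ax = spacing * np.arange(-radius, radius + 1)
    x1, x2 = np.meshgrid(ax, ax, indexing="ij")
    pts = np.stack([x1, x2], axis=-1)
    theta = 0.0 if axis == 0 else math.pi / 2.0
    spec = RFSpec(sigma1, sigma2, phi, deriv_theta=theta, m1=1, m2=0)
    # drop the sigma1 scale normalization: Eq. of gradient transform applies
    # to raw derivatives
    return general_directional_value(pts, spec) / sigma1 * spacing * spacing


def _interior_mask(
    image: SampledField,
    map: AffineMap,
    margin_src: float,
    margin_tgt: float,
) -> tuple[np.ndarray, float]:
    """Pixels whose value and whose image under the map are both far enough
    from the respective grid boundaries."""
    x1, x2 = image.coords()
    n1, n2 = image.shape
    h1 = (n1 - 1) / 2.0 * image.spacing
    h2 = (n2 - 1) / 2.0 * image.spacing
    a = map.matrix
    y1 = a[0, 0] * x1 + a[0, 1] * x2
    y2 = a[1, 0] * x1 + a[1, 1] * x2
    mask = (
        (np.abs(x1) <= h1 - margin_src)
        & (np.abs(x2) <= h2 - margin_src)
        & (np.abs(y1) <= h1 - margin_tgt)
        & (np.abs(y2) <= h2 - margin_tgt)
    )
    return mask, margin_src


def _residual_stats(diff: np.ndarray, reference: np.ndarray, mask: np.ndarray):
    """RMS and max interior error, both relative to the interior RMS
    amplitude of the reference (shared denominator so rms <= max)."""
    d = diff[mask]
    r = reference[mask]
    denom = float(np.sqrt(np.mean(r * r))) or 1.0
    rms_rel = float(np.sqrt(np.mean(d * d))) / denom
    max_rel = float(np.max(np.abs(d))) / denom
    return rms_rel, max_rel


def verify_affine_covariance(
    image: SampledField,
    map: AffineMap,
    cov: SpatialCovariance,
    deriv_spec: RFSpec | None = None,
    *,
    extra_margin: float = 2.0,
    truncation: float = 6.0,
) -> CovarianceReport:
    """Measure how well smoothing commutes with an affine warp.

    Computes ``L = g(.; Sigma) * f`` on the source grid, warps the image,
    smooths the warped image with ``Sigma' = A Sigma A^T``, pulls the result
    back through the map, and reports interior residuals between the two.
    If ``deriv_spec`` is given, gradient responses are additionally compared
    after transforming the source gradient by ``A^{-T}``.
    """
    factors = decompose(map)
    if factors.stretch > STRETCH_LIMIT:
        raise ConfigurationError(
            f"stretch ratio {factors.stretch:.3g} exceeds limit {STRETCH_LIMIT}"
        )
    cov_t = transform_covariance(cov, map)
    margin_src = truncation * cov.max_sigma() + extra_margin * image.spacing
    margin_tgt = truncation * cov_t.max_sigma() + extra_margin * image.spacing

    source_l = smooth(image, cov, truncation=truncation)
    warped = warp_image(image, map)
    target_l = smooth(warped, cov_t, truncation=truncation)
    pullback = warp_image(target_l, map.inverse())  # x -> L'(A x)

    mask, margin = _interior_mask(image, map, margin_src, margin_tgt)
    if not mask.any():
        raise ConfigurationError(
            "interior region is empty: image too small for the requested "
            "covariance and map"
        )
    rms_rel, max_rel = _residual_stats(
        pullback.values - source_l.values, source_l.values, mask
    )
    details: dict = {}
    if deriv_spec is not None:
        ginv_t = map.inverse().matrix.T  # A^{-T}
        grads_src = [
            _smooth_with_kernel(
                image, _derivative_weights(cov, ax, image.spacing, truncation)
            )
            for ax in (0, 1)
        ]
        grads_tgt = [
            _smooth_with_kernel(
                warped, _derivative_weights(cov_t, ax, image.spacing, truncation)
            )
            for ax in (0, 1)
        ]
        pull_tgt = [
            warp_image(SampledField(g, image.spacing, image.origin),
                       map.inverse()).values
            for g in grads_tgt
        ]
        pred = [
            ginv_t[0, 0] * grads_src[0] + ginv_t[0, 1] * grads_src[1],
            ginv_t[1, 0] * grads_src[0] + ginv_t[1, 1] * grads_src[1],
        ]
        ref_amp = np.sqrt(pred[0] ** 2 + pred[1] ** 2)
        grad_rms, grad_max = _residual_stats(
            np.hypot(pull_tgt[0] - pred[0], pull_tgt[1] - pred[1]), ref_amp, mask
        )
        details["gradient_rms_relative_error"] = grad_rms
        details["gradient_max_relative_error"] = grad_max
    return CovarianceReport(rms_rel, max_rel, margin, int(mask.sum()), details)


def _spatiotemporal_smooth(
    frames: list[SampledField],
    spec: SpatioTemporalRFSpec,
    dt: float = 1.0,
) -> tuple[list[SampledField], list[int]]:
    """Velocity-adapted separable smoothing of a frame stack.

    Returns smoothed output frames and the indices of temporally valid
    frames (those whose temporal support lies inside the stack).
    """
    spatial = [smooth(f, spec.sigma_matrix) for f in frames]
    radius = int(math.ceil(4.0 * math.sqrt(spec.tau) / dt))
    taps = np.arange(-radius, radius + 1) * dt
    h = temporal_gaussian(taps, spec.tau) * dt
    h = h / h.sum()
    v = np.asarray(spec.velocity)
    n = len(frames)
    valid = [t for t in range(n) if t - radius >= 0 and t + radius < n]
    out: list[SampledField] = []
    for t in valid:
        acc = np.zeros(frames[0].shape)
        for s_idx, s in enumerate(range(-radius, radius + 1)):
            frame = spatial[t - s]
            shift_px = v * (s * dt) / frame.spacing
            if np.any(shift_px != 0.0):
                shifted = ndimage.shift(frame.values, shift_px, order=3,
                                        mode="reflect")
            else:
                shifted = frame.values
            acc += h[s_idx] * shifted
        out.append(SampledField(acc, frames[0].spacing, frames[0].origin))
    return out, valid


def verify_spatiotemporal_covariance(
    video: list[SampledField],
    map: AffineMap,
    spec: SpatioTemporalRFSpec,
    *,
    extra_margin: float = 2.0,
    velocity_transform: str = "identity",
) -> CovarianceReport:
    """Spatio-temporal covariance check under a pure spatial warp (t' = t).

    The target stack is the frame-by-frame warp of the source stack; it is
    smoothed with ``Sigma' = A Sigma A^T``, equal temporal scale and, per
    ``velocity_transform``, either the same velocity (``"identity"``) or
    ``A v`` (``"map"``).
    """
    factors = decompose(map)
    if factors.stretch > STRETCH_LIMIT:
        raise ConfigurationError(
            f"stretch ratio {factors.stretch:.3g} exceeds limit {STRETCH_LIMIT}"
        )
    if velocity_transform not in ("identity", "map"):
        raise ConfigurationError(
            f"velocity_transform must be 'identity' or 'map', got "
            f"{velocity_transform!r}"
        )
    cov_t = transform_covariance(spec.sigma_matrix, map)
    if velocity_transform == "map":
        v_t = tuple(map.matrix @ np.asarray(spec.velocity))
    else:
        v_t = spec.velocity
    spec_t = SpatioTemporalRFSpec(cov_t, spec.tau, v_t)

    src_l, valid = _spatiotemporal_smooth(video, spec)
    warped = [warp_image(f, map) for f in video]
    tgt_l, _ = _spatiotemporal_smooth(warped, spec_t)

    spacing = video[0].spacing
    v_reach = max(
        np.max(np.abs(np.asarray(spec.velocity))),
        np.max(np.abs(np.asarray(v_t))),
    ) * 4.0 * math.sqrt(spec.tau)
    margin_src = 4.0 * spec.sigma_matrix.max_sigma() + v_reach + extra_margin * spacing
    margin_tgt = 4.0 * cov_t.max_sigma() + v_reach + extra_margin * spacing
    mask, margin = _interior_mask(video[0], map, margin_src, margin_tgt)
    if not mask.any():
        raise ConfigurationError("interior region is empty for this geometry")

    sq_err = 0.0
    sq_ref = 0.0
    max_err = 0.0
    count = 0
    for src_frame, tgt_frame in zip(src_l, tgt_l):
        pullback = warp_image(tgt_frame, map.inverse())
        d = (pullback.values - src_frame.values)[mask]
        r = src_frame.values[mask]
        sq_err += float(np.sum(d * d))
        sq_ref += float(np.sum(r * r))
        max_err = max(max_err, float(np.max(np.abs(d))))
        count += d.size
    denom = math.sqrt(sq_ref / count) or 1.0
    rms_rel = math.sqrt(sq_err / count) / denom
    max_rel = max_err / denom
    return CovarianceReport(rms_rel, max_rel, margin, count,
                            {"valid_frames": valid})


def directional_basis_vector(order_m: int, theta: float) -> np.ndarray:
    """Monomial coefficients of (cos t d1 + sin t d2)^m in the Cartesian
    partial-derivative basis d1^{m-i} d2^{i}, i = 0..m."""
    c, s = math.cos(theta), math.sin(theta)
    return np.array(
        [comb(order_m, i, exact=True) * c ** (order_m - i) * s**i
         for i in range(order_m + 1)]
    )


def _check_angles_distinct(basis_angles: np.ndarray) -> None:
    n = len(basis_angles)
    for i in range(n):
        for j in range(i + 1, n):
            sep = abs(math.remainder(basis_angles[i] - basis_angles[j], math.pi))
            if sep < 1e-9:
                raise DegenerateBasisError(
                    f"basis angles {basis_angles[i]} and {basis_angles[j]} "
                    "coincide modulo pi; directions must be sufficiently "
                    "different"
                )


def steer_coefficients(
    order_m: int,
    target_theta: float,
    basis_angles,
    shape: tuple[float, float, float] | None = None,
    *,
    residual_grid: int = 33,
) -> SteeringSolution:
    """Coefficients expressing an order-m directional derivative at
    ``target_theta`` as a combination of the same-order derivatives at the
    basis angles.

    The linear system is solved in the (m+1)-dimensional space of Cartesian
    partial-derivative coefficients; when more than m+1 basis directions
    are supplied, the least-squares solution is returned.  The reported
    residual is an independent pointwise check: the reconstructed kernel is
    compared against the target kernel on a sampled grid (using ``shape``
    for the underlying Gaussian; isotropic unit scale if omitted).
    """
    basis_angles = np.asarray(basis_angles, dtype=float)
    if order_m < 1:
        raise DegenerateBasisError(f"order must be >= 1, got {order_m}")
    if len(basis_angles) < order_m + 1:
        raise DegenerateBasisError(
            f"need at least m + 1 = {order_m + 1} basis directions, got "
            f"{len(basis_angles)}"
        )
    _check_angles_distinct(basis_angles)
    matrix = np.column_stack(
        [directional_basis_vector(order_m, a) for a in basis_angles]
    )
    condition = float(np.linalg.cond(matrix))
    if condition > CONDITION_LIMIT:
        raise DegenerateBasisError(
            f"steering system condition estimate {condition:.3g} exceeds "
            f"{CONDITION_LIMIT:.0e}: directions not sufficiently different"
        )
    target = directional_basis_vector(order_m, target_theta)
    if len(basis_angles) == order_m + 1:
        coeffs = np.linalg.solve(matrix, target)
    else:
        coeffs, *_ = np.linalg.lstsq(matrix, target, rcond=None)

    sigma1, sigma2, phi = shape if shape is not None else (1.0, 1.0, 0.0)
    half = 4.0 * max(sigma1, sigma2)
    axis = np.linspace(-half, half, residual_grid)
    x1, x2 = np.meshgrid(axis, axis, indexing="ij")
    pts = np.stack([x1, x2], axis=-1)

    def kernel_at(angle: float) -> np.ndarray:
        spec = RFSpec(sigma1, sigma2, phi, deriv_theta=angle, m1=order_m, m2=0)
        return general_directional_value(pts, spec)

    target_kernel = kernel_at(target_theta)
    recon = sum(c * kernel_at(a) for c, a in zip(coeffs, basis_angles))
    scale = float(np.max(np.abs(target_kernel)))
    residual = float(np.max(np.abs(recon - target_kernel))) / (scale or 1.0)
    return SteeringSolution(coeffs, basis_angles, residual, condition)


def match_responses(
    source_response: SampledField,
    target_responses: list[SampledField],
    map: AffineMap,
    order_m: int,
    *,
    basis_angles=None,
    margin: float | None = None,
) -> SteeringSolution:
    """Least-squares combination of warped target responses matching a
    source response.

    Each target response (computed at ``Sigma' = A Sigma A^T`` for some
    derivative direction) is pulled back through the map; the coefficients
    minimizing the interior residual against the source response are
    reported together with the relative RMS residual.
    """
    if len(target_responses) < order_m + 1:
        raise DegenerateBasisError(
            f"need at least m + 1 = {order_m + 1} target responses, got "
            f"{len(target_responses)}"
        )
    if basis_angles is not None:
        _check_angles_distinct(np.asarray(basis_angles, dtype=float))
    if margin is None:
        margin = 8.0 * source_response.spacing
    mask, _ = _interior_mask(source_response, map, margin, margin)
    if not mask.any():
        raise ConfigurationError("interior region is empty for this margin")
    pulled = [
        warp_image(resp, map.inverse()).values[mask] for resp in target_responses
    ]
    design = np.column_stack(pulled)
    norms = np.linalg.norm(design, axis=0)
    if np.any(norms == 0.0):
        raise DegenerateBasisError("a target response vanishes on the interior")
    condition = float(np.linalg.cond(design / norms))
    if condition > CONDITION_LIMIT:
        raise DegenerateBasisError(
            f"response basis condition estimate {condition:.3g} exceeds "
            f"{CONDITION_LIMIT:.0e}"
        )
    rhs = source_response.values[mask]
    coeffs, *_ = np.linalg.lstsq(design, rhs, rcond=None)
    resid = rhs - design @ coeffs
    denom = float(np.sqrt(np.mean(rhs * rhs))) or 1.0
    residual = float(np.sqrt(np.mean(resid * resid))) / denom
    angles = (
        np.asarray(basis_angles, dtype=float)
        if basis_angles is not None
        else np.full(len(target_responses), np.nan)
    )
    return SteeringSolution(coeffs, angles, residual, condition)


def cascade_smooth(response: SampledField, delta_cov) -> SampledField:
    """Advance an already-smoothed response from Sigma1 to Sigma2 by
    convolving with the Gaussian at ``delta = Sigma2 - Sigma1``.

    ``delta_cov`` may be a :class:`SpatialCovariance`, a 2x2 array, or zero
    (``None``, 0, or a zero matrix), in which case the response is returned
    unchanged.  A delta with any negative eigenvalue is infeasible: coarser
    representations can only be cascaded from strictly finer ones.
    """
    if delta_cov is None:
        return response
    if isinstance(delta_cov, SpatialCovariance):
        matrix = delta_cov.matrix
    else:
        matrix = np.asarray(delta_cov, dtype=float)
        if matrix.shape == ():
            matrix = float(matrix) * np.eye(2)
        if matrix.shape != (2, 2):
            raise CascadeInfeasibleError(
                f"delta covariance must be 2x2 or zero, got shape {matrix.shape}"
            )
    if np.all(matrix == 0.0):
        return response
    evals = np.linalg.eigvalsh(0.5 * (matrix + matrix.T))
    if evals[0] <= 0.0:
        raise CascadeInfeasibleError(
            f"delta covariance has non-positive eigenvalue {evals[0]:.6g}; "
            "cascade smoothing requires a positive definite increment"
        )
    return smooth(response, SpatialCovariance.from_matrix(matrix))
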