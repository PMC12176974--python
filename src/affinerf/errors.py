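"""Exception hierarchy.

All domain errors derive from :class:`AffineRFError` so callers can catch
one base class; specific subclasses name the contract that was violated.
"""


class AffineRFError(Exception):
    """Base class for all errors raised by affinerf."""


class InvalidInputError(AffineRFError, ValueError):
    """Non-finite or otherwise malformed numeric input."""


class DegenerateMapError(AffineRFError, ValueError):
    """P = 0: the map has no rotation/scaling component (e.g. pure skew)."""


class OutsideApplicabilityError(AffineRFError, ValueError):
    """The smaller singular value is non-positive; the closed-form
    decomposition only covers maps close to a positive multiple of the
    identity."""


class InvalidFactorsError(AffineRFError, ValueError):
    """Factor object violates its invariants (non-positive singular values)."""


class GrazingViewError(AffineRFError, ValueError):
    """Slant angle at or beyond 90 degrees."""


class InvalidGeometryError(AffineRFError, ValueError):
    """A denominator in the binocular disparity-gradient map vanishes."""


class InvalidShapeError(AffineRFError, ValueError):
    """Non-positive kernel scale parameters."""


class InvalidCovarianceError(AffineRFError, ValueError):
    """Covariance matrix is not symmetric positive definite."""


class OrderError(AffineRFError, ValueError):
    """Derivative order outside the closed-form range."""


class InvalidMapError(AffineRFError, ValueError):
    """Singular affine map where an invertible one is required."""


class ExtentError(AffineRFError, ValueError):
    """Grid extent too small for the requested kernel truncation."""


class CascadeInfeasibleError(AffineRFError, ValueError):
    """Covariance increment is not positive semi-definite."""


class DegenerateBasisError(AffineRFError, ValueError):
    """Steering basis directions are not sufficiently different."""


class ConfigurationError(AffineRFError, ValueError):
    """Inconsistent verification configuration (stretch, extent, margins)."""


class ParameterError(AffineRFError, ValueError):
    """Stimulus parameters would alias or violate size constraints."""
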