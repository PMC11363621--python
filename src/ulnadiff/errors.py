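"""Exception hierarchy for the measurement pipeline.

Every stage raises a subclass of :class:`UlnadiffError` so batch drivers can
catch pipeline failures without masking programming errors.
"""


class UlnadiffError(Exception):
    """Base class for all pipeline errors."""


class MeshIOError(UlnadiffError, IOError):
    """A mesh file could not be read or written."""


class MeshValidationError(UlnadiffError, ValueError):
    """A mesh violates a structural invariant (named in the message)."""


class DegenerateGeometryError(UlnadiffError, ValueError):
    """Geometry too degenerate for the requested operation (coincident
    landmarks, non-elongated mesh, ...)."""


class DegenerateFitError(UlnadiffError, ValueError):
    """Fit input is rank-deficient (e.g. collinear contour points)."""


class EmptySectionError(UlnadiffError, ValueError):
    """A cutting plane does not intersect the mesh."""


class MissingAdjudicationError(UlnadiffError, ValueError):
    """Observer discrepancy above threshold without an adjudicated value."""


class InsufficientDataError(UlnadiffError, ValueError):
    """Too few observations for the requested statistic."""
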