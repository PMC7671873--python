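"""Exception hierarchy used across the package.

All domain errors derive from :class:`OnhMorphError` so callers can catch a
single base class at pipeline boundaries while tests can assert on the
specific failure mode.
"""


class OnhMorphError(Exception):
    """Base class for all errors raised by this package."""


class SchemaError(OnhMorphError):
    """An interchange file violates the documented schema.

    The message names the offending field.
    """


class CompletenessError(OnhMorphError):
    """A radial set is missing B-scan indices (all 24 are required)."""


class GeometryError(OnhMorphError):
    """Coordinates violate a geometric invariant (ordering, finiteness)."""


class CoverageError(OnhMorphError):
    """A polyline does not span the lateral interval a metric requires."""


class QualityError(OnhMorphError):
    """A scan fails an acceptance rule (signal quality, masked fraction)."""


class DegenerateFitError(OnhMorphError):
    """Too few or collinear points for an ellipse fit."""


class FitError(OnhMorphError):
    """A conic fit did not yield an ellipse."""


class MeasurementError(OnhMorphError):
    """A geometric measurement could not be taken (e.g. no sheath crossing)."""


class AnalysisError(OnhMorphError):
    """A statistical routine received degenerate or insufficient input."""
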