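"""Exception hierarchy shared across the pipeline stages."""


class SharkhealError(Exception):
    """Base class for all package-specific errors."""


class InvalidGeometryError(SharkhealError):
    """Polygon is degenerate: <3 vertices, repeated points or self-intersecting."""


class DegenerateScaleError(SharkhealError):
    """Anchor marking has zero or negative area/perimeter and cannot scale."""


class AmbiguousDateError(SharkhealError):
    """Two annotations of the same injury share a sighting date."""


class InsufficientDataError(SharkhealError):
    """Not enough sightings/observations for the requested computation."""


class OrderingError(SharkhealError):
    """Day offsets are not strictly increasing / sorted as required."""


class DegenerateBaselineError(SharkhealError):
    """Day-0 normalized extent is zero; percent healed is undefined."""


class ClassificationUnavailableError(SharkhealError):
    """A quantitative severity rule needs a dorsal-fin reference that is missing."""


class FitFailureError(SharkhealError):
    """Nonlinear least squares failed to converge from every starting value."""


class UnreachableThresholdError(SharkhealError):
    """Requested closure threshold is at or above the fitted asymptote."""


class UndefinedR2Error(SharkhealError):
    """Null model likelihood degenerate; pseudo-r² denominator vanishes."""


class RangeError(SharkhealError):
    """A measurement lies outside its physically meaningful range."""


class ConfigError(SharkhealError):
    """A simulation or run configuration is infeasible."""
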