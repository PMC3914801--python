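"""Typed errors raised by the topography toolkit."""


class TopomapError(Exception):
    """Base class for all package errors."""


class InvalidInputError(TopomapError, ValueError):
    """Input data violates a basic validity requirement (non-finite, too few units...)."""


class ConfigurationError(TopomapError, ValueError):
    """Inconsistent or missing configuration (e.g. periodic labels without a period)."""


class DegenerateGeometryError(TopomapError, ValueError):
    """Unit positions are too degenerate for a Delaunay triangulation."""


class UndefinedMeasureError(TopomapError, ValueError):
    """A measure is mathematically undefined for this map (e.g. zero distance variance)."""


class DisconnectedGraphError(TopomapError, ValueError):
    """Geodesic distances requested on a disconnected neighbor graph."""


class FitFailureError(TopomapError, RuntimeError):
    """Tuning-curve fit did not converge."""


class OutOfRangeError(TopomapError, RuntimeError):
    """A searched quantity (e.g. N80) lies outside the allowed bracket."""
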