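"""Exception hierarchy shared by the analysis modules."""


class OrganoidMechError(Exception):
    """Base class for all package errors."""


class InvalidInputError(OrganoidMechError, ValueError):
    """Input data violates a precondition (bad shapes, signs, ranges)."""


class InvalidParameterError(OrganoidMechError, ValueError):
    """A model or algorithm parameter is outside its valid domain."""


class FitFailureError(OrganoidMechError, RuntimeError):
    """A nonlinear fit failed to converge; carries residual diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class DegenerateModelError(OrganoidMechError, ValueError):
    """A model limit in which a derived quantity is undefined."""


class GeometryError(OrganoidMechError, ValueError):
    """Degenerate or infeasible geometry (zero-length edges, overlaps)."""


class MinimizationError(OrganoidMechError, RuntimeError):
    """Energy minimization did not reach the requested tolerance."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class SegmentationError(OrganoidMechError, RuntimeError):
    """Automatic segmentation produced an empty or unusable mask."""


class DesignError(OrganoidMechError, ValueError):
    """A statistical design requirement is not met (e.g. unmatched scans)."""


class ConfigError(OrganoidMechError, ValueError):
    """A run configuration violates the schema."""
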