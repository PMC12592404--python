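"""Exception hierarchy shared across the pipeline."""


class MagestError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(MagestError):
    """A table or config file does not match the canonical schema."""


class ValidationError(MagestError):
    """A record or configuration value violates an invariant."""


class DegenerateDesignError(MagestError):
    """An estimation step received degenerate inputs (e.g. constant regressor)."""


class SolverError(MagestError):
    """Numerical solve failed to reach the requested tolerance."""

    def __init__(self, message: str, residuals=None):
        super().__init__(message)
        self.residuals = residuals


class InfeasibleTargetError(SolverError):
    """Requested moments cannot be attained by any member of the family."""
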