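"""Exception hierarchy.

Every error raised by this package derives from :class:`GalatrackError` so
callers (and the CLI) can distinguish validation problems (exit code 2) from
analysis/convergence failures (exit code 3).
"""


class GalatrackError(Exception):
    """Base class for all package errors."""


class ValidationError(GalatrackError):
    """A parameter, configuration value, or input violates its contract."""


class CodingError(ValidationError):
    """Unknown factor level passed to a contrast-coding scheme."""


class SchemaError(ValidationError):
    """A delimited-text file is missing required columns."""

    def __init__(self, missing, path=None):
        self.missing = list(missing)
        self.path = path
        where = f" in {path}" if path else ""
        super().__init__(f"missing required column(s){where}: {', '.join(self.missing)}")


class IntegrityError(ValidationError):
    """A log violates a structural invariant (e.g. non-monotone timestamps)."""


class AssemblyError(ValidationError):
    """The item inventory cannot support the session design."""


class PreprocessError(GalatrackError):
    """Trajectory regridding received unusable input."""


class ScreeningError(GalatrackError):
    """Screening received an empty or degenerate table."""


class SimulationError(GalatrackError):
    """An agent or dynamics component produced an out-of-range state."""


class AnalysisError(GalatrackError):
    """A statistical analysis is undefined on the given input."""


class ConvergenceError(AnalysisError):
    """No model on the simplification ladder converged."""

    def __init__(self, trail):
        self.trail = trail
        super().__init__(
            "no mixed model converged; simplification trail: "
            + " -> ".join(str(step) for step in trail)
        )
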