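"""Exception hierarchy for the autoreservoir package."""


class AutoReservoirError(Exception):
    """Base class for package errors."""


class ConfigError(AutoReservoirError, ValueError):
    """Invalid configuration value."""


class DimensionError(AutoReservoirError, ValueError):
    """Array shapes incompatible with the requested operation."""


class SimulationDivergedError(AutoReservoirError, RuntimeError):
    """Numerical integration produced a non-finite or unbounded state."""

    def __init__(self, step: int, message: str | None = None):
        self.step = step
        super().__init__(message or f"integration diverged at step {step}")


class SolvabilityError(AutoReservoirError, ValueError):
    """Problem dimensions violate the solvability requirement (feature dim > L)."""


class SelectionError(AutoReservoirError, ValueError):
    """Invalid variable-selection request."""


class DegenerateNormalizationError(AutoReservoirError, ValueError):
    """Normalization by the std of a constant segment is undefined."""
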