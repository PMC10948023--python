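"""Exception hierarchy."""


class RetstimError(Exception):
    """Base class for all package errors."""


class ConfigError(RetstimError):
    """Invalid configuration value or schema violation."""


class SWCParseError(RetstimError):
    """Malformed SWC content; carries the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class StructuralError(RetstimError):
    """Morphology graph is not a single connected tree."""


class SingularityError(RetstimError):
    """Evaluation point too close to a point-source electrode."""


class StateError(RetstimError):
    """Invalid dynamical state (e.g. non-positive calcium concentration)."""


class SolverDivergenceError(RetstimError):
    """Membrane potential left the plausibility bounds during integration."""

    def __init__(self, message: str, compartment: int | None = None,
                 time_ms: float | None = None):
        self.compartment = compartment
        self.time_ms = time_ms
        super().__init__(message)


class CalibrationError(RetstimError):
    """Synapse calibration failed tolerance; carries achieved values."""

    def __init__(self, message: str, achieved: dict | None = None):
        self.achieved = achieved or {}
        super().__init__(message)
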