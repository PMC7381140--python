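"""Exception hierarchy for coagsim."""


class CoagSimError(Exception):
    """Base class for all coagsim errors."""


class SchemaError(CoagSimError):
    """A parameter table, config file, or data file violates its schema."""


class ValidationError(CoagSimError):
    """A value or object violates a model invariant."""


class ConfigError(CoagSimError):
    """A run configuration is inconsistent or incomplete."""


class SolverError(CoagSimError):
    """The ODE solver failed; carries the last successful time if known."""

    def __init__(self, message: str, last_time: float | None = None):
        super().__init__(message)
        self.last_time = last_time
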