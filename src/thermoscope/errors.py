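"""Exception hierarchy for the thermoscope pipeline."""


class ThermoscopeError(Exception):
    """Base class for all pipeline errors."""


class SchemaError(ThermoscopeError):
    """An input table does not match the documented CSV contract."""


class ShortTraceError(ThermoscopeError):
    """A closed-phase trace is too short to survive edge trimming."""


class DegenerateFitError(ThermoscopeError):
    """A regression cannot be computed (e.g. all time points identical)."""


class NoLinearWindowError(ThermoscopeError):
    """No contiguous temperature range satisfies the linearity gates."""
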