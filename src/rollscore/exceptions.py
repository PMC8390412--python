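"""Exception hierarchy shared across the package."""


class RollscoreError(Exception):
    """Base class for all package errors."""


class InputError(RollscoreError, ValueError):
    """Invalid user-supplied data or parameters."""


class DegenerateInputError(InputError):
    """Input is structurally valid but degenerate for the requested operation."""


class SchemaError(InputError):
    """Tabular input does not match the expected schema."""


class ConvergenceError(RollscoreError, RuntimeError):
    """An iterative fit failed to converge.

    Carries the optimisation trace in ``trace`` when available.
    """

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace
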