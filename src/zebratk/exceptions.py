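"""Exception hierarchy for zebratk."""


class ZebraTKError(Exception):
    """Base class for all zebratk errors."""


class InvalidInputError(ZebraTKError, ValueError):
    """An argument violates a documented precondition."""


class DegenerateInputError(InvalidInputError):
    """Inputs are individually valid but jointly degenerate (e.g. division by zero)."""


class SchemaError(ZebraTKError, ValueError):
    """A tabular input or config file does not match the expected schema."""


class NumericalError(ZebraTKError, RuntimeError):
    """A numerical computation failed (singular system, overflow, ...)."""


class ConvergenceError(NumericalError):
    """An iterative procedure failed to converge within its budget."""
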