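"""Exception types shared across the package."""


class SeqblupError(Exception):
    """Base class for package-specific errors."""


class ConfigurationError(SeqblupError, ValueError):
    """Invalid user-supplied configuration or parameters."""


class DataError(SeqblupError, ValueError):
    """Input data violates a structural precondition."""


class ConvergenceError(SeqblupError, RuntimeError):
    """Iterative algorithm failed to produce a usable result."""
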