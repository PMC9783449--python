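"""Exception hierarchy used across the package."""


class IedmapError(Exception):
    """Base class for all package errors."""


class ParameterError(IedmapError, ValueError):
    """A user-supplied parameter violates an operation's precondition."""


class DomainError(IedmapError, ValueError):
    """Input data are outside the mathematical domain of an operation."""


class InferenceError(IedmapError, RuntimeError):
    """Model inference failed irrecoverably."""
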