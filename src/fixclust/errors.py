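"""Exception types shared across the package."""


class FixclustError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(FixclustError, ValueError):
    """A setting or geometry value is invalid (non-positive, non-divisor, ...)."""


class InputError(FixclustError, ValueError):
    """An input signal violates a precondition of the operation."""
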