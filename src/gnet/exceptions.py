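"""Exception types shared across the package."""


class GNetError(Exception):
    """Base class for package errors."""


class ShapeError(GNetError, ValueError):
    """An array has the wrong rank or incompatible dimensions."""


class ConfigurationError(GNetError, ValueError):
    """A configuration value is invalid or inconsistent."""


class DataError(GNetError, ValueError):
    """Input data violates a contract (labels out of range, unreadable file...)."""
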