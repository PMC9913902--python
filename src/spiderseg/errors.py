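"""Exception hierarchy shared across the package."""


class SpiderSegError(Exception):
    """Base class for all package errors."""


class ValidationError(SpiderSegError, ValueError):
    """A configuration object or argument violates a documented invariant."""


class DataError(SpiderSegError, ValueError):
    """Input data cannot be processed (empty foreground, shape mismatch, ...)."""


class EmptyForegroundError(DataError):
    """Binarization produced no foreground pixels (background-only image)."""
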