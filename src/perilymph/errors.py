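"""Exception hierarchy shared across the package."""


class PerilymphError(Exception):
    """Base class for all package errors."""


class ValidationError(PerilymphError, ValueError):
    """Raised when inputs violate a documented precondition."""
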