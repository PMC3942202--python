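"""Exception types raised across the package."""


class SrcLatLrrError(ValueError):
    """Base class for all package errors."""


class InvalidInputError(SrcLatLrrError):
    """Raised when data passed to an operation violates its preconditions
    (non-finite entries, shape mismatches, zero columns, bad files, ...)."""


class InvalidParameterError(SrcLatLrrError):
    """Raised when a tuning parameter is outside its valid range."""
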