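"""Typed exceptions shared across the package."""


class WhaledensError(Exception):
    """Base class for all package errors."""


class SchemaError(WhaledensError):
    """A required column or config key is missing or has the wrong type."""


class ValidationError(WhaledensError):
    """Input values violate a documented invariant (row-indexed where possible)."""


class FitError(WhaledensError):
    """A maximum-likelihood fit failed or produced degenerate estimates."""
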