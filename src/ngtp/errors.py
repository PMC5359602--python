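"""Exception hierarchy shared across the pipeline."""

from __future__ import annotations


class NgtpError(Exception):
    """Base class for all package errors."""


class ValidationError(NgtpError, ValueError):
    """A domain invariant was violated (negative N amount, bad fraction, ...)."""


class ConfigurationError(NgtpError, ValueError):
    """A configuration document is malformed (unknown key, non-numeric value)."""


class UndefinedSharesError(NgtpError, ZeroDivisionError):
    """Shares requested of a zero total."""
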