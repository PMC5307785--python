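"""Exception hierarchy shared across the package.

The CLI maps :class:`ConfigurationError` to exit code 2 and
:class:`DataError` to exit code 3.
"""


class PetResponseError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PetResponseError, ValueError):
    """An invalid parameter, option or configuration field."""


class DataError(PetResponseError, ValueError):
    """Input data that violates a precondition (wrong shape, degenerate, …)."""


class DegenerateImageWarning(UserWarning):
    """Raised when a constant raw image is normalized to all zeros."""
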