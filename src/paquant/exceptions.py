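"""Exception hierarchy. Validation errors map to CLI exit code 2,
numerical failures to exit code 3."""


class PAQuantError(Exception):
    """Base class for all package errors."""


class ValidationError(PAQuantError, ValueError):
    """Invalid user input or inconsistent data (CLI exit code 2)."""


class NumericalError(PAQuantError, RuntimeError):
    """A numerical procedure failed to converge or is singular (exit code 3)."""


class FormatError(ValidationError):
    """A file on disk does not match the expected on-disk format."""
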