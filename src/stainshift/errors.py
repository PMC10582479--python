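"""Exception taxonomy shared across the package.

The CLI maps these onto distinct exit codes (usage 2, I/O 3, validation 4,
configuration 5).
"""


class StainShiftError(Exception):
    """Base class for all package errors."""


class ParameterError(StainShiftError, ValueError):
    """Invalid user-supplied parameter (bad range, bad proportion, ...)."""


class ValidationError(StainShiftError, ValueError):
    """Runtime data fails a contract (shape mismatch, out-of-range values)."""


class FormatError(StainShiftError, ValueError):
    """A file on disk does not match the expected image/manifest format."""


class ConfigurationError(StainShiftError, ValueError):
    """Architecture/image-size combination is inconsistent."""
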