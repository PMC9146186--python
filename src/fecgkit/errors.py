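"""Exception hierarchy shared across the package."""


class FecgError(Exception):
    """Base class for all fecgkit errors."""


class FormatError(FecgError):
    """A file could not be parsed in the expected on-disk format."""


class UnsupportedFormatError(FormatError):
    """The file is recognized but uses a storage variant we do not read."""


class LengthError(FecgError, ValueError):
    """A signal is too short for the requested operation."""


class DegenerateSignalError(FecgError, ValueError):
    """The signal content makes the operation meaningless (e.g. mostly artifact)."""


class DegenerateInputError(FecgError, ValueError):
    """Numerically degenerate input, e.g. rank-deficient channel covariance."""


class InsufficientBeatsError(FecgError, ValueError):
    """Fewer heartbeats than the operation needs."""


class ExtractionError(FecgError):
    """End-to-end extraction failed; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}
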