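"""Exception hierarchy shared across the package."""


class MarkerQuantError(Exception):
    """Base class for all package-specific errors."""


class FormatError(MarkerQuantError, ValueError):
    """Malformed image or table data (bad headers, ragged frames, ...)."""


class ConfigurationError(MarkerQuantError, ValueError):
    """Inconsistent configuration (e.g. channel map vs. frame count)."""


class StateError(MarkerQuantError, RuntimeError):
    """Operation applied to an object in the wrong state (e.g. double rescale)."""


class ParseError(MarkerQuantError, ValueError):
    """Unparseable tabular input; carries the offending row number when known."""

    def __init__(self, message: str, row: int | None = None):
        super().__init__(message if row is None else f"row {row}: {message}")
        self.row = row


class SpecError(MarkerQuantError, ValueError):
    """Invalid synthetic-fixture specification."""
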