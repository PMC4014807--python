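"""Exception types raised by screen-table ingestion and analysis."""


class ScreenSiftError(Exception):
    """Base class for all package errors."""


class SchemaError(ScreenSiftError):
    """A mandatory column is missing or malformed."""


class IntegrityError(ScreenSiftError):
    """Records violate a table invariant (e.g. duplicate plate/well)."""


class LimitError(ScreenSiftError):
    """An input exceeds a documented size limit."""


class DegenerateDataError(ScreenSiftError):
    """A statistic is undefined on the given data (e.g. equal control means)."""
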