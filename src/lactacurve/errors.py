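"""Exception hierarchy shared across the package."""


class LactacurveError(Exception):
    """Base class for all package errors."""


class FormatError(LactacurveError):
    """An input table is structurally malformed (missing columns, bad dialect)."""


class RowError(LactacurveError):
    """One or more rows of an input table are invalid.

    Carries the offending line numbers (1-based, header included) in
    ``self.lines``.
    """

    def __init__(self, message: str, lines=()):
        super().__init__(message)
        self.lines = tuple(lines)


class InsufficientDataError(LactacurveError):
    """Too few observations for the requested computation."""


class LevelNotReachedError(LactacurveError):
    """A target lactate level has no rising crossing on the search interval."""


class UndefinedStatisticError(LactacurveError):
    """The statistic is undefined for this input (e.g. zero variance)."""


class ConfigError(LactacurveError):
    """Invalid configuration; ``self.fields`` lists the offending fields."""

    def __init__(self, message: str, fields=()):
        super().__init__(message)
        self.fields = tuple(fields)
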