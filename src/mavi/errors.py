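"""Exception hierarchy shared across the toolkit."""


class MaviError(Exception):
    """Base class for all toolkit errors."""


class ConfigError(MaviError):
    """Invalid configuration value or file."""


class DataError(MaviError):
    """Malformed, inconsistent, or insufficient input data."""


class UndefinedIndexError(MaviError):
    """An index value is undefined (e.g. a vanishing denominator).

    Raised instead of silently propagating NaN so that undefined cells
    are always an explicit, countable event.
    """


class UndefinedStatisticError(MaviError):
    """A statistic is undefined for the supplied values (e.g. zero mean
    in the DR denominator, zero variance in a correlation)."""
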