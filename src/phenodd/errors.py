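"""Exception hierarchy.

``ConfigError`` maps to CLI exit code 2, ``DataError`` subclasses to exit
code 3; everything else is a programming error and propagates.
"""


class PhenoddError(Exception):
    """Base class for all package errors."""


class ConfigError(PhenoddError):
    """Invalid run configuration (bad field, unresolvable path, bad scan)."""


class DataError(PhenoddError):
    """Problem with input data content."""


class FormatError(DataError):
    """A file does not conform to the expected dialect."""


class EmptyGridError(DataError):
    """A spatial selection covers no grid cells."""


class MissingDataError(DataError):
    """Required days, years or cells are absent from the data."""


class NoCommonYearsError(DataError):
    """Model and observations share no years to compare."""
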