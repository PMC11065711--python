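"""Exception hierarchy shared across the package.

Exit-code mapping used by the command line interface:
``DataError`` -> 2, ``ConfigError`` -> 3.
"""


class PopneError(Exception):
    """Base class for all package errors."""


class FormatError(PopneError):
    """A file does not conform to its declared text format (names the line)."""


class DataError(PopneError):
    """Input parses but violates a data contract (cycle, >2 alleles, ...)."""


class ConfigError(PopneError):
    """Invalid configuration or parameter combination."""


class UndefinedResult(PopneError):
    """A quantity is mathematically undefined for the given input."""
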