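"""Exception hierarchy.

Everything raised deliberately by this package derives from :class:`MrError`,
so callers (and the CLI) can distinguish analysis failures from bugs.
"""


class MrError(Exception):
    """Base class for all errors raised by mrmediate."""


class ConfigError(MrError, ValueError):
    """A configuration object or file is invalid; the message names the field."""


class FormatError(MrError, ValueError):
    """An input file does not conform to the documented tabular dialect."""


class DataError(MrError, ValueError):
    """The data are structurally valid but unusable for the requested operation
    (e.g. no shared SNPs, a SNP missing from the LD matrix, too few instruments)."""


class DomainError(MrError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class UsageError(MrError, TypeError):
    """The API was called with inconsistent arguments (e.g. mixed result types)."""
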