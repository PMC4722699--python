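"""Exception hierarchy.

Everything raised deliberately by the package derives from :class:`SdconsError`,
so callers (and the CLI) can catch one type and turn it into a diagnostic.
"""


class SdconsError(Exception):
    """Base class for all errors raised by sdcons."""


class ConfigurationError(SdconsError):
    """A parameter or option is outside the range an operation accepts."""


class ParseError(SdconsError):
    """An input file could not be parsed; the message names the offending line."""


class ValidationError(SdconsError):
    """Structurally parseable input violates a contract (duplicate ids, unknown ids...)."""


class DegenerateDistributionError(SdconsError):
    """All scores of a program are identical: the standard deviation is zero and
    z-scores are undefined."""


class UndefinedMetricError(SdconsError):
    """A metric has no defined value (e.g. corrected yield with zero actives)."""


class InfeasibleConsensusError(SdconsError):
    """The requested consensus size cannot be reached.

    Only molecules scored by *every* program can ever be consensus members, so
    ``max_achievable`` reports the hard ceiling on nCM for the given tables.
    """

    def __init__(self, message: str, max_achievable: int):
        super().__init__(message)
        self.max_achievable = max_achievable
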