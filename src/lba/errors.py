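"""Exception hierarchy for the lba package."""


class LbaError(Exception):
    """Base class for all lba-specific errors."""


class InvalidParameterError(LbaError, ValueError):
    """A parameter is outside its documented domain (e.g. |rho| > 1)."""


class InvalidInputError(LbaError, ValueError):
    """Input data violate a precondition (empty, non-finite, wrong shape)."""


class AlignmentError(LbaError, ValueError):
    """Row identifiers or lengths of two objects do not line up."""


class UndefinedStatisticError(LbaError, ArithmeticError):
    """A statistic is undefined for the given data (e.g. constant input to a correlation)."""


class InvalidComparisonError(LbaError, ValueError):
    """Two prediction results cannot be compared with the requested method."""
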