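"""Exception hierarchy for resistkit.

Contract violations (bad inputs to an operation) raise :class:`ContractError`;
statistical pathologies that make an estimate undefined or a fit impossible
get their own subclasses so callers can distinguish "your data are malformed"
from "your data cannot support this estimate".
"""


class ResistkitError(Exception):
    """Base class for all resistkit errors."""


class ContractError(ResistkitError):
    """An operation was called with inputs that violate its preconditions."""


class ParseError(ResistkitError):
    """A bioassay CSV could not be parsed; the message names the row."""


class RejectedAssayError(ResistkitError):
    """Control mortality at or above the rejection threshold (default 20%)."""


class NonConvergenceError(ResistkitError):
    """The maximum-likelihood fit did not converge."""


class SeparationError(NonConvergenceError):
    """Complete separation: mortality steps perfectly from 0 to 1, so the
    probit slope diverges and the MLE does not exist."""


class UnidentifiableSlopeError(ResistkitError):
    """All concentration groups show identical mortality; the slope is
    unidentifiable."""


class UndefinedStatisticError(ResistkitError):
    """A requested statistic is undefined for these inputs (zero degrees of
    freedom, zero denominator, expected mortality of exactly 0 or 1, ...)."""
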