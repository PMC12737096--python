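"""Exception hierarchy for gaitval.

All exceptions derive from :class:`GaitValError` so callers can catch the
package's failures with a single handler; each also subclasses the closest
builtin so generic code behaves sensibly.
"""


class GaitValError(Exception):
    """Base class for all gaitval errors."""


class ParseError(GaitValError, ValueError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(GaitValError, ValueError):
    """Input data violates a structural invariant (e.g. event interleaving)."""


class DomainError(GaitValError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class UndefinedResultError(GaitValError, ArithmeticError):
    """The requested statistic is undefined for this input (e.g. zero variance)."""
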