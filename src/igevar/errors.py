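"""Exception hierarchy.

All package errors derive from :class:`IgevarError` so callers can catch one
base class; each also derives from the closest builtin so generic handlers
(``ValueError`` for bad inputs, ``RuntimeError`` for bad state) keep working.
"""


class IgevarError(Exception):
    """Base class for all igevar errors."""


class InvalidParameterError(IgevarError, ValueError):
    """A model input (parameter, effect, weight) is non-finite or out of range."""


class ConfigError(IgevarError, ValueError):
    """Inconsistent simulation configuration (e.g. family design vs group count)."""


class StateError(IgevarError, RuntimeError):
    """An operation was called before its required state exists (e.g. weights)."""


class UndefinedStatisticError(IgevarError, ArithmeticError):
    """A statistic is undefined for the given data (zero variance, empty input)."""


class MatchingError(IgevarError, RuntimeError):
    """A feasible group assignment could not be found under the active policy."""


class ExtinctionError(IgevarError, RuntimeError):
    """A selection round left too few parents of one sex to continue."""
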