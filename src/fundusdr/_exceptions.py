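"""Exception hierarchy.

``ContractError`` marks violated preconditions (caller bugs);
``ConfigurationError`` marks missing/invalid configuration; the I/O and
domain-specific errors subclass the closest builtin so callers can catch
either way.
"""


class FundusError(Exception):
    """Base class for all package errors."""


class ContractError(FundusError, ValueError):
    """A documented precondition was violated."""


class ConfigurationError(FundusError, ValueError):
    """Missing or inconsistent configuration (e.g. an untrained model)."""


class ImageReadError(FundusError, IOError):
    """File could not be decoded as an image."""


class ImageSizeError(FundusError, ValueError):
    """Image below the minimum supported frame size."""


class NoFieldFound(FundusError, ValueError):
    """No circular field of view could be located in the photograph."""


class GenerationError(FundusError, RuntimeError):
    """Synthetic scene generation failed (e.g. lesion placement infeasible)."""

    def __init__(self, message: str, lesion_class: str | None = None):
        super().__init__(message)
        self.lesion_class = lesion_class


class UndefinedMetricError(FundusError, ZeroDivisionError):
    """A screening metric is undefined for the given table margins."""

    def __init__(self, metric: str, reason: str = ""):
        self.metric = metric
        super().__init__(f"metric '{metric}' undefined" + (f": {reason}" if reason else ""))


class InfiniteFError(FundusError, ArithmeticError):
    """Within-group mean square is zero; the F statistic is unbounded."""
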