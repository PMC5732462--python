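"""Exception hierarchy.

All package errors derive from :class:`PsabootError` so callers can catch
everything with one clause while still distinguishing data problems from
configuration problems and from feasibility exhaustion during resampling.
"""


class PsabootError(Exception):
    """Base class for all errors raised by psaboot."""


class DataError(PsabootError):
    """Invalid input data: non-positive times, unknown event labels, schema
    violations in IPD files."""


class UnfittableError(PsabootError):
    """A distribution cannot be fitted: too few observations, degenerate
    (all-identical) samples, or optimizer failure. The caller decides the
    fallback (e.g. suppress the event, reject the resample)."""


class NoModelError(PsabootError):
    """No model can be built at all, e.g. every event is below the scarce-
    event threshold or the record set is empty."""


class FeasibilityError(PsabootError):
    """Repeated resamples or multivariate-Normal draws failed the feasibility
    screen more than ``max_attempts`` times in a row."""

    def __init__(self, message: str, context: str | None = None):
        super().__init__(message)
        self.context = context


class ConfigurationError(PsabootError):
    """Inconsistent model/strategy configuration: missing parameter bindings,
    unknown states, invalid economic parameter specifications."""


class EstimationError(PsabootError):
    """A density or divergence estimate cannot be formed (too few values,
    zero variance)."""
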