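"""Exception and warning types shared across the package."""

from __future__ import annotations


class CompactMixError(Exception):
    """Base class for all package-specific errors."""


class InvalidMeasurementError(CompactMixError, ValueError):
    """A tablet measurement field is non-positive or otherwise unusable."""


class InsufficientDataError(CompactMixError, ValueError):
    """Too few usable points to fit a compactibility profile."""


class FitFailureError(CompactMixError, RuntimeError):
    """Nonlinear fit did not converge.

    Carries the log-linear fallback estimate so callers can inspect or
    accept it explicitly.
    """

    def __init__(self, message: str, fallback=None):
        super().__init__(message)
        self.fallback = fallback


class CompositionError(CompactMixError, ValueError):
    """Invalid mixture composition (lengths, signs, normalization)."""


class ConfigurationError(CompactMixError, ValueError):
    """Invalid model/variant selection or missing profile."""


class EvaluationError(CompactMixError, ValueError):
    """Invalid measured/predicted data for accuracy evaluation."""


class ExtrapolationWarning(UserWarning):
    """A profile is evaluated outside the porosity range it was fitted on."""


class InconsistentMeasurementWarning(UserWarning):
    """Computed solid fraction exceeds 1 (porosity <= 0): inputs disagree."""
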