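"""Exception and warning hierarchy shared across the pipeline.

Every error raised by lichendry derives from :class:`LichenDryError`; the
``stage`` attribute is filled in by composite operations (e.g. full isotherm
elaboration) so callers can tell which step of a chained analysis failed.
"""

from __future__ import annotations


class LichenDryError(Exception):
    """Base class for all lichendry errors."""

    def __init__(self, message: str, *, stage: str | None = None):
        super().__init__(message)
        self.stage = stage


class InvalidInputError(LichenDryError, ValueError):
    """Arguments violate a precondition (non-positive dry weight, too few points, ...)."""


class InvalidReadingError(InvalidInputError):
    """A physically impossible instrument reading, e.g. Fm < F0."""


class UnusableRecordError(LichenDryError):
    """An isotherm record that cannot be elaborated (e.g. every point inside the
    apoplastic exclusion band)."""


class FitFailureError(LichenDryError):
    """A least-squares fit did not converge or is otherwise unusable."""


class InconsistentFitsError(FitFailureError):
    """Turgor pressure already non-positive at zero water loss: the exponential
    water-potential model and the osmotic line contradict each other."""


class NoTurgorLossError(FitFailureError):
    """No turgor-pressure sign change found on the scanned water-loss range."""


class RankDeficientError(FitFailureError):
    """Regression design matrix is rank deficient."""


class UndefinedStatisticError(LichenDryError):
    """A statistic is undefined for the given data (e.g. R^2 with zero variance)."""


class CoverageError(LichenDryError):
    """The paired drying series does not cover the acoustic recording span."""


class PairingError(LichenDryError):
    """An acoustic trace has no resolvable twin drying sample."""


class NoEmissionsError(LichenDryError):
    """Every monitored sample was silent: no emissions to locate."""


# --------------------------------------------------------------------------
# warnings


class LichenDryWarning(UserWarning):
    """Base class for all lichendry warnings."""


class FitQualityWarning(LichenDryWarning):
    """A fit passed but missed a quality gate (e.g. adjusted R^2 below 0.96)."""


class MonotonicityWarning(LichenDryWarning):
    """Fresh weight increased along the drying order beyond measurement noise."""


class NoBreakWarning(LichenDryWarning):
    """Segmented fit found no evidence of a breakpoint (single-slope data)."""


class BoundaryBreakWarning(LichenDryWarning):
    """Breakpoint estimate pinned at the edge of the candidate range."""


class WideCIWarning(LichenDryWarning):
    """Profile likelihood nearly flat: the confidence interval is uninformative."""


class SilentSampleWarning(LichenDryWarning):
    """A monitored sample produced no acoustic hits."""


class DegenerateDataWarning(LichenDryWarning):
    """Input data degenerate for the requested model (e.g. constant response)."""
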