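"""PSII maximum quantum yield and its decline along the water-potential axis.

Dark-adapted chlorophyll a fluorescence gives the steady-state (F0) and
maximum (Fm) signals, from which the maximum quantum yield of PSII is
``Fv/Fm = (Fm - F0)/Fm``. During desiccation Fv/Fm holds a plateau and then
declines as the water potential drops. Two characterizations are provided:

* a Weibull-type sigmoidal response ``Fv/Fm = fmax * exp(-(|psi|/b)^c)``,
  the standard form used for vulnerability-curve fitting, with a seeded
  bootstrap pointwise confidence band;
* a two-segment (breakpoint) regression on the raw (psi, Fv/Fm) points,
  whose break marks the onset of the significant Fv/Fm decline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from . import stats_core
from .errors import (
    DegenerateDataWarning,
    FitFailureError,
    InvalidInputError,
    InvalidReadingError,
)

__all__ = [
    "FluorescencePair",
    "FvFmCurve",
    "SigmoidFit",
    "compute_fvfm",
    "fit_fvfm_sigmoid",
    "locate_fvfm_breakpoint",
]


@dataclass(frozen=True)
class FluorescencePair:
    """A dark-adapted (F0, Fm) reading in arbitrary fluorescence units."""

    f0: float
    fm: float

    def __post_init__(self):
        if self.f0 < 0:
            raise InvalidInputError("F0 must be non-negative")


@dataclass(frozen=True)
class FvFmCurve:
    """Pooled (psi, Fv/Fm) points for one species, with per-point sample ids."""

    psi: np.ndarray  # MPa, <= 0
    fvfm: np.ndarray  # dimensionless, in [0, 1)
    sample_ids: tuple[str, ...]

    def __post_init__(self):
        psi = np.asarray(self.psi, dtype=float)
        fvfm = np.asarray(self.fvfm, dtype=float)
        object.__setattr__(self, "psi", psi)
        object.__setattr__(self, "fvfm", fvfm)
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        if not (psi.shape == fvfm.shape and len(self.sample_ids) == psi.size):
            raise InvalidInputError("psi, fvfm and sample_ids must have equal length")
        if np.any((fvfm < 0) | (fvfm >= 1)):
            raise InvalidInputError("Fv/Fm values must lie in [0, 1)")

    def __len__(self) -> int:
        return self.psi.size


def _sigmoid(abs_psi, fmax, b, c):
    with np.errstate(over="ignore"):
        return fmax * np.exp(-((abs_psi / b) ** c))


@dataclass(frozen=True)
class SigmoidFit:
    """Weibull-type decline ``fvfm = fmax * exp(-(|psi|/b)^c)``."""

    fmax: float  # plateau, in (0, 1)
    b: float  # MPa scale
    c: float  # shape
    ci_band: tuple[np.ndarray, np.ndarray, np.ndarray] | None  # (psi grid, lower, upper)
    flags: tuple[str, ...] = ()

    def predict(self, psi) -> np.ndarray:
        return _sigmoid(np.abs(np.asarray(psi, dtype=float)), self.fmax, self.b, self.c)


def compute_fvfm(pair: FluorescencePair) -> float:
    """``(Fm - F0)/Fm``, the PSII maximum quantum yield."""
    if pair.fm <= 0:
        raise InvalidInputError("Fm must be positive")
    if pair.fm < pair.f0:
        raise InvalidReadingError(f"Fm ({pair.fm}) below F0 ({pair.f0}): invalid reading")
    return (pair.fm - pair.f0) / pair.fm


def fit_fvfm_sigmoid(
    curve: FvFmCurve,
    *,
    n_boot: int = 1000,
    seed: int = stats_core.DEFAULT_SEED,
    ci_level: float = 0.95,
    n_band: int = 60,
) -> SigmoidFit:
    """Least-squares fit of the sigmoidal Fv/Fm response to water potential.

    The pointwise confidence band is a seeded pairs bootstrap (``n_boot``
    resamples, percentile interval). A response with no variance is returned
    as a flat fit flagged ``"flat"`` with a :class:`DegenerateDataWarning`
    rather than an error.
    """
    if len(curve) < 6:
        raise InvalidInputError("sigmoid fit needs at least 6 points")
    abs_psi = np.abs(curve.psi)
    y = curve.fvfm
    if float(np.std(y)) < 1e-12:
        warnings.warn("constant Fv/Fm response: shape parameter unidentifiable", DegenerateDataWarning, stacklevel=2)
        return SigmoidFit(fmax=float(np.mean(y)), b=np.inf, c=1.0, ci_band=None, flags=("flat",))

    p0 = _sigmoid_start(abs_psi, y)
    try:
        popt, _ = curve_fit(
            _sigmoid,
            abs_psi,
            y,
            p0=p0,
            bounds=([1e-6, 1e-6, 1e-3], [1.0, np.inf, 50.0]),
            maxfev=40000,
        )
    except (RuntimeError, ValueError) as exc:
        raise FitFailureError(f"sigmoidal Fv/Fm model did not converge: {exc}") from exc

    grid = np.linspace(curve.psi.min(), curve.psi.max(), n_band)
    rng = np.random.default_rng(seed)
    boot = np.empty((n_boot, n_band))
    n_ok = 0
    for _ in range(n_boot):
        idx = rng.integers(0, len(curve), len(curve))
        try:
            pb, _ = curve_fit(
                _sigmoid,
                abs_psi[idx],
                y[idx],
                p0=popt,
                bounds=([1e-6, 1e-6, 1e-3], [1.0, np.inf, 50.0]),
                maxfev=5000,
            )
        except (RuntimeError, ValueError):
            continue
        boot[n_ok] = _sigmoid(np.abs(grid), *pb)
        n_ok += 1
    if n_ok > 0:
        alpha = (1.0 - ci_level) / 2.0
        lower = np.quantile(boot[:n_ok], alpha, axis=0)
        upper = np.quantile(boot[:n_ok], 1.0 - alpha, axis=0)
        band = (grid, lower, upper)
    else:
        band = None
    return SigmoidFit(fmax=float(popt[0]), b=float(popt[1]), c=float(popt[2]), ci_band=band)


def _sigmoid_start(abs_psi: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    fmax0 = min(float(np.max(y)), 0.999)
    # b is |psi| where the response has fallen to fmax/e
    target = fmax0 / np.e
    order = np.argsort(abs_psi)
    xo, yo = abs_psi[order], y[order]
    below = np.flatnonzero(yo <= target)
    b0 = float(xo[below[0]]) if below.size else float(np.median(abs_psi))
    return (fmax0, max(b0, 1e-3), 3.0)


def locate_fvfm_breakpoint(curve: FvFmCurve, *, ci_level: float = 0.95) -> stats_core.BreakpointFit:
    """Onset of the significant Fv/Fm decline.

    Delegates to the two-segment linear regression on the raw (psi, Fv/Fm)
    points pooled across samples; the returned breakpoint is in MPa with its
    delta-method standard error and confidence interval.
    """
    if len(curve) < 8:
        raise InvalidInputError("breakpoint detection needs at least 8 points")
    return stats_core.fit_segmented_linear(curve.psi, curve.fvfm, ci_level=ci_level)
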