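"""Pressure-volume isotherm elaboration for desiccating thalli.

A drying run yields an ordered sequence of (water potential, fresh weight)
measurements plus a final dry weight. Elaboration proceeds in four steps:

1. points inside the apoplastic exclusion band (by default water potentials
   above -0.30 MPa) are dropped, and the first retained fresh weight defines
   the initial fresh weight (IFW) from which water loss ``WL_i = IFW - FW_i``
   is counted;
2. an exponential growth model ``|psi| = a * exp(b * WL)`` is fitted over the
   retained points;
3. the last five points (highest water loss, past turgor loss) give the
   linear relationship between 1/psi and WL, which is read as the
   1/(osmotic potential) line;
4. a fine sweep over water loss evaluates turgor ``P_T = psi - pi`` from the
   two fitted relations and the first sign change locates the turgor loss
   point; the corresponding water potential is psi_tlp, from which fresh
   weight and relative water content at turgor loss follow arithmetically.

Water potentials are negative throughout (MPa); weights are mg; relative
water content is expressed on a dry-mass basis in percent and may exceed 100.

The module also houses the van't Hoff osmometer-calibration utility for the
0.5 mol/kg KCl dewpoint-hygrometer standard.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from . import stats_core
from .errors import (
    FitFailureError,
    FitQualityWarning,
    InconsistentFitsError,
    InvalidInputError,
    LichenDryError,
    MonotonicityWarning,
    NoTurgorLossError,
    UndefinedStatisticError,
    UnusableRecordError,
)

#: gas constant in L MPa mol^-1 K^-1 (molality-based van't Hoff form)
GAS_CONSTANT_L_MPA = 0.0083145

#: default apoplastic exclusion band: water potentials in (lo, hi] are dropped
DEFAULT_EXCLUSION = (-0.30, 0.0)

__all__ = [
    "IsothermPoint",
    "IsothermRecord",
    "ExponentialFit",
    "InverseLineFit",
    "WaterRelationParams",
    "CalibrationSolution",
    "compute_rwc",
    "determine_ifw_and_wl",
    "fit_psi_exponential",
    "fit_inverse_psi_line",
    "derive_turgor_loss",
    "elaborate_isotherm",
    "kcl_reference_psi",
    "GAS_CONSTANT_L_MPA",
    "DEFAULT_EXCLUSION",
]


# --------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class IsothermPoint:
    """One measurement during a drying run."""

    time: float  # minutes since drying start
    psi: float  # water potential, MPa (<= 0 expected)
    fw: float  # fresh weight, mg
    f0: float | None = None  # steady-state fluorescence, a.u.
    fm: float | None = None  # maximum fluorescence, a.u.

    def __post_init__(self):
        if not np.isfinite(self.psi):
            raise InvalidInputError("water potential must be finite")
        if self.fw <= 0:
            raise InvalidInputError("fresh weight must be positive")


@dataclass(frozen=True)
class IsothermRecord:
    """One sample's ordered isotherm measurements plus its dry weight."""

    sample_id: str
    species: str
    points: tuple[IsothermPoint, ...]
    dw: float  # dry weight, mg

    def __post_init__(self):
        object.__setattr__(self, "points", tuple(self.points))
        if self.dw <= 0:
            raise InvalidInputError("dry weight must be positive")
        if self.points:
            min_fw = min(p.fw for p in self.points)
            if self.dw > 1.02 * min_fw:
                warnings.warn(
                    f"dry weight {self.dw:.1f} mg exceeds minimum fresh weight "
                    f"{min_fw:.1f} mg beyond measurement noise",
                    MonotonicityWarning,
                    stacklevel=3,
                )


@dataclass(frozen=True)
class ExponentialFit:
    """``|psi|(WL) = a * exp(b * WL)`` with its adjusted R^2."""

    a: float  # MPa
    b: float  # per mg
    adj_r2: float

    def predict_psi(self, wl) -> np.ndarray:
        return -self.a * np.exp(self.b * np.asarray(wl, dtype=float))


@dataclass(frozen=True)
class InverseLineFit:
    """OLS line of 1/psi on WL over the post-turgor-loss tail: the 1/pi line."""

    slope: float  # 1/(MPa mg)
    intercept: float  # 1/MPa
    n_points: int = 5

    def predict_pi(self, wl) -> np.ndarray:
        return 1.0 / (self.slope * np.asarray(wl, dtype=float) + self.intercept)


@dataclass(frozen=True)
class WaterRelationParams:
    """Derived water-relation quantities for one sample."""

    ifw: float  # mg
    wl_tlp: float  # mg
    fw_tlp: float  # mg
    psi_tlp: float  # MPa
    rwc_tlp: float  # % of dry mass
    exp_fit: ExponentialFit
    osmotic_line: InverseLineFit

    def __post_init__(self):
        if not 0 < self.fw_tlp < self.ifw:
            raise InvalidInputError("fresh weight at turgor loss must lie in (0, IFW)")


@dataclass(frozen=True)
class CalibrationSolution:
    """An osmometer calibration standard described by van't Hoff quantities."""

    molality: float  # mol/kg
    nu: int  # ions per formula unit
    phi: float  # osmotic coefficient
    temperature: float  # K

    def __post_init__(self):
        if self.molality < 0 or self.phi <= 0 or self.temperature <= 0:
            raise InvalidInputError("calibration solution parameters must be positive")
        if int(self.nu) != self.nu or self.nu < 1:
            raise InvalidInputError("nu must be an integer >= 1")

    @classmethod
    def kcl_standard(cls) -> "CalibrationSolution":
        """The 0.5 mol/kg KCl dewpoint-hygrometer standard (phi = 0.900, 293.15 K)."""
        return cls(molality=0.5, nu=2, phi=0.900, temperature=293.15)


# --------------------------------------------------------------------------
# operations


def compute_rwc(fw, dw) -> float | np.ndarray:
    """Relative water content on a dry-mass basis: ``(FW - DW)/DW * 100`` (%).

    Can exceed 100 for hydrated thalli. Accepts scalars or arrays.
    """
    fw = np.asarray(fw, dtype=float)
    dw = np.asarray(dw, dtype=float)
    if np.any(dw <= 0):
        raise InvalidInputError("dry weight must be positive")
    if np.any(fw < 0):
        raise InvalidInputError("fresh weight must be non-negative")
    out = (fw - dw) / dw * 100.0
    return float(out) if out.ndim == 0 else out


def determine_ifw_and_wl(
    record: IsothermRecord,
    exclusion: tuple[float, float] = DEFAULT_EXCLUSION,
) -> tuple[float, np.ndarray, tuple[IsothermPoint, ...]]:
    """Apply the apoplastic exclusion band and compute water loss.

    Points with water potential above ``exclusion[0]`` (default -0.30 MPa,
    the band where dewpoint readings are unreliable and apoplastic water
    still dominates) are dropped; -0.30 itself is retained. The first
    retained fresh weight is the initial fresh weight (IFW), and water loss
    is ``WL_i = IFW - FW_i`` for every retained point.

    Returns ``(ifw, wl, retained_points)``. Raises
    :class:`UnusableRecordError` when every point falls inside the band;
    fresh weight increasing beyond 1% of IFW raises a
    :class:`MonotonicityWarning` but the points are kept.
    """
    lo, _hi = exclusion
    retained = tuple(p for p in record.points if p.psi <= lo)
    if not retained:
        raise UnusableRecordError(
            f"no point at or below {lo} MPa: record {record.sample_id!r} unusable"
        )
    ifw = retained[0].fw
    fw = np.array([p.fw for p in retained])
    wl = ifw - fw
    increases = np.diff(fw)
    if np.any(increases > 0.01 * ifw):
        warnings.warn(
            f"fresh weight increases along drying order beyond 1% of IFW "
            f"in record {record.sample_id!r}; points kept",
            MonotonicityWarning,
            stacklevel=2,
        )
    return float(ifw), wl, retained


def fit_psi_exponential(wl, psi, *, qc_adj_r2: float = 0.96) -> ExponentialFit:
    """Least-squares fit of the exponential growth model ``|psi| = a exp(b WL)``.

    A fit whose adjusted R^2 falls below ``qc_adj_r2`` is flagged with a
    :class:`FitQualityWarning` but not rejected.
    """
    wl = np.asarray(wl, dtype=float)
    psi = np.asarray(psi, dtype=float)
    if wl.size < 3:
        raise InvalidInputError("exponential fit needs at least 3 points")
    if np.any(psi >= 0):
        raise InvalidInputError("exponential fit requires strictly negative water potentials")
    y = np.abs(psi)
    # log-linear starting values
    b0, loga0 = np.polyfit(wl, np.log(y), 1)
    p0 = (float(np.exp(loga0)), float(max(b0, 0.0)))
    try:
        popt, _ = curve_fit(
            lambda w, a, b: a * np.exp(b * w),
            wl,
            y,
            p0=p0,
            bounds=([1e-12, 0.0], [np.inf, np.inf]),
            maxfev=20000,
        )
    except (RuntimeError, ValueError) as exc:
        raise FitFailureError(f"exponential growth model did not converge: {exc}") from exc
    a, b = float(popt[0]), float(popt[1])
    y_hat = a * np.exp(b * wl)
    try:
        adj = stats_core.adjusted_r2(y, y_hat, 2)
    except (UndefinedStatisticError, InvalidInputError):
        # constant response or minimal n: report 1 for a (near-)perfect fit,
        # leave the statistic undefined otherwise
        adj = 1.0 if float(np.max(np.abs(y - y_hat))) < 1e-8 * (1 + y.mean()) else np.nan
    if np.isfinite(adj) and adj < qc_adj_r2:
        warnings.warn(
            f"exponential fit adjusted R^2 = {adj:.3f} below QC gate {qc_adj_r2}",
            FitQualityWarning,
            stacklevel=2,
        )
    return ExponentialFit(a=a, b=b, adj_r2=float(adj))


def fit_inverse_psi_line(wl, psi, n_tail: int = 5) -> InverseLineFit:
    """OLS of 1/psi on WL over the ``n_tail`` points of highest water loss.

    Past turgor loss the reciprocal of water potential is linear in water
    loss, so this tail line is the 1/pi-versus-WL relationship. Ties in WL
    are broken toward the latest measurement (last position in drying
    order).
    """
    wl = np.asarray(wl, dtype=float)
    psi = np.asarray(psi, dtype=float)
    if wl.size < n_tail:
        raise InvalidInputError(f"inverse-psi line needs at least n_tail={n_tail} points")
    order = np.argsort(wl, kind="stable")
    tail = order[-n_tail:]
    if np.any(psi[tail] >= 0):
        raise InvalidInputError("tail water potentials must be strictly negative")
    slope, intercept = np.polyfit(wl[tail], 1.0 / psi[tail], 1)
    line = InverseLineFit(slope=float(slope), intercept=float(intercept), n_points=n_tail)
    pred = line.slope * wl[tail] + line.intercept
    if np.any(pred >= 0):
        warnings.warn(
            "fitted 1/pi line predicts non-negative values over the tail range",
            FitQualityWarning,
            stacklevel=2,
        )
    return line


def derive_turgor_loss(
    exp_fit: ExponentialFit,
    osmotic_line: InverseLineFit,
    ifw: float,
    dw: float,
    wl_max: float,
    *,
    n_grid: int = 10_000,
) -> WaterRelationParams:
    """Sweep water loss until turgor pressure reaches zero.

    On a uniform grid of ``n_grid`` steps over ``[0, wl_max]`` the two fitted
    relations give ``psi(WL) = -a exp(b WL)`` and ``pi(WL) = 1/(slope WL +
    intercept)``; turgor is ``P_T = psi - pi``. The first grid step where
    ``P_T <= 0`` is refined by linear interpolation between the bracketing
    steps and taken as the turgor loss point. Grid points past the pole of
    the 1/pi line (where predicted pi turns non-negative) are outside the
    line's validity and excluded from the scan.
    """
    if wl_max <= 0:
        raise InvalidInputError("wl_max must be positive")
    if dw <= 0:
        raise InvalidInputError("dry weight must be positive")
    wl = np.linspace(0.0, wl_max, n_grid + 1)
    denom = osmotic_line.slope * wl + osmotic_line.intercept
    valid = denom < 0
    if not valid[0]:
        raise InconsistentFitsError("1/pi line predicts non-negative pi at zero water loss")
    if not valid.all():
        stop = int(np.argmin(valid))  # first invalid index
        wl, denom = wl[:stop], denom[:stop]
    psi = exp_fit.predict_psi(wl)
    pi = 1.0 / denom
    pt = psi - pi
    if pt[0] <= 0:
        raise InconsistentFitsError(
            "turgor pressure non-positive already at zero water loss; "
            "exponential and osmotic fits are inconsistent"
        )
    crossing = np.flatnonzero(pt <= 0)
    if crossing.size == 0:
        raise NoTurgorLossError(
            f"no turgor-pressure sign change up to WL = {wl[-1]:.3f} mg"
        )
    i = int(crossing[0])
    frac = pt[i - 1] / (pt[i - 1] - pt[i])
    wl_tlp = float(wl[i - 1] + frac * (wl[i] - wl[i - 1]))
    psi_tlp = float(exp_fit.predict_psi(wl_tlp))
    fw_tlp = ifw - wl_tlp
    return WaterRelationParams(
        ifw=float(ifw),
        wl_tlp=wl_tlp,
        fw_tlp=float(fw_tlp),
        psi_tlp=psi_tlp,
        rwc_tlp=float(compute_rwc(fw_tlp, dw)),
        exp_fit=exp_fit,
        osmotic_line=osmotic_line,
    )


def elaborate_isotherm(
    record: IsothermRecord,
    *,
    exclusion: tuple[float, float] = DEFAULT_EXCLUSION,
    n_tail: int = 5,
    qc_adj_r2: float = 0.96,
    n_grid: int = 10_000,
) -> WaterRelationParams:
    """Full isotherm elaboration: exclusion, exponential fit, osmotic line,
    turgor-loss sweep.

    The sweep extends 5% past the largest observed water loss. Errors from
    individual stages propagate with their ``stage`` attribute set to one of
    ``"exclusion"``, ``"exp_fit"``, ``"osmotic_line"``, ``"turgor_loss"``.
    """

    def _staged(stage: str, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except LichenDryError as exc:
            exc.stage = stage
            raise

    ifw, wl, retained = _staged("exclusion", determine_ifw_and_wl, record, exclusion)
    if len(retained) < max(n_tail + 3, 8):
        raise UnusableRecordError(
            f"record {record.sample_id!r} has {len(retained)} points after exclusion; "
            f"need at least {max(n_tail + 3, 8)}",
            stage="exclusion",
        )
    psi = np.array([p.psi for p in retained])
    exp_fit = _staged("exp_fit", fit_psi_exponential, wl, psi, qc_adj_r2=qc_adj_r2)
    line = _staged("osmotic_line", fit_inverse_psi_line, wl, psi, n_tail)
    wl_max = 1.05 * float(wl.max())
    return _staged(
        "turgor_loss", derive_turgor_loss, exp_fit, line, ifw, record.dw, wl_max, n_grid=n_grid
    )


def kcl_reference_psi(solution: CalibrationSolution) -> float:
    """Molality-based van't Hoff osmotic potential of a calibration solution.

    ``psi = -phi * nu * m * R * T`` in MPa with R = 0.0083145 L MPa / (mol K).
    The 0.5 mol/kg KCl standard evaluates to -2.19 MPa.
    """
    return float(
        -solution.phi * solution.nu * solution.molality * GAS_CONSTANT_L_MPA * solution.temperature
    )
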