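"""Shared statistical machinery.

This module implements the regression tools the desiccation analyses lean on:

* a continuous two-segment ("broken-stick") linear model estimated by the
  iterative gap-variable linearization, with a delta-method standard error for
  the breakpoint, plus an exhaustive grid-search oracle used for verification;
* a Gaussian random-intercept mixed model fitted by REML, with the variance
  components profiled down to a one-dimensional search over the
  between/within variance ratio;
* a two-segment fixed-effect trend inside the random-intercept model, with a
  profile-likelihood confidence interval for the breakpoint;
* cubic polynomial regression with a pointwise confidence band;
* adjusted R^2.

All stochastic routines take an explicit seed; the module default is
``DEFAULT_SEED``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .errors import (
    BoundaryBreakWarning,
    InvalidInputError,
    NoBreakWarning,
    RankDeficientError,
    UndefinedStatisticError,
    WideCIWarning,
)

DEFAULT_SEED = 20240724

__all__ = [
    "BreakpointFit",
    "RandomInterceptFit",
    "PolynomialFit",
    "fit_segmented_linear",
    "segmented_oracle_grid",
    "fit_random_intercept",
    "fit_segmented_mixed",
    "fit_polynomial_cubic",
    "adjusted_r2",
    "DEFAULT_SEED",
]


# --------------------------------------------------------------------------
# result containers


@dataclass(frozen=True)
class BreakpointFit:
    """A continuous two-segment linear fit.

    The fitted function is ``y = intercept_left + slope_left * x`` for
    ``x <= breakpoint`` and continues with ``slope_right`` beyond it; the
    right-hand intercept is implied by continuity.
    """

    slope_left: float
    slope_right: float
    intercept_left: float
    breakpoint: float
    se_breakpoint: float
    ci_low: float
    ci_high: float
    rss: float
    flags: tuple[str, ...] = ()

    @property
    def intercept_right(self) -> float:
        return self.intercept_left + (self.slope_left - self.slope_right) * self.breakpoint

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        left = self.intercept_left + self.slope_left * x
        right = self.intercept_right + self.slope_right * x
        return np.where(x <= self.breakpoint, left, right)


@dataclass(frozen=True)
class RandomInterceptFit:
    """REML fit of ``y = b0 + b1 x + u_group + e`` with Gaussian components."""

    fixed_intercept: float
    fixed_slope: float
    sigma_between: float
    sigma_within: float
    per_group_intercepts: dict
    loglik: float
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class PolynomialFit:
    """Degree-3 polynomial regression on the original predictor scale."""

    coefficients: tuple[float, float, float, float]  # ascending powers
    ci_band: tuple[np.ndarray, np.ndarray, np.ndarray]  # (x grid, lower, upper)
    r2: float

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return np.polynomial.polynomial.polyval(x, np.asarray(self.coefficients))


# --------------------------------------------------------------------------
# helpers


def _as_xy(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or x.shape != y.shape:
        raise InvalidInputError("x and y must be equal-length 1-D sequences")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise InvalidInputError("x and y must be finite")
    return x, y


def _ols(X: np.ndarray, y: np.ndarray):
    """Least squares with coefficient covariance; returns (beta, rss, cov)."""
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    n, p = X.shape
    if rank < p or n <= p:
        return beta, rss, None
    sigma2 = rss / (n - p)
    cov = sigma2 * np.linalg.inv(X.T @ X)
    return beta, rss, cov


def _segment_design(x: np.ndarray, c: float) -> np.ndarray:
    return np.column_stack([np.ones_like(x), x, np.maximum(x - c, 0.0)])


def _segment_fit_at(x: np.ndarray, y: np.ndarray, c: float):
    X = _segment_design(x, c)
    return _ols(X, y)


def _check_segmented_input(x: np.ndarray, y: np.ndarray) -> None:
    if x.size < 6:
        raise InvalidInputError("segmented fit needs at least 6 points")
    if np.unique(x).size < 6:
        raise InvalidInputError(
            "segmented fit needs >= 3 distinct x values on each side of a candidate break"
        )


def _candidate_range(x: np.ndarray, trim: float = 0.05) -> tuple[float, float]:
    lo = float(np.quantile(x, trim))
    hi = float(np.quantile(x, 1.0 - trim))
    if not lo < hi:
        raise InvalidInputError("x range too narrow for a candidate breakpoint lattice")
    return lo, hi


# --------------------------------------------------------------------------
# two-segment linear model


def fit_segmented_linear(
    x,
    y,
    *,
    max_iter: int = 50,
    tol: float = 1e-6,
    ci_level: float = 0.95,
) -> BreakpointFit:
    """Continuous two-segment linear regression by iterative linearization.

    Starting from a break at the median of ``x``, each iteration fits
    ``y ~ 1 + x + (x - c)_+ + gap`` where the extra "gap" regressor is the
    negative right-side indicator; the ratio of the gap coefficient to the
    slope change updates the break. Iteration stops when the break moves less
    than ``tol * range(x)``. The breakpoint standard error comes from the
    delta method on the (gap, slope-change) coefficients, and the CI is the
    usual Wald interval.

    The gap-variable iteration can stall in a local RSS minimum, so the
    converged estimate is checked against the exhaustive grid oracle: when
    the oracle attains a lower RSS, the iteration restarts from the
    oracle's break (flag ``"grid_restart"``); if it then fails to improve,
    the oracle's estimate itself is kept (flag ``"fallback_grid"``). A
    break with an uninformative (near-flat) slope change triggers
    :class:`NoBreakWarning` and a wide CI.
    """
    x, y = _as_xy(x, y)
    _check_segmented_input(x, y)
    rng_x = float(np.ptp(x))
    lo, hi = _candidate_range(x)
    z = stats.norm.ppf(0.5 + ci_level / 2.0)

    flags: list[str] = []
    c, converged, hit_boundary = _gap_iterate(x, y, float(np.median(x)), lo, hi, max_iter, tol * rng_x)
    rss_c = _segment_fit_at(x, y, c)[1] if converged else np.inf

    oracle = segmented_oracle_grid(x, y, ci_level=ci_level)
    if oracle.rss < rss_c * (1.0 - 1e-9) - 1e-12:
        # local minimum (or no convergence): restart from the global lattice optimum
        c2, conv2, hb2 = _gap_iterate(x, y, oracle.breakpoint, lo, hi, max_iter, tol * rng_x)
        rss_c2 = _segment_fit_at(x, y, c2)[1] if conv2 else np.inf
        if conv2 and rss_c2 <= oracle.rss * (1.0 + 1e-9) + 1e-12:
            c, converged, hit_boundary = c2, True, hb2
            flags.append("grid_restart")
        else:
            c, converged, hit_boundary = oracle.breakpoint, True, "boundary" in oracle.flags
            flags.append("fallback_grid")
            if not conv2:
                warnings.warn(
                    "segmented iteration did not converge; using grid-search estimate",
                    NoBreakWarning,
                    stacklevel=2,
                )

    # delta-method pieces refitted at the final break
    U = np.maximum(x - c, 0.0)
    V = -(x > c).astype(float)
    X4 = np.column_stack([np.ones_like(x), x, U, V])
    beta4, _, cov4 = _ols(X4, y)
    se_c = _breakpoint_se(float(beta4[3]), float(beta4[2]), cov4)
    beta3, rss, _ = _segment_fit_at(x, y, c)
    ci_low, ci_high = c - z * se_c, c + z * se_c

    if hit_boundary or c <= lo or c >= hi:
        warnings.warn("breakpoint estimate pinned at candidate boundary", BoundaryBreakWarning, stacklevel=2)
        flags.append("boundary")
    if not np.isfinite(se_c) or z * se_c > 0.5 * rng_x:
        warnings.warn("no clear breakpoint: confidence interval spans most of x", NoBreakWarning, stacklevel=2)
        flags.append("no_break")

    return BreakpointFit(
        slope_left=float(beta3[1]),
        slope_right=float(beta3[1] + beta3[2]),
        intercept_left=float(beta3[0]),
        breakpoint=float(c),
        se_breakpoint=float(se_c),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        rss=float(rss),
        flags=tuple(flags),
    )


def _gap_iterate(
    x: np.ndarray,
    y: np.ndarray,
    c0: float,
    lo: float,
    hi: float,
    max_iter: int,
    tol_abs: float,
) -> tuple[float, bool, bool]:
    """Gap-variable update loop; returns (break, converged, hit_boundary)."""
    c = min(max(c0, lo), hi)
    hit_boundary = False
    for _ in range(max_iter):
        U = np.maximum(x - c, 0.0)
        V = -(x > c).astype(float)
        X4 = np.column_stack([np.ones_like(x), x, U, V])
        beta4, _, _ = _ols(X4, y)
        gamma, b2 = float(beta4[3]), float(beta4[2])
        if abs(b2) < 1e-12 * (1.0 + abs(gamma)):
            return c, False, hit_boundary
        c_new = c + gamma / b2
        if c_new < lo or c_new > hi:
            c_new = min(max(c_new, lo), hi)
            hit_boundary = True
        if abs(c_new - c) < tol_abs:
            return c_new, True, hit_boundary
        c = c_new
    return c, False, hit_boundary


def _breakpoint_se(gamma: float, b2: float, cov4) -> float:
    if cov4 is None or abs(b2) < 1e-300:
        return np.inf
    r = gamma / b2
    var = (cov4[3, 3] + r * r * cov4[2, 2] - 2.0 * r * cov4[3, 2]) / (b2 * b2)
    return float(np.sqrt(max(var, 0.0)))


def segmented_oracle_grid(x, y, n_grid: int = 201, *, ci_level: float = 0.95) -> BreakpointFit:
    """Exhaustive verification oracle for the two-segment model.

    Evaluates every candidate break on an ``n_grid`` lattice over the central
    90% of ``x``, fits the continuous two-segment model by least squares at
    each, and returns the RSS-minimizing candidate (ties broken toward the
    smallest x). Slower but assumption-free; used to cross-check the
    iterative estimator.
    """
    x, y = _as_xy(x, y)
    _check_segmented_input(x, y)
    lo, hi = _candidate_range(x)
    candidates = np.linspace(lo, hi, n_grid)
    rss_all = np.full(n_grid, np.inf)
    for i, c in enumerate(candidates):
        X = _segment_design(x, c)
        if np.linalg.matrix_rank(X) < 3:
            continue
        _, rss, _ = _ols(X, y)
        rss_all[i] = rss
    best = int(np.argmin(rss_all))  # first minimum -> smallest x among ties
    c = float(candidates[best])
    beta3, rss, _ = _segment_fit_at(x, y, c)
    # delta-method se at the oracle break, for comparability with the
    # iterative estimator
    U = np.maximum(x - c, 0.0)
    V = -(x > c).astype(float)
    X4 = np.column_stack([np.ones_like(x), x, U, V])
    beta4, _, cov4 = _ols(X4, y)
    se_c = _breakpoint_se(float(beta4[3]), float(beta4[2]), cov4)
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    return BreakpointFit(
        slope_left=float(beta3[1]),
        slope_right=float(beta3[1] + beta3[2]),
        intercept_left=float(beta3[0]),
        breakpoint=c,
        se_breakpoint=float(se_c),
        ci_low=float(c - z * se_c),
        ci_high=float(c + z * se_c),
        rss=float(rss),
        flags=("oracle",),
    )


# --------------------------------------------------------------------------
# random-intercept REML machinery


def _group_indices(groups) -> tuple[list, list[np.ndarray]]:
    groups = np.asarray(groups)
    labels = list(dict.fromkeys(groups.tolist()))  # preserve first-seen order
    idx = [np.flatnonzero(groups == g) for g in labels]
    return labels, idx


def _profile_reml(X: np.ndarray, y: np.ndarray, idx: list[np.ndarray]):
    """Profile REML for a random-intercept model with arbitrary fixed design.

    The between/within variance ratio ``lam = sigma_b^2 / sigma_w^2`` is the
    only free parameter; beta and sigma_w^2 have closed forms given lam
    thanks to the compound-symmetry structure of each group's covariance.

    Returns ``(lam, beta, sigma_w2, loglik_reml, blups)``.
    """
    n, p = X.shape
    sizes = np.array([len(ix) for ix in idx], dtype=float)

    def neg2_reml(lam: float):
        A = np.zeros((p, p))
        bvec = np.zeros(p)
        for ix, ni in zip(idx, sizes):
            Xi, yi = X[ix], y[ix]
            ci = lam / (1.0 + ni * lam)
            sx = Xi.sum(axis=0)
            sy = yi.sum()
            A += Xi.T @ Xi - ci * np.outer(sx, sx)
            bvec += Xi.T @ yi - ci * sx * sy
        try:
            beta = np.linalg.solve(A, bvec)
        except np.linalg.LinAlgError:
            return np.inf, None, None, None
        rss_w = 0.0
        for ix, ni in zip(idx, sizes):
            ri = y[ix] - X[ix] @ beta
            ci = lam / (1.0 + ni * lam)
            sr = ri.sum()
            rss_w += ri @ ri - ci * sr * sr
        sigma_w2 = max(rss_w / (n - p), 1e-300)
        sign, logdet_a = np.linalg.slogdet(A)
        if sign <= 0:
            return np.inf, None, None, None
        crit = (
            (n - p) * (np.log(2.0 * np.pi * sigma_w2) + 1.0)
            + float(np.sum(np.log1p(sizes * lam)))
            + logdet_a
        )
        return crit, beta, sigma_w2, A

    # optimize over log-lambda, also checking the lam = 0 boundary
    def obj(u: float) -> float:
        return neg2_reml(np.exp(u))[0]

    res = optimize.minimize_scalar(obj, bounds=(-14.0, 14.0), method="bounded")
    lam = float(np.exp(res.x))
    crit0 = neg2_reml(0.0)[0]
    if crit0 <= res.fun:
        lam = 0.0
    crit, beta, sigma_w2, _ = neg2_reml(lam)
    blups = {}
    for ix, ni in zip(idx, sizes):
        ri = y[ix] - X[ix] @ beta
        blups_val = (ni * lam / (1.0 + ni * lam)) * float(ri.mean()) if lam > 0 else 0.0
        blups[len(blups)] = blups_val
    return lam, beta, sigma_w2, -0.5 * crit, blups


def fit_random_intercept(x, y, groups) -> RandomInterceptFit:
    """REML fit of a linear trend with a Gaussian random intercept per group.

    ``y = b0 + b1 x + u_group + e`` with ``u ~ N(0, sigma_b^2)`` i.i.d. per
    group and ``e ~ N(0, sigma_w^2)``. Variance components are found by
    one-dimensional profile optimization of the REML criterion over the
    variance ratio. A boundary solution ``sigma_b = 0`` is returned with a
    ``"singular"`` flag rather than raised.
    """
    x, y = _as_xy(x, y)
    labels, idx = _group_indices(groups)
    if len(labels) < 2:
        raise InvalidInputError("random-intercept fit needs at least 2 groups")
    if min(len(ix) for ix in idx) < 3:
        raise InvalidInputError("random-intercept fit needs at least 3 points per group")

    X = np.column_stack([np.ones_like(x), x])
    lam, beta, sigma_w2, loglik, blups_by_pos = _profile_reml(X, y, idx)
    flags: list[str] = []
    if lam == 0.0:
        flags.append("singular")
    sigma_w = float(np.sqrt(sigma_w2))
    sigma_b = float(np.sqrt(lam * sigma_w2))
    per_group = {g: float(blups_by_pos[i]) for i, g in enumerate(labels)}
    return RandomInterceptFit(
        fixed_intercept=float(beta[0]),
        fixed_slope=float(beta[1]),
        sigma_between=sigma_b,
        sigma_within=sigma_w,
        per_group_intercepts=per_group,
        loglik=float(loglik),
        flags=tuple(flags),
    )


def fit_segmented_mixed(
    x,
    y,
    groups,
    *,
    n_grid: int = 41,
    ci_level: float = 0.95,
    refine: bool = True,
) -> BreakpointFit:
    """Two-segment fixed-effect trend with a random intercept per group.

    The breakpoint is profiled on a candidate lattice over the central 90% of
    ``x``; at each candidate the random-intercept model with two-segment
    fixed effects is fitted by profile REML, and the restricted-likelihood
    maximizer wins (after one local grid refinement). The confidence interval
    inverts the profile likelihood-ratio at the chi-square(1) threshold for
    ``ci_level``; its half-width also provides the reported (approximate)
    standard error.
    """
    x, y = _as_xy(x, y)
    _check_segmented_input(x, y)
    labels, idx = _group_indices(groups)
    if len(labels) < 2:
        raise InvalidInputError("segmented mixed fit needs at least 2 groups")

    lo, hi = _candidate_range(x)

    def profile_at(c: float):
        X = np.column_stack([np.ones_like(x), x, np.maximum(x - c, 0.0)])
        return _profile_reml(X, y, idx)

    cand = np.linspace(lo, hi, n_grid)
    ll = np.array([profile_at(c)[3] for c in cand])
    best = int(np.argmax(ll))
    c_best = float(cand[best])
    if refine:
        step = cand[1] - cand[0]
        fine = np.linspace(max(lo, c_best - step), min(hi, c_best + step), n_grid)
        ll_fine = np.array([profile_at(c)[3] for c in fine])
        j = int(np.argmax(ll_fine))
        if ll_fine[j] >= ll[best]:
            c_best = float(fine[j])
        cand = np.concatenate([cand, fine])
        ll = np.concatenate([ll, ll_fine])
        order = np.argsort(cand)
        cand, ll = cand[order], ll[order]

    lam, beta, sigma_w2, ll_max, blups = profile_at(c_best)

    flags: list[str] = []
    thresh = ll_max - 0.5 * stats.chi2.ppf(ci_level, 1)
    ci_low, ci_high = _invert_profile(cand, ll, c_best, thresh)
    if np.ptp(ll[np.isfinite(ll)]) < 0.5:
        warnings.warn("profile restricted likelihood nearly flat; CI is uninformative", WideCIWarning, stacklevel=2)
        flags.append("wide_ci")
    if c_best <= lo + 1e-12 or c_best >= hi - 1e-12:
        warnings.warn("breakpoint estimate pinned at candidate boundary", BoundaryBreakWarning, stacklevel=2)
        flags.append("boundary")

    # residual sum of squares about fixed effects + BLUPs
    X = np.column_stack([np.ones_like(x), x, np.maximum(x - c_best, 0.0)])
    u = np.zeros_like(y)
    for i, ix in enumerate(idx):
        u[ix] = blups[i]
    resid = y - X @ beta - u
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    return BreakpointFit(
        slope_left=float(beta[1]),
        slope_right=float(beta[1] + beta[2]),
        intercept_left=float(beta[0]),
        breakpoint=c_best,
        se_breakpoint=float((ci_high - ci_low) / (2.0 * z)),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        rss=float(resid @ resid),
        flags=tuple(flags),
    )


def _invert_profile(cand: np.ndarray, ll: np.ndarray, c_best: float, thresh: float):
    """Linear-interpolation inversion of a profile log-likelihood at ``thresh``."""
    ok = np.isfinite(ll)
    cand, ll = cand[ok], ll[ok]
    below = ll < thresh
    left = cand[0]
    right = cand[-1]
    # walk left from the best candidate
    i_best = int(np.argmin(np.abs(cand - c_best)))
    for i in range(i_best, 0, -1):
        if below[i - 1] and not below[i]:
            f = (ll[i] - thresh) / (ll[i] - ll[i - 1])
            left = cand[i] - f * (cand[i] - cand[i - 1])
            break
    for i in range(i_best, len(cand) - 1):
        if below[i + 1] and not below[i]:
            f = (ll[i] - thresh) / (ll[i] - ll[i + 1])
            right = cand[i] + f * (cand[i + 1] - cand[i])
            break
    return float(left), float(right)


# --------------------------------------------------------------------------
# cubic polynomial and adjusted R^2


def fit_polynomial_cubic(x, y, *, ci_level: float = 0.95, n_band: int = 100) -> PolynomialFit:
    """Ordinary least squares on the degree-3 polynomial basis.

    The predictor is centered and scaled internally for conditioning; the
    returned coefficients are on the original scale, in ascending powers.
    The pointwise confidence band comes from the coefficient covariance.
    """
    x, y = _as_xy(x, y)
    if np.unique(x).size < 5:
        raise InvalidInputError("cubic fit needs at least 5 distinct x values")
    mu = float(x.mean())
    s = float(x.std())
    z_x = (x - mu) / s
    X = np.column_stack([np.ones_like(z_x), z_x, z_x**2, z_x**3])
    rank = np.linalg.matrix_rank(X)
    if rank < 4:
        raise RankDeficientError(
            f"cubic basis (1, z, z^2, z^3) is rank deficient (rank {rank}) on these x values"
        )
    beta_z, rss, cov_z = _ols(X, y)

    # compose with the affine map z = (x - mu)/s to get original-scale coefficients
    shift = np.array([-mu / s, 1.0 / s])
    P = np.polynomial.polynomial
    coef = np.zeros(4)
    for k in range(4):
        coef_k = beta_z[k] * P.polypow(shift, k) if k else np.array([beta_z[0]])
        coef[: len(coef_k)] += coef_k

    grid = np.linspace(x.min(), x.max(), n_band)
    Gz = (grid - mu) / s
    G = np.column_stack([np.ones_like(Gz), Gz, Gz**2, Gz**3])
    fit_g = G @ beta_z
    if cov_z is not None:
        var_g = np.einsum("ij,jk,ik->i", G, cov_z, G)
    else:
        var_g = np.zeros_like(fit_g)
    zq = stats.norm.ppf(0.5 + ci_level / 2.0)
    band = (grid, fit_g - zq * np.sqrt(var_g), fit_g + zq * np.sqrt(var_g))

    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / ss_tot if ss_tot > 0 else 1.0
    return PolynomialFit(coefficients=tuple(float(c) for c in coef), ci_band=band, r2=float(r2))


def adjusted_r2(y, y_hat, n_params: int) -> float:
    """Adjusted coefficient of determination,
    ``1 - (1 - R^2) (n - 1) / (n - n_params - 1)``."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    n = y.size
    if n <= n_params + 1:
        raise InvalidInputError("adjusted R^2 needs n > n_params + 1")
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0.0:
        raise UndefinedStatisticError("total variance is zero; R^2 undefined")
    ss_res = float(((y - y_hat) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot
    return 1.0 - (1.0 - r2) * (n - 1) / (n - n_params - 1)
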