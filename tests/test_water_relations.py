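"""Tests for the pressure-volume isotherm elaboration and osmometry utility."""

import numpy as np
import pytest

from lichendry.errors import (
    FitQualityWarning,
    InconsistentFitsError,
    InvalidInputError,
    MonotonicityWarning,
    NoTurgorLossError,
    UnusableRecordError,
)
from lichendry.synthetic_data import PVTruth, gen_pv_isotherm
from lichendry.water_relations import (
    CalibrationSolution,
    ExponentialFit,
    InverseLineFit,
    IsothermPoint,
    IsothermRecord,
    compute_rwc,
    derive_turgor_loss,
    determine_ifw_and_wl,
    elaborate_isotherm,
    fit_inverse_psi_line,
    fit_psi_exponential,
    kcl_reference_psi,
)


def _record(psi, fw, dw=50.0, times=None):
    times = times if times is not None else 30.0 * np.arange(len(psi))
    pts = tuple(IsothermPoint(time=t, psi=p, fw=f) for t, p, f in zip(times, psi, fw))
    return IsothermRecord(sample_id="s1", species="sp", points=pts, dw=dw)


class TestComputeRwc:
    @pytest.mark.parametrize(
        "fw,dw,expected",
        [(50.0, 50.0, 0.0), (100.0, 50.0, 100.0), (133.5, 50.0, 167.0)],
    )
    def test_dry_mass_basis(self, fw, dw, expected):
        assert compute_rwc(fw, dw) == pytest.approx(expected)

    def test_invalid_dry_weight(self):
        with pytest.raises(InvalidInputError):
            compute_rwc(10.0, 0.0)


class TestDetermineIfwAndWl:
    def test_exclusion_band_drops_high_psi(self):
        ifw, wl, retained = determine_ifw_and_wl(
            _record([-0.1, -0.5, -2.0], [120.0, 110.0, 95.0])
        )
        assert ifw == 110.0
        np.testing.assert_allclose(wl, [0.0, 15.0])
        assert len(retained) == 2

    def test_nothing_excluded_when_all_below_band(self):
        ifw, wl, _ = determine_ifw_and_wl(_record([-0.5, -1.0], [100.0, 90.0]))
        assert ifw == 100.0
        np.testing.assert_allclose(wl, [0.0, 10.0])

    def test_all_points_in_band_unusable(self):
        with pytest.raises(UnusableRecordError):
            determine_ifw_and_wl(_record([-0.05, -0.2], [100.0, 99.0]))

    def test_boundary_value_retained(self):
        ifw, wl, _ = determine_ifw_and_wl(_record([-0.30, -1.0], [100.0, 90.0]))
        assert ifw == 100.0

    def test_non_monotone_fw_warns_but_keeps(self):
        with pytest.warns(MonotonicityWarning):
            _, wl, retained = determine_ifw_and_wl(
                _record([-0.5, -1.0, -2.0], [100.0, 103.0, 90.0])
            )
        assert len(retained) == 3


class TestFitPsiExponential:
    def test_noiseless_self_consistency(self):
        wl = np.linspace(0, 30, 12)
        psi = -0.4 * np.exp(0.05 * wl)
        fit = fit_psi_exponential(wl, psi)
        assert fit.a == pytest.approx(0.4, rel=1e-6)
        assert fit.b == pytest.approx(0.05, rel=1e-6)
        assert fit.adj_r2 == pytest.approx(1.0, abs=1e-9)

    def test_flat_degenerate_limit(self):
        fit = fit_psi_exponential([0.0, 10.0, 20.0], [-1.0, -1.0, -1.0])
        assert fit.a == pytest.approx(1.0, abs=1e-6)
        assert fit.b == pytest.approx(0.0, abs=1e-6)

    def test_noisy_fit_matches_grid_search_oracle(self):
        rng = np.random.default_rng(11)
        a_true, b_true = 0.5, 0.08
        wl = np.linspace(0, 30, 12)
        psi = -(a_true * np.exp(b_true * wl)) + rng.normal(0, 0.05, 12)
        psi = np.minimum(psi, -1e-3)
        fit = fit_psi_exponential(wl, psi)
        assert fit.a == pytest.approx(a_true, rel=0.10)
        assert fit.b == pytest.approx(b_true, rel=0.10)
        # independent coarse grid search over (a, b) minimizing SSE
        aa = np.linspace(0.7 * a_true, 1.3 * a_true, 121)
        bb = np.linspace(0.7 * b_true, 1.3 * b_true, 121)
        y = np.abs(psi)
        sse = np.array(
            [[((y - a * np.exp(b * wl)) ** 2).sum() for b in bb] for a in aa]
        )
        i, j = np.unravel_index(np.argmin(sse), sse.shape)
        sse_fit = ((y - fit.a * np.exp(fit.b * wl)) ** 2).sum()
        assert sse_fit <= sse[i, j] + 1e-9
        assert fit.a == pytest.approx(aa[i], rel=0.02)
        assert fit.b == pytest.approx(bb[j], rel=0.02)

    def test_low_quality_fit_warns(self, rng):
        wl = np.linspace(0, 30, 15)
        psi = -(0.5 * np.exp(0.05 * wl)) + rng.normal(0, 0.6, 15)
        psi = np.minimum(psi, -1e-3)
        with pytest.warns(FitQualityWarning):
            fit_psi_exponential(wl, psi)

    def test_positive_psi_rejected(self):
        with pytest.raises(InvalidInputError):
            fit_psi_exponential([0, 1, 2], [-1.0, 0.1, -2.0])


class TestFitInversePsiLine:
    def test_exact_tail_line(self):
        wl = np.linspace(10, 30, 5)
        inv = -0.02 * wl - 0.10
        fit = fit_inverse_psi_line(wl, 1.0 / inv)
        assert fit.slope == pytest.approx(-0.02, rel=1e-9)
        assert fit.intercept == pytest.approx(-0.10, rel=1e-9)

    def test_only_tail_used(self):
        wl = np.concatenate([[0.0, 5.0], np.linspace(10, 30, 5)])
        inv = -0.02 * wl - 0.10
        psi = 1.0 / inv
        psi[:2] = [-0.4, -0.6]  # off-line points outside the tail
        fit = fit_inverse_psi_line(wl, psi)
        assert fit.slope == pytest.approx(-0.02, rel=1e-9)
        assert fit.intercept == pytest.approx(-0.10, rel=1e-9)

    def test_matches_closed_form_ols(self, rng):
        wl = np.linspace(5, 25, 5)
        psi = -1.0 / (0.05 + 0.01 * wl) + rng.normal(0, 0.05, 5)
        fit = fit_inverse_psi_line(wl, psi)
        y = 1.0 / psi
        sxx = ((wl - wl.mean()) ** 2).sum()
        slope = ((wl - wl.mean()) * (y - y.mean())).sum() / sxx
        intercept = y.mean() - slope * wl.mean()
        assert fit.slope == pytest.approx(slope, rel=1e-10)
        assert fit.intercept == pytest.approx(intercept, rel=1e-10)

    def test_too_few_points(self):
        with pytest.raises(InvalidInputError):
            fit_inverse_psi_line([1, 2, 3], [-1, -2, -3])


class TestDeriveTurgorLoss:
    # construct fits whose turgor crossing sits exactly at WL = 12:
    # 1/pi line gives pi(12) = 1/(0.01*12 - 0.5); a chosen so psi(12) = pi(12)
    LINE = InverseLineFit(slope=0.01, intercept=-0.5)
    A = 0.3
    B = float(np.log((1.0 / (0.5 - 0.12)) / 0.3) / 12.0)

    def test_arithmetic_of_printed_formulas(self):
        exp_fit = ExponentialFit(a=self.A, b=self.B, adj_r2=1.0)
        p = derive_turgor_loss(exp_fit, self.LINE, ifw=100.0, dw=40.0, wl_max=20.0)
        assert p.wl_tlp == pytest.approx(12.0, abs=1e-3)
        assert p.fw_tlp == pytest.approx(88.0, abs=1e-3)
        assert p.rwc_tlp == pytest.approx(120.0, abs=1e-2)
        assert p.fw_tlp == p.ifw - p.wl_tlp  # bit-exact identity

    def test_grid_convergence(self):
        exp_fit = ExponentialFit(a=self.A, b=self.B, adj_r2=1.0)
        p1 = derive_turgor_loss(exp_fit, self.LINE, 100.0, 40.0, 20.0, n_grid=10_000)
        p2 = derive_turgor_loss(exp_fit, self.LINE, 100.0, 40.0, 20.0, n_grid=20_000)
        assert abs(p1.psi_tlp - p2.psi_tlp) < 1e-4

    def test_inconsistent_fits_rejected(self):
        # psi already below pi at zero water loss
        exp_fit = ExponentialFit(a=5.0, b=0.01, adj_r2=1.0)
        with pytest.raises(InconsistentFitsError):
            derive_turgor_loss(exp_fit, self.LINE, 100.0, 40.0, 20.0)

    def test_no_sign_change_raises(self):
        exp_fit = ExponentialFit(a=self.A, b=self.B, adj_r2=1.0)
        with pytest.raises(NoTurgorLossError):
            derive_turgor_loss(exp_fit, self.LINE, 100.0, 40.0, wl_max=5.0)


class TestElaborateIsotherm:
    def test_noiseless_recovery_across_parameter_grid(self):
        for pi0 in (-1.0, -2.0, -4.0):
            for eps in (4.0, 8.0, 16.0):
                record, truth = gen_pv_isotherm(PVTruth(pi0=pi0, epsilon=eps), seed=1)
                p = elaborate_isotherm(record)
                assert abs(p.psi_tlp) == pytest.approx(abs(truth.psi_tlp_true), rel=0.02)

    def test_internal_consistency_identities(self):
        record, _ = gen_pv_isotherm(PVTruth(sigma_psi=0.1), seed=3)
        p = elaborate_isotherm(record)
        assert p.fw_tlp == p.ifw - p.wl_tlp
        assert p.rwc_tlp == (p.fw_tlp - record.dw) / record.dw * 100.0
        assert 0 < p.fw_tlp < p.ifw

    def test_time_rescaling_invariance(self):
        record, _ = gen_pv_isotherm(PVTruth(), seed=4)
        from dataclasses import replace

        scaled = replace(
            record, points=tuple(replace(pt, time=7.0 * pt.time) for pt in record.points)
        )
        assert elaborate_isotherm(record) == elaborate_isotherm(scaled)

    def test_exclusion_failure_carries_stage(self):
        record = _record([-0.05, -0.1, -0.2], [100.0, 99.0, 98.0])
        with pytest.raises(UnusableRecordError) as exc:
            elaborate_isotherm(record)
        assert exc.value.stage == "exclusion"

    def test_agrees_with_finer_bruteforce_scan(self):
        """The interpolated crossing must sit within one coarse grid step of a
        10x finer brute-force sign-change scan."""
        record, _ = gen_pv_isotherm(PVTruth(sigma_psi=0.15), seed=9)
        p_coarse = elaborate_isotherm(record, n_grid=1000)
        p_fine = elaborate_isotherm(record, n_grid=10_000)
        wl_max = 1.05 * p_fine.wl_tlp / 0.9  # generous bound on the scanned range
        coarse_step = wl_max / 1000
        assert abs(p_coarse.wl_tlp - p_fine.wl_tlp) <= coarse_step


class TestKclReference:
    def test_pure_water(self):
        sol = CalibrationSolution(molality=0.0, nu=2, phi=0.9, temperature=293.15)
        assert kcl_reference_psi(sol) == 0.0

    def test_half_molal_standard(self):
        assert kcl_reference_psi(CalibrationSolution.kcl_standard()) == pytest.approx(
            -2.19, abs=0.005
        )

    def test_matches_direct_arithmetic(self):
        sol = CalibrationSolution(molality=1.0, nu=2, phi=0.898, temperature=293.15)
        assert kcl_reference_psi(sol) == pytest.approx(
            -0.898 * 2 * 1.0 * 0.0083145 * 293.15, rel=1e-12
        )

    def test_invalid_nu(self):
        with pytest.raises(InvalidInputError):
            CalibrationSolution(molality=0.5, nu=0, phi=0.9, temperature=293.15)
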