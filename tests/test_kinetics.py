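"""Bateman model, tracer fitting, identifiability and EGP reconstruction."""

import dataclasses

import numpy as np
import pytest
from scipy.integrate import quad, solve_ivp

from glucotrace.ingest import BolusSpec, MouseTimeCourse
from glucotrace.kinetics import (FitError, KineticFit, assess_identifiability,
                                 bateman_conc, fit_tracer, reconstruct_egp)
from glucotrace.simulate import STUDY_TIMES, simulate_mouse


def _make_fit(**overrides):
    base = dict(mouse_id="m", k_a=0.06, k_2=0.03, V=20.0, V_per_bw=700.0,
                residual_sse=0.01, ci_ka=(0.04, 0.08), ci_k2=(0.02, 0.04),
                ci_V=(15.0, 25.0), identifiable_ka=True, identifiable_k2=True,
                converged=True, t_peak=23.1, c_peak=1.0)
    base.update(overrides)
    return KineticFit(**base)


class TestBateman:
    def test_zero_at_time_zero(self):
        assert bateman_conc(0.0, 1000, 20, 0.08, 0.03) == 0

    def test_degenerate_equal_rates_value(self):
        # limit of the Bateman form as k_a -> k_2 is (D/V) k t e^{-kt};
        # the ODE oracle below confirms: 10 * 0.05 * 20 * e^-1 = 3.6788
        expected = 10 * 0.05 * 20 * np.exp(-1.0)
        assert bateman_conc(20.0, 200.0, 20.0, 0.05, 0.05) == pytest.approx(
            expected, rel=1e-12)
        assert expected == pytest.approx(3.67879, abs=1e-5)

    def test_degenerate_value_matches_ode_oracle(self):
        dose, V, k = 200.0, 20.0, 0.05

        def rhs(t, y):
            return [-k * y[0], k * y[0] / V - k * y[1]]

        sol = solve_ivp(rhs, (0, 20), [dose, 0.0], t_eval=[20.0],
                        rtol=1e-12, atol=1e-14)
        assert bateman_conc(20.0, dose, V, k, k) == pytest.approx(
            sol.y[1][0], rel=1e-8)

    def test_continuous_at_equal_rates(self):
        near = bateman_conc(20.0, 200.0, 20.0, 0.05 * (1 + 2e-8), 0.05)
        limit = bateman_conc(20.0, 200.0, 20.0, 0.05, 0.05)
        assert near == pytest.approx(limit, rel=1e-6)

    def test_mass_balance_quadrature(self):
        # integral of C dt over [0, inf) = dose / (V k_2)
        dose, V, ka, k2 = 1500.0, 18.0, 0.09, 0.025
        total, _ = quad(lambda t: bateman_conc(t, dose, V, ka, k2),
                        0, np.inf)
        assert total == pytest.approx(dose / (V * k2), rel=1e-6)

    def test_matches_two_ode_system(self):
        dose, V, ka, k2 = 1200.0, 15.0, 0.07, 0.02

        def rhs(t, y):
            gut, conc = y
            return [-ka * gut, ka * gut / V - k2 * conc]

        t_eval = np.linspace(0, 120, 25)
        sol = solve_ivp(rhs, (0, 120), [dose, 0.0], t_eval=t_eval,
                        rtol=1e-12, atol=1e-14)
        closed = bateman_conc(t_eval, dose, V, ka, k2)
        assert np.allclose(sol.y[1], closed, rtol=1e-8, atol=1e-12)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            bateman_conc(-1.0, 100, 10, 0.05, 0.02)


class TestFitTracer:
    def test_noise_free_recovery(self):
        ka, k2, V = 0.08, 0.03, 20.0
        bw = 0.025
        bolus = BolusSpec()
        dose = bolus.tracer_dose_umol(bw)
        t = STUDY_TIMES
        y = bateman_conc(t, dose, V, ka, k2)
        tc = MouseTimeCourse("m", "LF", "AL", 4, bw, t, y,
                             np.full_like(t, 9.0), bolus=bolus)
        fit = fit_tracer(tc)
        assert fit.converged
        assert fit.k_a == pytest.approx(ka, rel=1e-3)
        assert fit.k_2 == pytest.approx(k2, rel=1e-3)
        assert fit.V == pytest.approx(V, rel=1e-3)

    def test_noisy_median_k2_bias_small(self, truth):
        """50 replicate fits at 5% noise: median k_2 bias under 3%."""
        cohort = truth.cohorts[0]
        rng = np.random.default_rng(11)
        est = []
        for i in range(50):
            tc = simulate_mouse(cohort, BolusSpec(), cohort.body_weight,
                                STUDY_TIMES, measurement_cv=0.05, rng=rng,
                                mouse_id=f"r{i}")
            est.append(fit_tracer(tc).k_2)
        bias = np.median(est) / cohort.k_2 - 1
        assert abs(bias) < 0.03

    def test_t_peak_matches_numerical_argmax(self, clean_mouse):
        tc, cohort = clean_mouse
        fit = fit_tracer(tc)
        dose = tc.bolus.tracer_dose_umol(tc.body_weight)
        grid = np.arange(0, 120, 0.001)
        curve = bateman_conc(grid, dose, fit.V, fit.k_a, fit.k_2)
        assert fit.t_peak == pytest.approx(grid[np.argmax(curve)], abs=0.01)
        assert fit.c_peak == pytest.approx(curve.max(), rel=1e-6)

    def test_fitted_curve_mass_balance(self, clean_mouse):
        tc, _ = clean_mouse
        fit = fit_tracer(tc)
        dose = tc.bolus.tracer_dose_umol(tc.body_weight)
        grid = np.linspace(0, 600, 6001)
        auc = np.trapezoid(bateman_conc(grid, dose, fit.V, fit.k_a, fit.k_2),
                           grid)
        assert fit.V * fit.k_2 * auc == pytest.approx(dose, rel=0.02)

    def test_all_zero_tracer_errors(self):
        t = STUDY_TIMES
        tc = MouseTimeCourse("m", "LF", "AL", 4, 0.03, t, np.zeros_like(t),
                             np.full_like(t, 9.0))
        with pytest.raises(FitError, match="zero"):
            fit_tracer(tc)

    def test_too_few_timepoints_errors(self):
        tc = MouseTimeCourse("m", "LF", "AL", 4, 0.03, [0.0, 120.0],
                             [0.0, 0.4], [9.0, 9.0])
        with pytest.raises(FitError, match="timepoints"):
            fit_tracer(tc)

    def test_profile_ci_brackets_estimate(self, clean_mouse):
        tc, cohort = clean_mouse
        rng = np.random.default_rng(5)
        noisy = dataclasses.replace(
            tc, tracer_conc=np.concatenate(
                [[0.0], tc.tracer_conc[1:]
                 * np.exp(rng.normal(0, 0.05, len(tc.times) - 1))]))
        fit = fit_tracer(noisy, ci_method="profile")
        lo, hi = fit.ci_k2
        assert lo < fit.k_2 < hi


class TestIdentifiabilityRule:
    def test_narrow_ci_identifiable(self):
        fit = _make_fit(ci_k2=(0.02, 0.04), k_2=0.03)
        assert assess_identifiability(fit)[1]  # width ratio 0.67 < 2

    def test_nonpositive_lower_bound_not_identifiable(self):
        fit = _make_fit(ci_ka=(-0.01, 0.12))
        assert not assess_identifiability(fit)[0]

    def test_wide_ci_not_identifiable(self):
        fit = _make_fit(ci_ka=(0.001, 0.5), k_a=0.06)
        assert not assess_identifiability(fit)[0]

    def test_nonconverged_never_identifiable(self):
        fit = _make_fit(converged=False)
        assert assess_identifiability(fit) == (False, False)

    def test_cohort_proportion_counting(self):
        flags = [True] * 6 + [False] * 2
        assert np.mean(flags) == pytest.approx(0.75)


class TestReconstructEGP:
    def test_basal_steady_state_recovers_v_k2_c0(self):
        """No bolus, flat unlabelled baseline: EGP(t) = V k_2 C0 on the grid."""
        c0, V, k2 = 9.0, 20.0, 0.03
        t = STUDY_TIMES
        bolus = BolusSpec(dose_unlabelled=0.0, dose_tracer=0.0)
        tc = MouseTimeCourse("m", "LF", "AL", 4, 0.025, t, np.zeros_like(t),
                             np.full_like(t, c0), bolus=bolus)
        fit = _make_fit(V=V, k_2=k2, V_per_bw=V / 0.025)
        prof = reconstruct_egp(tc, fit)
        assert np.allclose(prof.egp_absolute, V * k2 * c0, rtol=1e-12)
        assert prof.avg_specific_egp_5_120 == pytest.approx(
            V * k2 * c0 / 0.025, rel=1e-12)

    def test_doubling_bw_halves_specific_egp(self):
        c0, V, k2 = 9.0, 20.0, 0.03
        t = STUDY_TIMES
        bolus = BolusSpec(dose_unlabelled=0.0, dose_tracer=0.0)
        fit = _make_fit(V=V, k_2=k2)
        prof = {}
        for bw in (0.025, 0.05):
            tc = MouseTimeCourse("m", "LF", "AL", 4, bw, t, np.zeros_like(t),
                                 np.full_like(t, c0), bolus=bolus)
            prof[bw] = reconstruct_egp(tc, fit)
        assert np.allclose(prof[0.05].egp_specific,
                           prof[0.025].egp_specific / 2)

    def test_constant_true_egp_closed_loop(self, truth):
        """depth=0 mouse: reconstructed average matches true basal within 2%."""
        cohort = dataclasses.replace(truth.cohorts[0],
                                     egp_suppression_depth=0.0)
        tc = simulate_mouse(cohort, BolusSpec(), cohort.body_weight,
                            STUDY_TIMES, measurement_cv=0.0, mouse_id="m")
        prof = reconstruct_egp(tc, fit_tracer(tc))
        assert prof.avg_specific_egp_5_120 == pytest.approx(
            cohort.basal_egp_specific, rel=0.02)

    def test_nonconverged_fit_rejected(self, clean_mouse):
        tc, _ = clean_mouse
        fit = _make_fit(converged=False)
        with pytest.raises(FitError):
            reconstruct_egp(tc, fit)
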