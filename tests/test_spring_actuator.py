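"""Leg force-length series, hysteresis area and the spring-actuator fit."""

import numpy as np
import pytest

from bouncework import errors
from bouncework.spring_actuator import (
    LegSeries,
    SpringMassActuator,
    compression_split,
    fit_spring_actuator,
    hysteresis_area,
    leg_series,
)
from bouncework.synthetic_data import SimulationParams, simulate_spring_loop
from bouncework.trial_io import ForceSeries


def loop_series(cst=2.0, k=30.0, c=-100.0, A=0.05, T=0.3, L0=1.0,
                fs=1000.0, noise=0.0, seed=0):
    """One closed force-length loop from the damped-spring law."""
    omega = 2 * np.pi / T
    t = np.arange(int(round(T * fs)) + 1) / fs
    L = L0 - A * (1 - np.cos(omega * t))
    V = -A * omega * np.sin(omega * t)
    F = cst + k * L + c * V
    if noise:
        F = F + np.random.default_rng(seed).normal(0, noise, t.size)
    return LegSeries(time=t, L_leg=L, V_leg=V, F_projected=F,
                     leg_angle=np.zeros(t.size),
                     valid=np.ones(t.size, bool), mass=70.0)


class TestLegSeries:
    @staticmethod
    def forces_with(fy, fz, cop, n=400, fs=1000.0):
        t = np.arange(n) / fs
        return ForceSeries(t, np.full(n, fy), np.full(n, fz),
                           np.full(n, cop)).with_cop_mask(300.0)

    def test_vertical_leg_projection(self):
        """COP directly below GT, GRF (0, 800 N), m = 80 kg → 10 N/kg."""
        forces = self.forces_with(0.0, 800.0, 0.0)
        gt = np.tile([0.0, 0.9], (400, 1))
        ls = leg_series(forces, gt, (0, 400), 80.0)
        np.testing.assert_allclose(ls.F_projected, 10.0, rtol=1e-12)
        np.testing.assert_allclose(ls.L_leg, 0.9, rtol=1e-12)

    def test_inclined_leg_projects_cosine(self):
        """Leg at 45° from vertical: F_projected = 10·cos45° = 7.07 N/kg."""
        forces = self.forces_with(0.0, 800.0, 0.0)
        gt = np.tile([0.9, 0.9], (400, 1))
        ls = leg_series(forces, gt, (0, 400), 80.0)
        np.testing.assert_allclose(ls.F_projected,
                                   10.0 * np.cos(np.pi / 4), rtol=1e-12)
        np.testing.assert_allclose(np.abs(ls.leg_angle), np.pi / 4,
                                   rtol=1e-12)

    def test_constant_length_rotating_leg_has_zero_velocity(self):
        n, fs, R = 400, 1000.0, 1.0
        t = np.arange(n) / fs
        ang = 0.3 * np.sin(2 * np.pi * t)
        forces = ForceSeries(t, np.zeros(n), np.full(n, 800.0),
                             np.zeros(n)).with_cop_mask(300.0)
        gt = R * np.column_stack([np.sin(ang), np.cos(ang)])
        ls = leg_series(forces, gt, (0, n), 80.0)
        assert np.max(np.abs(ls.V_leg)) < 1e-4

    def test_low_force_frames_masked(self):
        n = 400
        t = np.arange(n) / 1000.0
        fz = np.full(n, 800.0)
        fz[:50] = 100.0
        forces = ForceSeries(t, np.zeros(n), fz,
                             np.zeros(n)).with_cop_mask(300.0)
        gt = np.tile([0.0, 0.9], (n, 1))
        ls = leg_series(forces, gt, (0, n), 80.0)
        assert not ls.valid[:50].any() and ls.valid[50:].all()

    def test_marker_gap_inside_contact_rejected(self):
        forces = self.forces_with(0.0, 800.0, 0.0)
        gt = np.tile([0.0, 0.9], (400, 1))
        gt[100, 0] = np.nan
        with pytest.raises(errors.GeometryError):
            leg_series(forces, gt, (0, 400), 80.0)


class TestCompressionSplit:
    @staticmethod
    def series_from_L(L, fs=1000.0):
        t = np.arange(L.size) / fs
        return LegSeries(time=t, L_leg=L, V_leg=np.gradient(L, 1 / fs),
                         F_projected=np.ones(L.size),
                         leg_angle=np.zeros(L.size),
                         valid=np.ones(L.size, bool))

    def test_v_shape_splits_at_vertex(self):
        L = np.concatenate([np.linspace(1.0, 0.8, 50),
                            np.linspace(0.8, 1.0, 50)[1:]])
        comp, decomp = compression_split(self.series_from_L(L))
        assert comp.stop - 1 == 49 and decomp.start == 49

    def test_cosine_minimum_at_half_period(self):
        """L = 1 − 0.05(1 − cos(2πt/0.3)): minimum at t = 0.15 s."""
        ls = loop_series(c=0.0)
        comp, _ = compression_split(ls)
        assert abs(ls.time[comp.stop - 1] - 0.15) <= 1.5e-3

    def test_tie_breaks_to_earliest(self):
        L = np.ones(100)
        L[30] = L[60] = 0.8
        comp, _ = compression_split(self.series_from_L(L))
        assert comp.stop - 1 == 30

    def test_monotone_length_is_degenerate(self):
        L = np.linspace(1.0, 0.8, 100)
        with pytest.warns(UserWarning, match="monotone leg length"):
            assert compression_split(self.series_from_L(L)) is None
        assert np.isnan(hysteresis_area(self.series_from_L(L)))


class TestHysteresisArea:
    def test_pure_spring_closed_loop_is_zero(self):
        area = hysteresis_area(loop_series(c=0.0))
        assert abs(area) < 1e-10

    def test_damper_loop_matches_closed_form_and_quadrature(self):
        """Δ_area = −c·π·A²·ω = 16.45 J/kg for c = −100, A = 0.05 m,
        ω = 2π/0.3; cross-checked against −c∫V²dt quadrature."""
        ls = loop_series(c=-100.0)
        area = hysteresis_area(ls)
        closed = 100.0 * np.pi * 0.05**2 * (2 * np.pi / 0.3)
        assert abs(closed - 16.45) < 0.01
        assert abs(area - closed) < 0.005 * closed
        quad = -(-100.0) * np.trapezoid(ls.V_leg**2, ls.time)
        assert abs(area - quad) < 0.005 * quad

    def test_resampling_invariance(self):
        a1 = hysteresis_area(loop_series(c=-100.0, fs=1000.0))
        a2 = hysteresis_area(loop_series(c=-100.0, fs=2000.0))
        assert abs(a1 - a2) < 0.005 * abs(a1)

    def test_literal_variant_nonzero_for_pure_spring(self):
        """The printed two-branch signed integral does not vanish for a
        conservative spring; it is kept only as an audit variant."""
        lit = hysteresis_area(loop_series(c=0.0), literal=True)
        assert abs(lit) > 1.0

    def test_open_loop_warns(self):
        ls = loop_series(c=0.0)
        ls.L_leg[-60:] = ls.L_leg[-60]  # truncate the return branch
        with pytest.warns(UserWarning, match="open force-length loop"):
            hysteresis_area(ls)


class TestFit:
    def test_exact_recovery_on_noiseless_law(self):
        res = fit_spring_actuator(loop_series(cst=2.0, k=30.0, c=-5.0))
        np.testing.assert_allclose([res.cst, res.k, res.c], [2.0, 30.0, -5.0],
                                   rtol=1e-9, atol=1e-9)
        assert res.rmse < 1e-10
        assert abs(res.r_squared - 1.0) < 1e-12

    def test_agrees_with_normal_equations_and_statsmodels(self):
        import statsmodels.api as sm
        ls = loop_series(cst=2.0, k=30.0, c=-5.0, noise=1.0, seed=42)
        model = SpringMassActuator.from_leg_series(ls)
        res = model.fit()
        X, y = model.exog, model.endog
        beta_ne = np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose(res.params, beta_ne, rtol=1e-8)
        sm_res = sm.OLS(y, X).fit()
        np.testing.assert_allclose(res.params, sm_res.params, rtol=1e-8)
        np.testing.assert_allclose(res.bse, sm_res.bse, rtol=1e-6)
        assert abs(res.rsquared - sm_res.rsquared) < 1e-10

    def test_diagnostics_match_textbook_definitions(self):
        ls = loop_series(noise=0.5, seed=7)
        model = SpringMassActuator.from_leg_series(ls)
        res = model.fit()
        resid = model.endog - model.exog @ res.params
        rmse = np.sqrt(np.mean(resid**2))
        r2 = 1 - np.sum(resid**2) / np.sum(
            (model.endog - model.endog.mean())**2)
        assert abs(res.rmse - rmse) < 1e-10
        assert abs(res.rsquared - r2) < 1e-10

    def test_rank_deficient_design_rejected(self):
        n = 50
        t = np.arange(n) / 1000.0
        L = np.linspace(1.0, 0.9, n)
        V = 2.0 * L  # collinear with L
        ls = LegSeries(time=t, L_leg=L, V_leg=V, F_projected=np.ones(n),
                       leg_angle=np.zeros(n), valid=np.ones(n, bool))
        with pytest.raises(errors.DegenerateFitError):
            fit_spring_actuator(ls)

    def test_too_few_frames_rejected(self):
        with pytest.raises(errors.DegenerateFitError):
            SpringMassActuator(np.ones(5), np.ones(5), np.ones(5))

    def test_summary_mentions_parameters(self):
        res = SpringMassActuator.from_leg_series(loop_series()).fit()
        text = res.summary()
        for token in ("cst", "k", "c", "R-squared", "RMSE"):
            assert token in text


class TestMonteCarloRecovery:
    def test_mean_estimates_over_noisy_steps(self):
        """50 steps from F = 2 + 30L − 5V with σ = 1 N/kg noise: mean k̂
        within 2%, mean ĉ within 5%, mean RMSE within 10% of σ."""
        params = SimulationParams(spring=(2.0, 30.0, -5.0))
        series, truth = simulate_spring_loop(params, seed=11, n_steps=50,
                                             noise_sd=1.0)
        fits = [fit_spring_actuator(s) for s in series]
        k_hat = np.mean([f.k for f in fits])
        c_hat = np.mean([f.c for f in fits])
        rmse = np.mean([f.rmse for f in fits])
        assert abs(k_hat - 30.0) < 0.02 * 30.0
        assert abs(c_hat + 5.0) < 0.05 * 5.0
        assert abs(rmse - 1.0) < 0.10
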