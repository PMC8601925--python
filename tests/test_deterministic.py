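"""Unit tests for the deterministic sweep: integration and closed forms."""

import math
import warnings

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from hitchsweep import (
    Case1Constants,
    Case2Constants,
    DomainError,
    InitialConditions,
    ModelAssumptionWarning,
    SweepIncompleteError,
    SweepParams,
    UnsupportedRegimeError,
    case1_solution,
    case1_x_of_t,
    case2_solution,
    case3_solution,
    het_ratio_after_sweep,
    integrate_sweep,
    mutation_selection_balance,
    soft_sweep_threshold,
    sweep_duration,
)
from hitchsweep.deterministic import kappa_below_deterministic_threshold


CASE1 = SweepParams(s2=0.01, mu_B=1e-4)
INIT1 = InitialConditions(x0=0.005, p10=0.0, p20=0.7)


class TestIntegrateSweep:
    def test_classical_limit_matches_logistic(self):
        params = SweepParams(s2=0.01)
        init = InitialConditions(x0=0.005, p10=0.5, p20=0.5)
        traj = integrate_sweep(params, init, 0.995)
        t = traj.times
        logistic = 0.005 / (0.005 + 0.995 * np.exp(-0.01 * t))
        assert np.max(np.abs(traj.frame["x"].to_numpy() - logistic)) < 1e-8

    def test_stop_time_close_to_sweep_duration(self):
        params = SweepParams(s2=0.01)
        init = InitialConditions(x0=0.005, p10=0.5, p20=0.5)
        traj = integrate_sweep(params, init, 1 - 0.005)
        tau_hat = sweep_duration(params, 0.005)
        assert traj.times[-1] == pytest.approx(tau_hat, rel=0.005)

    def test_incomplete_sweep_raises_with_partial_trajectory(self):
        params = SweepParams(s2=0.01, mu_B=1e-6)
        init = InitialConditions(x0=0.005, p10=0.0, p20=0.5)
        with pytest.raises(SweepIncompleteError, match="did not complete") as err:
            integrate_sweep(params, init, 0.99, max_time=50.0)
        partial = err.value.trajectory
        assert partial.frame["x"].iloc[-1] < 0.99

    def test_invalid_stop_rejected(self):
        with pytest.raises(DomainError):
            integrate_sweep(CASE1, INIT1, 0.001)


class TestCase1:
    def test_integration_constant(self):
        C = Case1Constants.from_conditions(CASE1, INIT1).C
        assert C == pytest.approx(0.005 / 1.5e-4 * (-0.7), rel=1e-12)

    def test_equal_backgrounds_keep_constant_haplotype_ratio(self):
        init = InitialConditions(x0=0.005, p10=0.3, p20=0.3)
        xs = np.linspace(0.005, 0.99, 50)
        sol = case1_solution(xs, CASE1, init)
        assert np.max(np.abs(sol.p1 - 0.3)) < 1e-14
        assert np.max(np.abs(sol.x1 / xs - 0.3)) < 1e-14

    def test_no_decay_without_beneficial_mutation(self):
        # mu_B -> 0: p1 - p2 stays at its initial value for all x
        params = SweepParams(s2=0.01, mu_B=1e-12)
        xs = np.linspace(0.005, 0.99, 20)
        sol = case1_solution(xs, params, INIT1)
        assert np.max(np.abs(sol.p1_minus_p2 - (-0.7))) < 1e-6

    def test_against_numerical_integration(self):
        traj = integrate_sweep(CASE1, INIT1, 0.995)
        xs = traj.frame["x"].to_numpy()
        sol = case1_solution(xs, CASE1, INIT1)
        assert np.max(np.abs(sol.p1 - traj.frame["p1"].to_numpy())) < 1e-8
        assert np.max(np.abs(sol.p2 - traj.frame["p2"].to_numpy())) < 1e-8

    def test_value_at_half_frequency(self):
        sol = case1_solution(0.5, CASE1, INIT1)
        assert float(sol.p1_minus_p2) == pytest.approx(-0.238, rel=1e-3)
        assert float(sol.p1) == pytest.approx(0.462, rel=1e-3)

    def test_regime_gate_names_violation(self):
        with pytest.raises(UnsupportedRegimeError, match="r = 0"):
            case1_solution(0.5, SweepParams(s2=0.01, mu_B=1e-4, r=1e-3), INIT1)


class TestCase1XofT:
    def test_initial_value(self):
        assert case1_x_of_t(0.0, CASE1, 0.005) == pytest.approx(0.005, rel=1e-14)

    def test_reduces_to_logistic_without_mutation(self):
        params = SweepParams(s2=0.01)
        t = np.linspace(0, 2000, 40)
        x = case1_x_of_t(t, params, 0.005)
        logistic = 0.005 / (0.005 + 0.995 * np.exp(-0.01 * t))
        assert np.max(np.abs(x - logistic)) < 1e-14

    def test_against_adaptive_quadrature(self):
        # independent oracle: integrate dx/dt = (s2 x + mu_B)(1-x) directly
        sol = solve_ivp(
            lambda t, y: [(0.01 * y[0] + 1e-4) * (1 - y[0])],
            (0, 500), [0.005], rtol=1e-12, atol=1e-14, dense_output=True,
        )
        for t in (100.0, 250.0, 500.0):
            assert case1_x_of_t(t, CASE1, 0.005) == pytest.approx(
                float(sol.sol(t)[0]), abs=1e-10
            )

    def test_monotone_increasing(self):
        t = np.linspace(0, 3000, 200)
        x = case1_x_of_t(t, CASE1, 0.005)
        assert np.all(np.diff(x) > 0)


class TestCase2:
    def test_collapses_to_case1_at_zero_recombination(self):
        xs = np.linspace(0.005, 0.95, 30)
        c2 = case2_solution(xs, CASE1, INIT1)
        c1 = case1_solution(xs, CASE1, INIT1)
        assert np.max(np.abs(c2.p1_minus_p2 - c1.p1_minus_p2)) < 1e-14
        assert np.max(np.abs(c2.p2_approx - c1.p2)) < 1e-14

    def test_equal_backgrounds_are_a_fixed_point(self):
        params = SweepParams(s2=0.01, mu_B=1e-4, r=1e-4)
        init = InitialConditions(x0=0.005, p10=0.4, p20=0.4)
        xs = np.linspace(0.005, 0.95, 10)
        sol = case2_solution(xs, params, init)
        assert np.max(np.abs(sol.p1_minus_p2)) == 0.0
        assert np.max(np.abs(sol.p2_approx - 0.4)) == 0.0

    def test_exact_difference_and_approximate_p2(self):
        params = SweepParams(s2=0.01, mu_B=1e-4, r=1e-4)
        rho = Case2Constants.from_conditions(params, INIT1).rho
        traj = integrate_sweep(params, INIT1, 0.95)
        xs = traj.frame["x"].to_numpy()
        sol = case2_solution(xs, params, INIT1)
        diff_num = (traj.frame["p1"] - traj.frame["p2"]).to_numpy()
        assert np.max(np.abs(sol.p1_minus_p2 - diff_num)) < 1e-8
        rel = np.abs(sol.p2_approx - traj.frame["p2"].to_numpy()) / traj.frame["p2"].to_numpy()
        assert np.max(rel) < 5 * rho

    def test_large_rho_warns(self):
        params = SweepParams(s2=0.01, mu_B=1e-4, r=0.005)
        with pytest.warns(ModelAssumptionWarning, match="rho"):
            Case2Constants.from_conditions(params, INIT1)


CASE3 = SweepParams(s2=0.05, s1=-0.001, mu_A=1e-5, r=5e-4)
INIT3 = InitialConditions(x0=0.005, p10=0.0, p20=0.01)


class TestCase3:
    def test_initial_state(self):
        sol = case3_solution(0.0, CASE3, INIT3)
        assert float(sol.x) == pytest.approx(0.005)
        assert float(sol.p1_minus_p2) == pytest.approx(-0.01)
        assert float(sol.p1) == 0.0
        assert float(sol.p2) == pytest.approx(0.01)

    def test_no_influx_without_recombination_or_selection(self):
        # r = 0 and s1 -> 0-: the A background cannot be reseeded
        params = SweepParams(s2=0.05, s1=-1e-10, mu_A=1e-12)
        sol = case3_solution(np.linspace(0, 500, 20), params, INIT3)
        assert np.max(np.abs(sol.p1)) < 1e-6

    def test_balance_frequency(self):
        assert mutation_selection_balance(CASE3) == pytest.approx(0.01)
        with pytest.raises(UnsupportedRegimeError):
            mutation_selection_balance(SweepParams(s2=0.05))

    def test_p1_rises_toward_balance(self):
        tau = np.linspace(0.0, 50_000.0, 200)
        sol = case3_solution(tau, CASE3, INIT3)
        assert np.all(np.diff(sol.p1) > -1e-15)
        assert float(sol.p1[-1]) == pytest.approx(0.01, rel=0.01)

    def test_regime_gate(self):
        with pytest.raises(UnsupportedRegimeError):
            case3_solution(1.0, SweepParams(s2=0.05, mu_B=1e-6), INIT3)


class TestSweepDuration:
    def test_printed_value(self):
        assert sweep_duration(SweepParams(s2=0.01), 0.005) == pytest.approx(
            200 * math.log(200), rel=1e-12
        )

    def test_doubling_selection_halves_duration(self):
        a = sweep_duration(SweepParams(s2=0.01), 0.005)
        b = sweep_duration(SweepParams(s2=0.02), 0.005)
        assert a == pytest.approx(2 * b, rel=1e-14)

    def test_logistic_reaches_complement_of_x0(self):
        x0 = 0.005
        params = SweepParams(s2=0.01)
        tau = sweep_duration(params, x0)
        x_end = float(case1_x_of_t(tau, SweepParams(s2=0.01, mu_B=0.0), x0))
        assert abs(x_end - (1 - x0)) < 2 * x0**2

    def test_exact_form(self):
        x0 = 0.005
        exact = sweep_duration(SweepParams(s2=0.01), x0, exact=True)
        assert exact == pytest.approx(200 * math.log((1 - x0) / x0), rel=1e-14)

    def test_domain(self):
        with pytest.raises(DomainError):
            sweep_duration(SweepParams(s2=0.01), 0.6)


class TestHetRatio:
    def test_closed_form_without_recombination(self):
        params = SweepParams(s2=0.01, s1=-0.001, mu_A=1e-5)
        s = het_ratio_after_sweep(params, 0.005, mode="closed_form")
        # X = x0^{-2 s1/s2} = 0.005^0.2
        assert s.H_ratio == pytest.approx(1 - 0.005**0.2, rel=1e-10)
        assert s.H_ratio == pytest.approx(0.6534, abs=5e-4)

    def test_neutral_limit_recovers_classical_hitchhiking(self):
        params = SweepParams(s2=0.01, r=1e-3)
        s = het_ratio_after_sweep(params, 0.005, mode="closed_form", p20=0.01)
        assert s.H_ratio == pytest.approx(1 - 0.005 ** (2 * 1e-3 / 0.01), rel=1e-10)

    def test_neutral_no_recombination_loses_everything(self):
        params = SweepParams(s2=0.01)
        s = het_ratio_after_sweep(params, 0.005, mode="closed_form", p20=0.01)
        assert s.H_ratio == pytest.approx(0.0, abs=1e-12)

    def test_modes_agree_in_regime(self):
        for r in (0.0, 1e-4):
            params = SweepParams(s2=0.01, s1=-0.001, mu_A=1e-5, r=r)
            closed = het_ratio_after_sweep(params, 0.005, mode="closed_form")
            numeric = het_ratio_after_sweep(params, 0.005, mode="numeric")
            assert closed.H_ratio == pytest.approx(numeric.H_ratio, rel=0.10)

    def test_numeric_ratio_monotone_in_recombination(self):
        ratios = []
        for r in (0.0, 1e-4, 1e-3, 5e-3):
            params = SweepParams(s2=0.01, s1=-0.001, mu_A=1e-5, r=r)
            ratios.append(het_ratio_after_sweep(params, 0.005, mode="numeric").H_ratio)
        assert all(b >= a - 1e-12 for a, b in zip(ratios, ratios[1:]))

    def test_free_recombination_preserves_heterozygosity(self):
        params = SweepParams(s2=0.01, s1=-1e-4, mu_A=1e-6, r=0.4)
        s = het_ratio_after_sweep(params, 0.005, mode="numeric")
        assert s.H_ratio >= 1 - 10 * 0.005

    def test_neutral_locus_requires_explicit_p20(self):
        with pytest.raises(UnsupportedRegimeError):
            het_ratio_after_sweep(SweepParams(s2=0.01), 0.005, mode="numeric")

    def test_large_balance_frequency_warns(self):
        params = SweepParams(s2=0.05, s1=-1e-4, mu_A=5e-5)  # p20 = 0.5
        with pytest.warns(ModelAssumptionWarning, match="p20"):
            het_ratio_after_sweep(params, 0.005, mode="closed_form")


class TestSoftSweepThreshold:
    def test_value(self):
        assert soft_sweep_threshold(SweepParams(s2=0.01, mu_B=1e-6)) == pytest.approx(1e-4)

    def test_hard_sweep_regime(self):
        assert soft_sweep_threshold(SweepParams(s2=0.01)) == 0.0

    def test_comparison_with_deterministic_threshold(self):
        # N = 1e4, s2 = 0.01 -> alpha = 200, x0 = 5/alpha = 0.025 > kappa = 1e-4
        params = SweepParams(s2=0.01, mu_B=1e-6)
        assert kappa_below_deterministic_threshold(params, 5 / 200) is True
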