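"""Exactly solvable two-strain model and the logistic competition model."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from ampliscope.theory import (
    GrowthResponse,
    TheoryParams,
    dose_response_time_difference,
    exact_solution,
    hotspot_dose,
    msw_boundaries,
    resistant_frequency,
    selection_coefficient,
    simulate_competition,
    thetas,
)

from conftest import random_exp_params


def integrate_two_strain(params, A, times):
    """Independent ODE oracle for the exponential-growth model."""
    th1, th2 = thetas(params, A)

    def rhs(t, y):
        return [th1 * y[0], th2 * y[1] + params.mu * y[0]]

    sol = solve_ivp(rhs, (0.0, times[-1]), [1.0, 0.0], t_eval=times, rtol=1e-10, atol=1e-14)
    return sol.y[0], sol.y[1]


class TestExactSolution:
    def test_no_mutation_keeps_population_clonal(self, exp_params):
        params = TheoryParams(
            mu=0.0, d=exp_params.d, ell=exp_params.ell, lam=exp_params.lam, g=exp_params.g
        )
        t = np.linspace(0, 8, 20)
        S, R = exact_solution(params, 1.0, t)
        th1, _ = thetas(params, 1.0)
        assert np.allclose(R, 0.0)
        assert np.allclose(S, np.exp(th1 * t))

    def test_matches_ode_integration(self, exp_params):
        t = np.linspace(0.0, 10.0, 41)
        S, R = exact_solution(exp_params, 1.0, t)
        S_ode, R_ode = integrate_two_strain(exp_params, 1.0, t)
        assert np.max(np.abs(S[1:] - S_ode[1:]) / np.abs(S_ode[1:])) < 1e-6
        assert np.max(np.abs(R[1:] - R_ode[1:]) / np.abs(R_ode[1:])) < 1e-6

    def test_matches_ode_on_random_draws(self):
        rng = np.random.default_rng(42)
        t = np.linspace(0.0, 6.0, 25)
        for _ in range(20):
            params = random_exp_params(rng)
            A = rng.uniform(0.0, 3.0)
            S, R = exact_solution(params, A, t)
            S_ode, R_ode = integrate_two_strain(params, A, t)
            assert np.max(np.abs(S[1:] - S_ode[1:]) / np.abs(S_ode[1:])) < 1e-6
            scale = np.maximum(np.abs(R_ode[1:]), 1e-30)
            assert np.max(np.abs(R[1:] - R_ode[1:]) / scale) < 1e-6

    def test_degenerate_thetas_use_lhopital_limit(self):
        # force g(A) - mu = ell g(lam A): with lam = 1, ell = 1 - mu/g(A)
        g = GrowthResponse("exponential", p=1.0)
        A, mu = 1.0, 0.01
        ell = 1.0 - mu / float(g(A))
        params = TheoryParams(mu=mu, d=0.2, ell=ell, lam=1.0, g=g)
        th1, th2 = thetas(params, A)
        assert abs(th1 - th2) < 1e-12
        t = np.linspace(0, 5, 11)
        _, R = exact_solution(params, A, t)
        assert np.allclose(R, mu * t * np.exp(th1 * t), rtol=1e-9)


class TestResistantFrequency:
    def test_initially_clonal(self, exp_params):
        assert resistant_frequency(exp_params, 1.0, 0.0) == 1.0

    def test_long_time_mutation_selection_balance(self):
        # theta1 = 0.5, theta2 = 0.3 via A = 0: g(0)=1, theta1 = 1-d-mu,
        # theta2 = ell-d; rho -> 1/(1 + mu/(theta1-theta2)) = 2/3
        params = TheoryParams(
            mu=0.1, d=0.4, ell=0.7, lam=0.5, g=GrowthResponse("exponential", p=1.0)
        )
        th1, th2 = thetas(params, 0.0)
        assert (th1, th2) == pytest.approx((0.5, 0.3))
        rho_inf = float(resistant_frequency(params, 0.0, 200.0))
        assert rho_inf == pytest.approx(1.0 / (1.0 + 0.1 / 0.2), abs=1e-6)
        # independent check: long-time integration of the ODE system
        t = np.array([0.0, 200.0])
        S, R = integrate_two_strain(params, 0.0, t)
        assert rho_inf == pytest.approx(S[-1] / (S[-1] + R[-1]), rel=1e-6)

    def test_invariant_under_death_rate(self):
        rng = np.random.default_rng(7)
        t = np.linspace(0.0, 20.0, 17)
        for _ in range(25):
            base = random_exp_params(rng)
            A = rng.uniform(0.0, 3.0)
            rho1 = resistant_frequency(base, A, t)
            shifted = TheoryParams(
                mu=base.mu, d=rng.uniform(0.0, 1.0), ell=base.ell, lam=base.lam, g=base.g
            )
            rho2 = resistant_frequency(shifted, A, t)
            assert np.allclose(rho1, rho2, rtol=0, atol=1e-12)

    def test_consistent_with_exact_solution(self, exp_params):
        t = np.linspace(0.5, 10.0, 20)
        S, R = exact_solution(exp_params, 1.0, t)
        rho = resistant_frequency(exp_params, 1.0, t)
        assert np.allclose(rho, S / (S + R), atol=1e-10)


class TestSelectionCoefficient:
    def test_identical_strains_leave_only_mutation(self, exp_params):
        params = TheoryParams(mu=0.01, d=0.1, ell=1.0, lam=1.0, g=exp_params.g)
        A = np.array([0.0, 0.5, 2.0, 10.0])
        assert np.allclose(selection_coefficient(params, A), 0.01)

    def test_zero_dose_value_forced_by_g0(self, exp_params):
        s0 = float(selection_coefficient(exp_params, 0.0))
        assert s0 == pytest.approx(exp_params.ell - 1.0 + exp_params.mu, abs=1e-12)

    def test_single_interior_peak(self):
        params = TheoryParams(
            mu=0.0, d=0.1, ell=0.9, lam=0.5, g=GrowthResponse("exponential", p=1.0)
        )
        grid = np.linspace(0.0, 10.0, 2001)
        s = selection_coefficient(params, grid)
        i = int(np.argmax(s))
        assert 0 < i < len(grid) - 1
        assert s[i] > s[0] and s[i] > s[-1]


class TestHotspotDose:
    def test_closed_form_matches_grid_maximum(self):
        params = TheoryParams(
            mu=0.0, d=0.1, ell=0.9, lam=0.5, g=GrowthResponse("exponential", p=1.0)
        )
        res = hotspot_dose(params)
        assert res.method == "closed_form"
        assert res.dose == pytest.approx(2.0 * np.log(1.0 / 0.45), abs=1e-9)
        numeric = hotspot_dose(params, method="numeric")
        assert numeric.dose == pytest.approx(res.dose, rel=1e-6)

    def test_closed_equals_numeric_on_random_draws(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            params = random_exp_params(rng)
            closed = hotspot_dose(params)
            numeric = hotspot_dose(params, method="numeric")
            assert closed.dose > 0  # positive whenever 0 < ell, lam < 1
            assert numeric.dose == pytest.approx(closed.dose, rel=1e-6, abs=1e-8)

    def test_doubling_efficacy_halves_hotspot(self):
        kw = dict(mu=0.0, d=0.1, ell=0.9, lam=0.5)
        a1 = hotspot_dose(TheoryParams(g=GrowthResponse("exponential", p=1.0), **kw)).dose
        a2 = hotspot_dose(TheoryParams(g=GrowthResponse("exponential", p=2.0), **kw)).dose
        assert a2 == pytest.approx(a1 / 2.0, rel=1e-12)

    def test_interior_maximum_is_concave(self, hill_params):
        res = hotspot_dose(hill_params)
        assert res.location == "interior"
        h = 1e-4
        s = selection_coefficient(hill_params, np.array([res.dose - h, res.dose, res.dose + h]))
        second = (s[0] - 2 * s[1] + s[2]) / h**2
        assert second < 0


class TestMswBoundaries:
    def test_exponential_mic_analytic(self):
        params = TheoryParams(
            mu=0.01, d=np.exp(-2.0), ell=0.9, lam=0.5, g=GrowthResponse("exponential", p=1.0)
        )
        b = msw_boundaries(params)
        assert b.mic_s == pytest.approx(2.0, abs=1e-10)

    def test_hill_mic_at_half_inhibition(self):
        params = TheoryParams(
            mu=0.01, d=0.5, ell=0.9, lam=0.5, g=GrowthResponse("hill", k_half=1.0, n_hill=7.0)
        )
        b = msw_boundaries(params)
        assert b.mic_s == pytest.approx(1.0, abs=1e-10)

    def test_mpc_exceeds_ancestral_mic(self):
        # with ell = 0.9 and lam = 0.5 the window is open for any decreasing
        # g and moderate d (for exponential g the condition is
        # d < ell^(1/(1-lam)) = 0.81); extreme cost/scaling combinations can
        # close it, so the parameter regime is fixed and d and g are drawn
        rng = np.random.default_rng(11)
        for _ in range(30):
            if rng.uniform() < 0.5:
                g = GrowthResponse("exponential", p=rng.uniform(0.2, 3.0))
            else:
                g = GrowthResponse(
                    "hill", k_half=rng.uniform(0.3, 3.0), n_hill=rng.uniform(1.0, 8.0)
                )
            params = TheoryParams(
                mu=rng.uniform(0.0, 0.05), d=rng.uniform(0.05, 0.7), ell=0.9, lam=0.5, g=g
            )
            b = msw_boundaries(params)
            assert b.mpc is not None and b.mic_s is not None
            assert b.mpc > b.mic_s

    def test_msc_zero_when_selected_from_zero_dose(self):
        params = TheoryParams(
            mu=0.2, d=0.1, ell=0.95, lam=0.5, g=GrowthResponse("exponential", p=1.0)
        )
        assert selection_coefficient(params, 0.0) > 0
        assert msw_boundaries(params).msc == 0.0


class TestCompetitionModel:
    def test_drug_free_logistic_saturation(self):
        df = simulate_competition(A=0.0, mu=0.0, S0=0.01, R0=0.0, t_end=30.0, dt_out=0.5)
        assert df["S"].iloc[-1] == pytest.approx(1.0, abs=1e-4)
        assert np.all(df["R"] == 0.0)  # no mutation, no initial resistance

    def test_resistant_excludes_susceptible_at_positive_dose(self):
        df = simulate_competition(A=0.5, mu=0.0, S0=0.01, R0=0.001, t_end=120.0, dt_out=1.0)
        assert df["R"].iloc[-1] == pytest.approx(1.0, abs=1e-3)
        assert df["S"].iloc[-1] < 1e-6

    def test_densities_stay_non_negative(self):
        df = simulate_competition(A=1.5, mu=1e-3, S0=0.01, R0=0.0, t_end=60.0, dt_out=0.25)
        assert (df[["S", "R"]] >= 0.0).all().all()


class TestDoseResponseTimeDifference:
    A_GRID = np.round(np.arange(0.0, 1.51, 0.1), 3)

    def test_no_resistance_makes_zero_dose_fastest(self):
        # without mutants the dose response stays monotone at every time, so
        # density gained from inoculation is always maximal drug-free
        density, _, argmax = dose_response_time_difference(
            self.A_GRID, mu=0.0, S0=0.01, R0=0.0, t_snapshots=[0.0, 6.0]
        )
        assert (argmax["argmax_dose"] == 0.0).all()
        for t, grp in density.groupby("t"):
            n = grp.sort_values("dose")["total"].to_numpy()
            assert np.all(np.diff(n) <= 1e-9)

    def test_monotone_early_nonmonotone_late(self):
        density, _, _ = dose_response_time_difference(
            self.A_GRID, mu=1e-4, S0=0.01, R0=0.0, t_snapshots=[6.0, 20.0]
        )
        early = density[density["t"] == 6.0].sort_values("dose")["total"].to_numpy()
        late = density[density["t"] == 20.0].sort_values("dose")["total"].to_numpy()
        assert np.all(np.diff(early) <= 1e-9)
        assert np.any(np.diff(late) > 1e-6)

    def test_hotspot_dose_grows_with_duration(self):
        _, _, argmax = dose_response_time_difference(
            self.A_GRID, mu=1e-4, S0=0.01, R0=0.0, t_snapshots=[2.0, 6.0, 12.0, 20.0]
        )
        seq = argmax.sort_values("t_start")["argmax_dose"].to_numpy()
        assert np.all(np.diff(seq) > 0)

    def test_super_mic_doses_only_lose_density_without_mutation(self):
        _, diffs, _ = dose_response_time_difference(
            np.array([1.1, 1.3, 1.5]), mu=0.0, S0=0.01, R0=0.0, t_snapshots=[2.0, 10.0, 25.0]
        )
        assert (diffs["delta_rate"] <= 1e-12).all()
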