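"""Core model: transition rate, integration, derived quantities, oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

from mscgrowth import (
    InitialComposition,
    ModelParameters,
    NoCrossingError,
    closed_form_constant_rate,
    cumulative_pd_from_folds,
    dividing_fraction,
    half_dividing_time,
    population_doublings,
    semi_analytic_states,
    simulate,
    stability_onset,
    stationary_pd,
    transition_rate,
)

LOG2_E = math.log2(math.e)


def grid(t_end, n):
    return np.linspace(0.0, t_end, n)


@st.composite
def feasible_params(draw):
    r1 = draw(st.floats(0.05, 0.6))
    r20 = draw(st.floats(0.005, 0.1))
    L = r1 + draw(st.floats(0.01, 0.3)) * (1.0 - r1)
    k = draw(st.floats(0.05, 0.9))
    T = draw(st.floats(20.0, 120.0))
    return ModelParameters(r1=r1, r20=r20, L=L, k=k, T=T)


class TestTransitionRate:
    def test_midpoint_is_half_the_upper_bound(self, all_conditions):
        for params in all_conditions.values():
            assert transition_rate(params, params.T) == pytest.approx(params.L / 2)
        # experiment A normoxia: L = 0.3588 gives rate 0.1794 at the midpoint
        assert transition_rate(all_conditions["expA-normoxia"], 47.3494) == pytest.approx(
            0.1794, abs=1e-10
        )

    def test_monotone_and_bounded(self, expa_normoxia):
        # window where the sigmoid is not yet saturated in double precision
        t = np.linspace(-50, 120, 341)
        r = transition_rate(expa_normoxia, t)
        assert np.all(np.diff(r) > 0)
        assert np.all((r > 0) & (r < expa_normoxia.L))

    def test_steep_curve_approaches_a_step(self):
        p = ModelParameters(r1=0.3, r20=0.02, L=0.5, k=0.95, T=50.0)
        assert transition_rate(p, p.T - 10) < 1e-4 * p.L
        assert transition_rate(p, p.T + 10) > (1 - 1e-4) * p.L


class TestParameterValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(r1=0.0, r20=0.01, L=0.3, k=0.3, T=50),
            dict(r1=1.0, r20=0.01, L=0.3, k=0.3, T=50),
            dict(r1=0.3, r20=0.0, L=0.4, k=0.3, T=50),
            dict(r1=0.3, r20=0.01, L=0.3, k=0.3, T=50),  # L must exceed r1
            dict(r1=0.3, r20=0.01, L=1.0, k=0.3, T=50),
            dict(r1=0.3, r20=0.01, L=0.4, k=1.0, T=50),
            dict(r1=0.3, r20=0.01, L=0.4, k=-0.1, T=50),
            dict(r1=0.3, r20=0.01, L=0.4, k=0.3, T=0.0),
        ],
    )
    def test_infeasible_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ModelParameters(**kwargs)

    def test_k_zero_is_allowed(self):
        p = ModelParameters(r1=0.3, r20=0.01, L=0.4, k=0.0, T=50.0)
        assert transition_rate(p, 0.0) == pytest.approx(p.L / 2)
        assert transition_rate(p, 1000.0) == pytest.approx(p.L / 2)

    def test_initial_composition_validation(self):
        with pytest.raises(ValueError):
            InitialComposition(dividing0=-1.0, nondividing0=0.0)
        with pytest.raises(ValueError):
            InitialComposition(dividing0=0.0, nondividing0=0.0)


class TestClosedFormConstantRate:
    def test_no_transition_is_pure_exponential_growth(self):
        init = InitialComposition(1.0, 0.0)
        t = np.array([0.0, 5.0, 10.0])
        x1, x2 = closed_form_constant_rate(0.3, 0.02, 0.0, init, t)
        assert x1 == pytest.approx(np.exp(0.3 * t))
        assert x2 == pytest.approx(np.zeros_like(t))

    def test_stationary_dividing_pool(self):
        # r1 = c: dividing cells are replaced exactly as fast as they leave
        r1 = c = 0.2
        r20 = 0.05
        t = np.array([0.0, 3.0, 30.0])
        x1, x2 = closed_form_constant_rate(r1, r20, c, InitialComposition(1.0, 0.0), t)
        assert x1 == pytest.approx(np.ones_like(t))
        assert x2 == pytest.approx((c / r20) * (1 - np.exp(-r20 * t)))

    def test_confluent_eigenvalue_case(self):
        # r1 - c = -r20 exercises the repeated-eigenvalue formula
        r1, c, r20 = 0.1, 0.15, 0.05
        t = np.array([0.0, 2.0, 10.0])
        x1, x2 = closed_form_constant_rate(r1, r20, c, InitialComposition(1.0, 0.5), t)
        assert x1 == pytest.approx(np.exp(-r20 * t))
        assert x2 == pytest.approx(0.5 * np.exp(-r20 * t) + c * t * np.exp(-r20 * t))

    def test_against_fixed_step_rk4(self):
        """Brute-force fixed-step integration reproduces the closed form."""
        r1, c, r20 = 0.3472, 0.1794, 0.0133
        h, t_end = 1e-3, 10.0
        x = np.array([1.0, 0.0])

        def f(x):
            return np.array([(r1 - c) * x[0], c * x[0] - r20 * x[1]])

        for _ in range(int(round(t_end / h))):
            k1 = f(x)
            k2 = f(x + 0.5 * h * k1)
            k3 = f(x + 0.5 * h * k2)
            k4 = f(x + h * k3)
            x = x + (h / 6) * (k1 + 2 * k2 + 2 * k3 + k4)

        x1, x2 = closed_form_constant_rate(r1, r20, c, InitialComposition(1.0, 0.0), t_end)
        assert x[0] == pytest.approx(float(x1), rel=1e-9)
        assert x[1] == pytest.approx(float(x2), rel=1e-9)


class TestSimulate:
    def test_negligible_transition_gives_decoupled_growth(self):
        # push the logistic far into the future so r12 ~ 0 over the window
        p = ModelParameters(r1=0.3, r20=0.05, L=0.5, k=0.3, T=10_000.0)
        t = grid(30, 31)
        traj = simulate(p, InitialComposition(1.0, 0.0), t)
        assert traj.x1 == pytest.approx(np.exp(0.3 * t), rel=1e-6)
        assert np.all(np.abs(traj.x2) < 1e-6)

    def test_matches_constant_rate_oracle_for_k_zero(self, expa_normoxia):
        p = expa_normoxia.replace(k=0.0)
        t = grid(120, 241)
        traj = simulate(p, InitialComposition(), t)
        x1o, x2o = closed_form_constant_rate(p.r1, p.r20, p.L / 2, InitialComposition(), t)
        assert np.max(np.abs(traj.y - (x1o + x2o)) / (x1o + x2o)) < 1e-6

    def test_semi_analytic_path_matches_integrator(self, all_conditions):
        t = grid(200, 401)
        for params in all_conditions.values():
            traj = simulate(params, InitialComposition(), t)
            x1, x2 = semi_analytic_states(params, InitialComposition(), t)
            assert np.max(np.abs((x1 + x2) - traj.y) / traj.y) < 1e-6

    def test_pd_curve_shape_near_linear_then_plateau(self, expa_normoxia):
        t = grid(120, 1201)
        traj = simulate(expa_normoxia, InitialComposition(), t)
        early = t <= 30
        slope = np.polyfit(t[early], traj.pd[early], 1)[0]
        assert slope == pytest.approx(expa_normoxia.r1 * LOG2_E, rel=0.05)
        late = traj.pd[t >= 80]
        assert np.max(late) - np.min(late) < 0.05 * traj.pd.max()

    def test_grid_validation(self, expa_normoxia):
        with pytest.raises(ValueError):
            simulate(expa_normoxia, times=[1.0, 2.0])  # must start at 0
        with pytest.raises(ValueError):
            simulate(expa_normoxia, times=[0.0, 2.0, 2.0])

    @settings(max_examples=20, deadline=None)
    @given(params=feasible_params())
    def test_states_nonnegative_and_output_identity(self, params):
        traj = simulate(params, InitialComposition(0.9, 0.1), grid(200, 101))
        assert np.all(traj.x1 >= 0)
        assert np.all(traj.x2 >= -1e-9)
        np.testing.assert_array_equal(traj.y, traj.x1 + traj.x2)
        assert traj.pd[0] == 0.0

    def test_population_bounded_with_plateau_inside_horizon(self, all_conditions):
        t = grid(400, 1601)
        for params in all_conditions.values():
            traj = simulate(params, InitialComposition(), t)
            peak = int(np.argmax(traj.pd))
            assert np.isfinite(traj.pd.max())
            assert 0 < t[peak] < 400.0


class TestPdArithmetic:
    def test_population_doublings(self):
        assert population_doublings(8.0, 1.0) == pytest.approx(3.0)
        assert population_doublings(5.0, 5.0) == 0.0
        assert population_doublings(0.5, 1.0) == pytest.approx(-1.0)
        with pytest.raises(ValueError):
            population_doublings(-1.0, 1.0)
        with pytest.raises(ValueError):
            population_doublings(1.0, 0.0)

    @pytest.mark.parametrize(
        "folds, expected",
        [([2, 2, 2], [1, 2, 3]), ([1, 1], [0, 0]), ([4, 0.5], [2, 1])],
    )
    def test_cumulative_pd_from_folds(self, folds, expected):
        assert cumulative_pd_from_folds(folds) == pytest.approx(expected)

    def test_nonpositive_fold_rejected(self):
        with pytest.raises(ValueError):
            cumulative_pd_from_folds([2.0, 0.0])


class TestDividingFraction:
    def test_initial_fraction_matches_composition(self, expa_normoxia):
        t = grid(10, 11)
        traj = simulate(expa_normoxia, InitialComposition(1.0, 0.0), t)
        assert dividing_fraction(traj)[0] == 1.0
        traj = simulate(expa_normoxia, InitialComposition(0.9, 0.1), t)
        assert dividing_fraction(traj)[0] == pytest.approx(0.9)

    def test_fraction_collapses_after_the_transition(self, expa_normoxia, expa_hypoxia):
        # under hypoxia the dividing pool shrinks faster than the nondividing
        # pool dies (L - r1 > r20), so the fraction decays toward zero
        traj = simulate(expa_hypoxia, InitialComposition(), grid(400, 401))
        frac = dividing_fraction(traj)
        assert frac[-1] < 0.01
        assert np.all((frac >= 0) & (frac <= 1))
        # under normoxia r20 slightly exceeds L - r1, so the fraction bottoms
        # out near zero and creeps back at very long times; the collapse from
        # an all-dividing start is still near-total
        traj = simulate(expa_normoxia, InitialComposition(), grid(400, 401))
        assert dividing_fraction(traj).min() < 0.02


class TestHalfDividingTime:
    def test_refinement_agrees_with_dense_grid(self, expa_normoxia):
        t_half = half_dividing_time(expa_normoxia, horizon=120.0)
        t = grid(120, 12001)
        traj = simulate(expa_normoxia, InitialComposition(), t)
        frac = dividing_fraction(traj)
        coarse = t[np.argmax(frac < 0.5)]
        assert abs(t_half - coarse) < 0.05

    def test_no_crossing_is_signaled(self):
        p = ModelParameters(r1=0.3, r20=0.02, L=0.5, k=0.3, T=500.0)
        with pytest.raises(NoCrossingError):
            half_dividing_time(p, horizon=120.0)

    def test_initial_fraction_below_half_rejected(self, expa_normoxia):
        with pytest.raises(ValueError):
            half_dividing_time(expa_normoxia, InitialComposition(0.4, 0.6))


class TestStationaryPd:
    def test_vanishing_growth_rate_gives_no_doublings(self):
        p = ModelParameters(r1=1e-4, r20=0.02, L=0.3, k=0.3, T=50.0)
        assert stationary_pd(p, t_eval=200.0) < 0.01

    def test_equals_constant_rate_oracle_for_k_zero(self, expa_normoxia):
        p = expa_normoxia.replace(k=0.0)
        value = stationary_pd(p, t_eval=200.0)
        t = np.linspace(0.0, 200.0, 801)
        x1, x2 = closed_form_constant_rate(p.r1, p.r20, p.L / 2, InitialComposition(), t)
        oracle = np.max(np.log2(x1 + x2))
        assert value == pytest.approx(oracle, rel=1e-6)

    def test_warns_before_the_plateau(self, expa_normoxia):
        with pytest.warns(UserWarning):
            stationary_pd(expa_normoxia, t_eval=30.0)

    def test_monotone_in_midpoint_time(self, expa_normoxia):
        values = [
            stationary_pd(expa_normoxia.replace(T=T), t_eval=300.0)
            for T in (40.0, 60.0, 80.0, 100.0)
        ]
        assert np.all(np.diff(values) > 0)


class TestStabilityOnset:
    def test_midpoint_when_bound_is_twice_the_rate(self):
        p = ModelParameters(r1=0.25, r20=0.02, L=0.5, k=0.3, T=60.0)
        assert stability_onset(p) == pytest.approx(60.0)

    def test_closed_form_agrees_with_root_finding(self, expa_normoxia):
        t_c = stability_onset(expa_normoxia)
        assert t_c == pytest.approx(58.0749, abs=1e-3)
        root = brentq(
            lambda t: transition_rate(expa_normoxia, t) - expa_normoxia.r1, 0, 200
        )
        assert t_c == pytest.approx(root, abs=1e-9)

    def test_bound_barely_above_rate_pushes_onset_far_out(self):
        p = ModelParameters(r1=0.3, r20=0.02, L=0.3 * 1.0001, k=0.3, T=50.0)
        assert stability_onset(p) > p.T + 20

    def test_undefined_for_constant_rate(self):
        p = ModelParameters(r1=0.3, r20=0.02, L=0.4, k=0.0, T=50.0)
        with pytest.raises(ValueError):
            stability_onset(p)


class TestEarlyTimeLimit:
    @settings(max_examples=10, deadline=None)
    @given(r1=st.floats(0.1, 0.6))
    def test_pd_slope_is_r1_log2e_before_senescence(self, r1):
        p = ModelParameters(r1=r1, r20=0.02, L=r1 + 0.1 * (1 - r1), k=0.3, T=250.0)
        t = grid(30, 31)
        traj = simulate(p, InitialComposition(), t)
        slope = np.polyfit(t, traj.pd, 1)[0]
        assert slope == pytest.approx(r1 * LOG2_E, rel=0.01)
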