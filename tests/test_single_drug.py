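"""Growth laws, response-shape reduction and single-drug steady states."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp
from scipy.optimize import minimize_scalar

from ribocomb import (
    DrugKinetics,
    GrowthLaws,
    ResponseShape,
    alpha_crit,
    alpha_crit_numeric,
    bistable_window,
    dose_response_curve,
    inverse_dose_response,
    kinetics_from_shape,
    reduce_kinetics,
    single_drug_rhs,
    steady_state_growth,
)


class TestGrowthLaws:
    def test_derived_constants(self, laws):
        assert laws.delta_r == pytest.approx(46.5)
        assert laws.lambda_max == pytest.approx(0.06 * 46.5)

    def test_nutrient_and_inhibition_laws_meet_at_drug_free_growth(self, laws):
        # r_u + r_b = r_tot must hold with r_b = 0 at lambda = lambda0
        assert laws.r_tot(laws.lambda0) == pytest.approx(laws.r_u(laws.lambda0))

    @pytest.mark.parametrize(
        "kwargs",
        [dict(r_min=70.0), dict(lambda0=5.0), dict(kappa_t=-1.0), dict(lambda0=0.0)],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            GrowthLaws(**kwargs)


class TestReduceKinetics:
    def test_characteristic_rate_formula(self):
        # p_out=10/h, kappa_t=0.06, K_D=10 uM -> lambda0* = 2*sqrt(6)
        laws = GrowthLaws(lambda0=2.5)
        kin = DrugKinetics(p_in=100.0, p_out=10.0, k_on=100.0, k_off=1000.0)
        shape = reduce_kinetics(kin, laws)
        assert shape.lambda0_star == pytest.approx(2.0 * math.sqrt(6.0), rel=1e-12)
        assert shape.alpha == pytest.approx(2.0 * math.sqrt(6.0) / 2.5, rel=1e-12)
        assert shape.ic50 == pytest.approx(
            shape.ic50_star * (shape.alpha**2 + 1) / (2 * shape.alpha), rel=1e-12
        )

    def test_irreversible_binder_flagged(self, laws):
        kin = DrugKinetics(p_in=50.0, p_out=10.0, k_on=1000.0, k_off=0.0)
        shape = reduce_kinetics(kin, laws)
        assert shape.alpha == 0.0 and shape.irreversible
        # alpha->0 limit of IC50*(alpha^2+1)/(2 alpha) with IC50* ~ alpha
        assert shape.ic50 == pytest.approx(laws.delta_r * laws.lambda0 / (4 * 50.0))

    def test_high_alpha_ic50_ratio(self, laws):
        kin = kinetics_from_shape(ResponseShape.from_alpha(50.0, laws), laws)
        shape = reduce_kinetics(kin, laws)
        assert shape.ic50 / shape.ic50_star == pytest.approx(50.0 / 2.0, rel=1e-3)

    def test_round_trip_through_kinetics(self, laws):
        for alpha in [0.1, 0.46, 1.04, 4.0]:
            shape = ResponseShape.from_alpha(alpha, laws, ic50=2.5)
            back = reduce_kinetics(kinetics_from_shape(shape, laws), laws)
            assert back.alpha == pytest.approx(alpha, rel=1e-12)
            assert back.ic50 == pytest.approx(2.5, rel=1e-12)

    def test_zero_influx_rejected(self, laws):
        with pytest.raises(ValueError):
            reduce_kinetics(DrugKinetics(p_in=0.0, p_out=1.0, k_on=1.0, k_off=1.0), laws)


class TestInverseDoseResponse:
    @pytest.mark.parametrize("alpha", [0.0, 0.1, 1.0, 10.0])
    def test_drug_free_identity(self, alpha):
        assert inverse_dose_response(alpha, 1.0) == 0.0

    @pytest.mark.parametrize("alpha", [0.01, 0.3849, 2.0, 100.0])
    def test_ic50_normalization(self, alpha):
        assert inverse_dose_response(alpha, 0.5) == pytest.approx(1.0, rel=1e-14)

    def test_stationary_point_at_bifurcation(self):
        alpha = math.sqrt(4.0 / 27.0)
        assert inverse_dose_response(alpha, 1.0 / 3.0) == pytest.approx(32.0 / 31.0)
        eps = 1e-6
        slope = (
            inverse_dose_response(alpha, 1 / 3 + eps)
            - inverse_dose_response(alpha, 1 / 3 - eps)
        ) / (2 * eps)
        assert abs(slope) < 1e-5

    def test_domain_error(self):
        with pytest.raises(ValueError):
            inverse_dose_response(1.0, 0.0)


class TestSteadyStateGrowth:
    def test_no_drug_single_root(self):
        s = steady_state_growth(1.0, 0.0)
        assert len(s.roots) == 1 and s.upper == pytest.approx(1.0)

    def test_high_alpha_langmuir(self):
        s = steady_state_growth(100.0, 3.0)
        assert s.upper == pytest.approx(0.25, abs=1e-3)

    def test_bistable_three_roots_outer_stable(self):
        lo, hi = bistable_window(0.2)
        s = steady_state_growth(0.2, 0.5 * (lo + hi))
        stable = [st for _, st in s.roots]
        assert len(s.roots) == 3 and stable == [True, False, True]

    @pytest.mark.parametrize("alpha", [0.05, 0.2, 0.3849, 1.0, 8.0, 128.0])
    def test_roots_invert_closed_form(self, alpha):
        """Cross-check of cubic roots against the analytic c(y) (oracle equivalence)."""
        for c in np.linspace(0.0, 5.0, 41):
            for y, _ in steady_state_growth(alpha, c).roots:
                assert abs(inverse_dose_response(alpha, y) - c) < 1e-10

    @given(
        alpha=st.floats(0.02, 50.0),
        y=st.floats(0.01, 1.0),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_closed_form_and_cubic_are_mutually_inverse(self, alpha, y):
        c = inverse_dose_response(alpha, y)
        roots = [r for r, _ in steady_state_growth(alpha, c).roots]
        assert min(abs(r - y) for r in roots) < 1e-7


class TestBifurcation:
    def test_exact_value(self):
        assert alpha_crit() == pytest.approx(2.0 / (3.0 * math.sqrt(3.0)), rel=1e-15)
        assert round(alpha_crit(), 3) == 0.385

    def test_brute_force_fold_condition_oracle(self):
        # alpha_crit^2 = max of 4y^2(1-2y) on (0, 1/2), attained at y = 1/3
        res = minimize_scalar(
            lambda y: -4.0 * y**2 * (1.0 - 2.0 * y), bounds=(0.0, 0.5), method="bounded"
        )
        assert -res.fun == pytest.approx(4.0 / 27.0, rel=1e-9)
        assert res.x == pytest.approx(1.0 / 3.0, abs=1e-6)
        assert math.sqrt(-res.fun) == pytest.approx(alpha_crit(), rel=1e-9)

    def test_monotonicity_scan_brackets_same_value(self):
        assert alpha_crit_numeric(tol=1e-8) == pytest.approx(alpha_crit(), abs=1e-6)


class TestBistableWindow:
    def test_no_window_above_threshold(self):
        assert bistable_window(0.5) is None
        assert bistable_window(alpha_crit()) is None

    def test_zero_alpha_limit(self):
        assert bistable_window(0.0) == (0.0, 1.0)
        assert bistable_window(1e-6)[1] == pytest.approx(1.0, abs=1e-4)

    def test_window_matches_extremum_scan_oracle(self):
        """Window edges are the local extrema of c(y), found independently."""
        alpha = 0.2
        y = np.linspace(1e-4, 1.0 - 1e-9, 200001)
        c = inverse_dose_response(alpha, y)
        interior = slice(1, -1)
        is_max = (c[1:-1] > c[:-2]) & (c[1:-1] > c[2:])
        is_min = (c[1:-1] < c[:-2]) & (c[1:-1] < c[2:])
        c_hi = c[interior][is_max].max()
        c_lo = c[interior][is_min].min()
        lo, hi = bistable_window(alpha)
        assert lo == pytest.approx(c_lo, rel=1e-6)
        assert hi == pytest.approx(c_hi, rel=1e-6)
        # the stationary (inflection-adjacent) concentration lies inside
        assert lo < inverse_dose_response(alpha, 1.0 / 3.0) < hi


class TestDoseResponseCurve:
    def test_shallow_curve_smooth_monotone(self):
        crv = dose_response_curve(4.0, np.linspace(0, 3, 61))
        assert crv.growth[0] == pytest.approx(1.0)
        assert np.all(np.diff(crv.growth) < 0)
        assert np.max(-np.diff(crv.growth)) < 0.05  # no abrupt drop

    def test_steep_curve_drops_at_window_edge(self):
        alpha = 2.0**-5
        _, hi = bistable_window(alpha)
        grid = np.linspace(0, 2, 201)
        crv = dose_response_curve(alpha, grid)
        drops = -np.diff(crv.growth)
        k = np.argmax(drops)
        assert drops[k] > 0.4  # discontinuous fall from upper branch
        assert grid[k] <= hi <= grid[k + 1] + 1e-9
        assert crv.branch[k] == "upper" and crv.branch[k + 1] == "lower"

    def test_irreversible_curve_arrests_past_unity(self):
        crv = dose_response_curve(0.0, np.array([0.0, 0.5, 0.99, 1.5]))
        assert crv.growth[0] == 1.0
        assert crv.growth[1] == pytest.approx((1 + math.sqrt(0.5)) / 2)
        assert crv.growth[3] == 0.0


class TestKineticODE:
    def test_drug_free_fixed_point(self, laws):
        kin = kinetics_from_shape(ResponseShape.from_alpha(1.0, laws), laws)
        state = (0.0, laws.r_min + laws.lambda0 / laws.kappa_t, 0.0)
        assert np.allclose(single_drug_rhs(state, 0.0, kin, laws), 0.0, atol=1e-9)

    def test_irreversible_bound_pool_only_dilutes(self, laws):
        kin = DrugKinetics(p_in=10.0, p_out=10.0, k_on=100.0, k_off=0.0)
        a, r_u, r_b = 0.3, 40.0, 5.0
        lam = laws.growth_rate(r_u)
        _, _, drb = single_drug_rhs((a, r_u, r_b), 1.0, kin, laws)
        assert drb == pytest.approx(-lam * r_b + kin.k_on * a * (r_u - laws.r_min))

    def test_integration_reaches_reduced_fixed_point(self, laws):
        """Time integration from a drug-free inoculum lands on the upper branch."""
        from ribocomb import PairSystem, pair_steady_state

        shape = ResponseShape.from_alpha(1.0, laws)
        kin = kinetics_from_shape(shape, laws)
        a_ex = 0.8 * shape.ic50
        x0 = [0.0, laws.r_min + laws.lambda0 / laws.kappa_t, 0.0]
        sol = solve_ivp(
            lambda t, x: single_drug_rhs(x, a_ex, kin, laws),
            (0.0, 2000.0),
            x0,
            method="LSODA",
            rtol=1e-12,
            atol=1e-12,
        )
        y_ode = laws.growth_rate(sol.y[1, -1]) / laws.lambda0
        y_fixed, _ = pair_steady_state((a_ex, 0.0), PairSystem.from_alphas(1.0, 1.0, laws=laws))
        assert abs(y_ode - y_fixed) < 1e-8
        # the reduced cubic is the rapid-kinetics limit of the same fixed point
        assert y_ode == pytest.approx(steady_state_growth(1.0, 0.8).upper, abs=2e-3)

    @pytest.mark.parametrize("alpha,c", [(2.0**7, 5.0), (1.0, 1.5)])
    def test_limit_curves(self, alpha, c):
        y = steady_state_growth(alpha, c).upper
        if alpha > 1:
            assert y == pytest.approx(1 / (1 + c), abs=1e-3)
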