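"""Two-drug kinetic system, steady-state surfaces, additivity and slow-growth limits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from ribocomb import (
    BindingModifiers,
    GrowthLaws,
    PairSystem,
    additivity_certificate,
    c_prime,
    pair_rhs,
    pair_steady_state,
    pair_steady_states_all,
    single_drug_rhs,
    slow_growth_y,
    steady_state_growth,
    surface,
)


class TestPairRHS:
    def test_reduces_to_single_drug_without_second_drug(self, laws):
        sys = PairSystem.from_alphas(1.0, 0.5, laws=laws)
        a, r_u, r_b = 0.4, 40.0, 6.0
        single = single_drug_rhs((a, r_u, r_b), 1.2, sys.kin_a, laws)
        full = pair_rhs((a, 0.0, r_b, 0.0, 0.0, r_u), (1.2, 0.0),
                        sys.kin_a, sys.kin_b, sys.deltas, laws)
        assert full[0] == pytest.approx(single[0])
        assert full[2] == pytest.approx(single[2])
        assert full[5] == pytest.approx(single[1])
        assert full[1] == full[3] == full[4] == 0.0

    def test_competitive_binding_keeps_double_pool_empty(self, laws):
        sys = PairSystem.from_alphas(1.0, 1.0, BindingModifiers.competitive(), laws)
        rhs = pair_rhs((0.5, 0.7, 4.0, 3.0, 0.0, 40.0), (1.0, 1.0),
                       sys.kin_a, sys.kin_b, sys.deltas, laws)
        assert rhs[4] == 0.0  # r_d has no source

    def test_ribosome_mass_balance(self, laws):
        """Binding fluxes cancel in the total ribosome budget."""
        sys = PairSystem.from_alphas(0.7, 2.0, BindingModifiers.symmetric(3.0), laws)
        state = (0.5, 0.7, 4.0, 3.0, 1.0, 40.0)
        rhs = pair_rhs(state, (1.0, 2.0), sys.kin_a, sys.kin_b, sys.deltas, laws)
        pools = state[2] + state[3] + state[4] + state[5]
        lam = laws.growth_rate(state[5])
        # binding fluxes are ~1e6 uM/h, so their cancellation leaves ~1e-9 noise
        assert rhs[2] + rhs[3] + rhs[4] + rhs[5] == pytest.approx(
            -lam * pools + laws.synthesis(lam), abs=1e-6
        )


class TestPairSteadyState:
    def test_boundary_matches_single_drug(self, laws):
        sys = PairSystem.from_alphas(1.0, 2.0, laws=laws)
        y, _ = pair_steady_state(sys.a_ex(1.5, 0.0), sys)
        assert y == pytest.approx(steady_state_growth(1.0, 1.5).upper, abs=1e-3)

    def test_fixed_point_satisfies_kinetics_and_ribosome_budget(self, laws):
        sys = PairSystem.from_alphas(0.7, 1.3, BindingModifiers.symmetric(2.0), laws)
        a_ex = sys.a_ex(0.8, 1.1)
        y, state = pair_steady_state(a_ex, sys)
        rhs = np.array(pair_rhs(state.as_array(), a_ex, sys.kin_a, sys.kin_b,
                                sys.deltas, laws))
        assert np.max(np.abs(rhs)) < 1e-8 * (1 + laws.synthesis(y * laws.lambda0))
        assert state.ribosome_total == pytest.approx(
            laws.r_tot(y * laws.lambda0), rel=1e-9
        )

    def test_self_combination_is_additive(self, laws):
        """The same drug on both axes: y depends only on the summed dose."""
        sys = PairSystem.from_alphas(1.0, 1.0, BindingModifiers.competitive(), laws)
        y_mix, _ = pair_steady_state(sys.a_ex(0.5, 0.7), sys)
        y_sum, _ = pair_steady_state(sys.a_ex(1.2, 0.0), sys)
        assert y_mix == pytest.approx(y_sum, abs=1e-9)

    def test_integration_fallback_consistency(self, laws):
        """Time integration of the full 6-D system lands on the reported root."""
        deltas = BindingModifiers.symmetric(2.0)
        sys = PairSystem.from_alphas(1.0, 0.5, deltas, laws)
        a_ex = sys.a_ex(0.7, 0.9)
        x0 = [0, 0, 0, 0, 0, laws.r_min + laws.lambda0 / laws.kappa_t]
        sol = solve_ivp(
            lambda t, x: np.array(pair_rhs(x, a_ex, sys.kin_a, sys.kin_b, deltas, laws)),
            (0.0, 2000.0), x0, method="LSODA", rtol=1e-12, atol=1e-12,
        )
        y_ode = laws.growth_rate(sol.y[5, -1]) / laws.lambda0
        y_fix, _ = pair_steady_state(a_ex, sys)
        assert abs(y_ode - y_fix) < 1e-8

    def test_stability_flags_match_jacobian(self, laws):
        """1-D slope criterion agrees with the eigenvalues of the 6-D Jacobian."""
        sys = PairSystem.from_alphas(2.0**-5, 2.0**-5,
                                     BindingModifiers.competitive(), laws)
        a_ex = sys.a_ex(0.45, 0.45)  # inside the bistable window of the sum
        roots = pair_steady_states_all(a_ex, sys)
        assert len(roots) == 3
        for y, stable in roots:
            if y <= 0:
                continue
            _, state = _state_at(y, a_ex, sys)
            jac = _numeric_jacobian(state, a_ex, sys)
            leading = np.max(np.linalg.eigvals(jac).real)
            assert (leading < 0) == bool(stable)


def _state_at(y, a_ex, sys):
    from ribocomb.pair import _pools, _solve_drugs

    lam = y * sys.laws.lambda0
    a_a, a_b = _solve_drugs(np.array(y), a_ex[0], a_ex[1], sys)
    r_ba, r_bb, r_d = (float(v) for v in _pools(float(a_a), float(a_b), lam, sys))
    return lam, np.array([float(a_a), float(a_b), r_ba, r_bb, r_d, sys.laws.r_u(lam)])


def _numeric_jacobian(state, a_ex, sys, eps=1e-7):
    f0 = np.array(pair_rhs(state, a_ex, sys.kin_a, sys.kin_b, sys.deltas, sys.laws))
    jac = np.empty((6, 6))
    for j in range(6):
        x = state.copy()
        h = eps * (abs(x[j]) + 1e-9)
        x[j] += h
        jac[:, j] = (
            np.array(pair_rhs(x, a_ex, sys.kin_a, sys.kin_b, sys.deltas, sys.laws)) - f0
        ) / h
    return jac


class TestSurface:
    def test_origin_and_boundaries(self, laws):
        sys = PairSystem.from_alphas(1.0, 2.0, laws=laws)
        g = np.linspace(0, 2, 9)
        surf = surface(sys, g, g)
        assert surf.y[0, 0] == 1.0
        assert np.all((surf.y >= 0) & (surf.y <= 1))
        for i, c in enumerate(g):
            y_single, _ = pair_steady_state(sys.a_ex(c, 0.0), sys)
            assert surf.y[i, 0] == pytest.approx(y_single, abs=1e-9)

    def test_swap_symmetry(self, laws):
        deltas = BindingModifiers(1.5, 0.7, 1.0, 1.2)
        sys = PairSystem.from_alphas(0.5, 2.0, deltas, laws)
        g = np.linspace(0, 2, 7)
        direct = surface(sys, g, g)
        swapped = surface(sys.swapped(), g, g)
        assert np.allclose(direct.y, swapped.y.T, atol=1e-8)


class TestAdditivityCertificate:
    def test_linear_isoboles_for_competitive_binding(self, laws):
        sys = PairSystem.from_alphas(1.0, 2.0, BindingModifiers.competitive(), laws)
        cert = additivity_certificate(sys, 0.5 * laws.lambda0)
        assert cert.isobole_gap < 1e-6

    def test_transport_coefficient_closed_form(self, laws):
        sys = PairSystem.from_alphas(1.0, 2.0, BindingModifiers.competitive(), laws)
        cert = additivity_certificate(sys, 0.4)
        kin = sys.kin_a
        lam = 0.4
        xi = kin.k_on * lam / ((kin.k_off + lam) * laws.kappa_t)
        assert cert.xi_a == pytest.approx(xi, rel=1e-12)
        ups = kin.p_in / (lam * (kin.k_on / laws.kappa_t + 1) + kin.p_out - xi * kin.k_off)
        assert cert.upsilon_a == pytest.approx(ups, rel=1e-12)

    def test_high_alpha_isobole_in_ic50_units(self, laws):
        """For shallow drugs the isobole reduces to c_A + c_B = lambda0/lambda - 1."""
        sys = PairSystem.from_alphas(30.0, 30.0, BindingModifiers.competitive(), laws)
        lam = 0.4 * laws.lambda0
        cert = additivity_certificate(sys, lam)
        rhs = laws.delta_r * (1 - lam / laws.lambda0)
        intercept_c = rhs / (cert.upsilon_a * cert.xi_a) / sys.shape_a.ic50
        assert intercept_c == pytest.approx(laws.lambda0 / lam - 1.0, rel=1e-2)

    def test_unreachable_growth_rejected(self, laws):
        sys = PairSystem.from_alphas(1.0, 1.0, laws=laws)
        with pytest.raises(ValueError):
            additivity_certificate(sys, 2.0 * laws.lambda0)


class TestSlowGrowthLimit:
    def test_rescaled_concentration_arithmetic(self):
        laws = GrowthLaws(lambda0=0.06 * 46.5 / 2.0)  # lambda_max / lambda0 = 2
        assert c_prime(1.0, 1.0, laws) == pytest.approx(4.0)
        assert c_prime(0.0, 1.0, laws) == 0.0
        with pytest.raises(ValueError):
            c_prime(1.0, 0.0, laws)

    def test_langmuir_product_limit(self):
        laws = GrowthLaws(lambda0=0.06 * 46.5)
        cp = c_prime(np.array([0.5, 1.0]), 1e6, laws)
        assert np.allclose(cp, [0.5, 1.0], rtol=1e-10)
        y = slow_growth_y(1.0, 2.0, BindingModifiers.independent(), laws)
        assert y == pytest.approx(1.0 / (2.0 * 3.0))

    @given(
        cpa=st.floats(0.0, 20.0),
        cpb=st.floats(0.0, 20.0),
        delta=st.floats(0.0, 8.0),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_symmetric_on_modifier_closed_form(self, cpa, cpb, delta, laws):
        """General formula collapses to 1/(1+c'_A+c'_B+delta c'_A c'_B)."""
        y = slow_growth_y(cpa, cpb, BindingModifiers.symmetric(delta), laws)
        expected = (laws.lambda_max / laws.lambda0) / (
            1.0 + cpa + cpb + delta * cpa * cpb
        )
        assert y == pytest.approx(expected, rel=1e-12)

    def test_blocked_unbinding_gives_zero_growth(self, laws):
        y = slow_growth_y(1.0, 1.0, BindingModifiers(1, 1, 0, 0), laws)
        assert y == 0.0

    def test_competitive_gives_loewe_form(self, laws):
        y = slow_growth_y(2.0, 3.0, BindingModifiers.competitive(), laws)
        assert y == pytest.approx((laws.lambda_max / laws.lambda0) / 6.0, rel=1e-12)

    def test_agrees_with_full_numerics_when_shallow_and_slow(self, laws):
        """High-alpha, strong-inhibition corner: Bliss-like product is accurate."""
        al = 8.0
        sys = PairSystem.from_alphas(al, al, laws=laws)
        c = 2.5
        y_full, _ = pair_steady_state(sys.a_ex(c, c), sys)
        y_approx = (laws.lambda_max / laws.lambda0) / (
            (1 + c_prime(c, al, laws)) * (1 + c_prime(c, al, laws))
        )
        assert y_full == pytest.approx(y_approx, rel=0.1)
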