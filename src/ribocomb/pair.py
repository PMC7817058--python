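"""Two-drug mass-action model and its steady-state dose-response surfaces.

Each ribosome can be free, bound by drug A, bound by drug B, or double
bound; the second binding step is scaled by dimensionless modifiers
``delta_on_i`` / ``delta_off_i`` (1 = independent binding, ``delta_on = 0``
= competitive binding, no double-bound pool).  Growth feeds back through
the same growth laws as the single-drug model.

Steady states are found by a one-dimensional reduction: for a trial
relative growth rate ``y`` the drug and ribosome-pool balances are solved
algebraically (a 2-D Newton iteration in the intracellular drug levels,
with the three ribosome pools eliminated in closed form), leaving a scalar
residual in the unbound-ribosome balance whose zeros are the fixed points
of the full six-dimensional system.  The reported value is the largest
root — the upper branch that dominates batch cultures.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

from .single_drug import (
    DrugKinetics,
    GrowthLaws,
    ResponseShape,
    kinetics_from_shape,
    reduce_kinetics,
)

__all__ = [
    "BindingModifiers",
    "PairState",
    "PairSystem",
    "DoseResponseSurface",
    "AdditivityCertificate",
    "SlowGrowthTerms",
    "pair_rhs",
    "pair_steady_state",
    "pair_steady_states_all",
    "surface",
    "additivity_certificate",
    "c_prime",
    "slow_growth_terms",
    "slow_growth_y",
    "slow_growth_surface",
]


@dataclass(frozen=True)
class BindingModifiers:
    """Relative change of binding rates on a ribosome already holding the other drug."""

    delta_on_a: float = 1.0
    delta_on_b: float = 1.0
    delta_off_a: float = 1.0
    delta_off_b: float = 1.0

    def __post_init__(self) -> None:
        if min(self.delta_on_a, self.delta_on_b, self.delta_off_a, self.delta_off_b) < 0:
            raise ValueError("delta modifiers must be >= 0")

    @classmethod
    def independent(cls) -> "BindingModifiers":
        return cls(1.0, 1.0, 1.0, 1.0)

    @classmethod
    def competitive(cls) -> "BindingModifiers":
        """No double-bound ribosomes can form (same binding site)."""
        return cls(0.0, 0.0, 1.0, 1.0)

    @classmethod
    def symmetric(cls, delta_on: float, delta_off: float = 1.0) -> "BindingModifiers":
        return cls(delta_on, delta_on, delta_off, delta_off)

    @property
    def is_competitive(self) -> bool:
        return self.delta_on_a == 0.0 and self.delta_on_b == 0.0

    def swapped(self) -> "BindingModifiers":
        return BindingModifiers(
            self.delta_on_b, self.delta_on_a, self.delta_off_b, self.delta_off_a
        )


@dataclass(frozen=True)
class PairState:
    """Intracellular drug levels and ribosome pools (all uM)."""

    a_a: float
    a_b: float
    r_u: float
    r_b_a: float
    r_b_b: float
    r_d: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.a_a, self.a_b, self.r_b_a, self.r_b_b, self.r_d, self.r_u]
        )

    @property
    def ribosome_total(self) -> float:
        return self.r_u + self.r_b_a + self.r_b_b + self.r_d


@dataclass(frozen=True)
class PairSystem:
    """A drug pair: kinetics, response shapes, binding modifiers, growth laws.

    ``removal`` optionally attaches one growth-coupled resistance-enzyme
    flux per drug as ``((v_max_prime, k_rem) or None, ...)``; see the
    resistance-gene module.
    """

    laws: GrowthLaws
    kin_a: DrugKinetics
    kin_b: DrugKinetics
    deltas: BindingModifiers = field(default_factory=BindingModifiers.independent)
    shape_a: ResponseShape | None = None
    shape_b: ResponseShape | None = None
    removal: tuple[tuple[float, float] | None, tuple[float, float] | None] = (None, None)

    def __post_init__(self) -> None:
        if self.shape_a is None:
            object.__setattr__(self, "shape_a", reduce_kinetics(self.kin_a, self.laws))
        if self.shape_b is None:
            object.__setattr__(self, "shape_b", reduce_kinetics(self.kin_b, self.laws))

    @classmethod
    def from_alphas(
        cls,
        alpha_a: float,
        alpha_b: float,
        deltas: BindingModifiers | None = None,
        laws: GrowthLaws | None = None,
        ic50: float = 1.0,
    ) -> "PairSystem":
        """Pair specified by response parameters only (IC50s placed at ``ic50`` uM)."""
        laws = laws or GrowthLaws()
        sa = ResponseShape.from_alpha(alpha_a, laws, ic50)
        sb = ResponseShape.from_alpha(alpha_b, laws, ic50)
        return cls(
            laws=laws,
            kin_a=kinetics_from_shape(sa, laws),
            kin_b=kinetics_from_shape(sb, laws),
            deltas=deltas or BindingModifiers.independent(),
            shape_a=sa,
            shape_b=sb,
        )

    def swapped(self) -> "PairSystem":
        return PairSystem(
            laws=self.laws,
            kin_a=self.kin_b,
            kin_b=self.kin_a,
            deltas=self.deltas.swapped(),
            shape_a=self.shape_b,
            shape_b=self.shape_a,
            removal=(self.removal[1], self.removal[0]),
        )

    def with_removal(self, rem_a, rem_b) -> "PairSystem":
        return replace(self, removal=(rem_a, rem_b))

    def a_ex(self, c_a: float, c_b: float) -> tuple[float, float]:
        """Extracellular concentrations (uM) from IC50-normalized ones."""
        return (c_a * self.shape_a.ic50, c_b * self.shape_b.ic50)


def pair_rhs(state, a_ex, kin_a: DrugKinetics, kin_b: DrugKinetics,
             deltas: BindingModifiers, laws: GrowthLaws, removal=(None, None)):
    """Time derivatives (da_A, da_B, dr_bA, dr_bB, dr_d, dr_u) of the pair model.

    State order ``(a_A, a_B, r_bA, r_bB, r_d, r_u)``.  The cross terms are
    ``delta_on_i * k_on_i * a_i * r_b_ibar`` (drug i binding a ribosome
    holding the other drug) and ``delta_off_i * k_off_i * r_d`` (drug i
    leaving a double-bound ribosome).  Optional ``removal`` fluxes are
    subtracted from the drug balances.
    """
    a_a, a_b, r_ba, r_bb, r_d, r_u = state
    lam = laws.growth_rate(r_u)
    f_a = kin_a.binding(r_u, r_ba, a_a, laws.r_min)
    f_b = kin_b.binding(r_u, r_bb, a_b, laws.r_min)
    on_a = deltas.delta_on_a * kin_a.k_on * a_a * r_bb
    on_b = deltas.delta_on_b * kin_b.k_on * a_b * r_ba
    off_a = deltas.delta_off_a * kin_a.k_off * r_d
    off_b = deltas.delta_off_b * kin_b.k_off * r_d
    rem_a = rem_b = 0.0
    if removal[0] is not None:
        v, krem = removal[0]
        rem_a = v * (lam / laws.lambda0) * a_a / (a_a + krem)
    if removal[1] is not None:
        v, krem = removal[1]
        rem_b = v * (lam / laws.lambda0) * a_b / (a_b + krem)
    da_a = -lam * a_a + f_a + off_a - on_a + kin_a.influx(a_ex[0], a_a) - rem_a
    da_b = -lam * a_b + f_b + off_b - on_b + kin_b.influx(a_ex[1], a_b) - rem_b
    dr_ba = -lam * r_ba - f_a + off_b - on_b
    dr_bb = -lam * r_bb - f_b + off_a - on_a
    dr_d = -lam * r_d + on_a + on_b - off_a - off_b
    dr_u = -lam * r_u + f_a + f_b + laws.synthesis(lam)
    return (da_a, da_b, dr_ba, dr_bb, dr_d, dr_u)


# ---------------------------------------------------------------------------
# Steady-state reduction: algebraic inner solve at fixed y
# ---------------------------------------------------------------------------


def _pools(a_a, a_b, lam, sys: PairSystem):
    """Ribosome pools (r_bA, r_bB, r_d) at fixed growth and drug levels.

    The three pool balances are linear in the pools; eliminated in closed
    form.  The effective double-bound drain ``lam + q_A + q_B - ...`` is
    bounded below by ``lam``, so the expressions stay positive.
    """
    ka, kb, d = sys.kin_a, sys.kin_b, sys.deltas
    u = lam / sys.laws.kappa_t
    w_a = d.delta_on_a * ka.k_on * a_a
    w_b = d.delta_on_b * kb.k_on * a_b
    q_a = d.delta_off_a * ka.k_off
    q_b = d.delta_off_b * kb.k_off
    m_a = lam + ka.k_off + w_b
    m_b = lam + kb.k_off + w_a
    b_a = ka.k_on * a_a * u
    b_b = kb.k_on * a_b * u
    denom = lam + q_a + q_b - w_a * q_a / m_b - w_b * q_b / m_a
    r_d = (w_a * b_b / m_b + w_b * b_a / m_a) / denom
    r_ba = (b_a + q_b * r_d) / m_a
    r_bb = (b_b + q_a * r_d) / m_b
    return r_ba, r_bb, r_d


def _drug_residuals(a_a, a_b, y, aex_a, aex_b, sys: PairSystem):
    """Steady-state drug balances F_A, F_B (zero at the fixed point)."""
    ka, kb, d = sys.kin_a, sys.kin_b, sys.deltas
    lam = y * sys.laws.lambda0
    u = lam / sys.laws.kappa_t
    r_ba, r_bb, r_d = _pools(a_a, a_b, lam, sys)
    q_a = d.delta_off_a * ka.k_off
    q_b = d.delta_off_b * kb.k_off
    f_a = (
        ka.p_in * aex_a
        - (lam + ka.p_out + ka.k_on * u) * a_a
        + ka.k_off * r_ba
        + q_a * r_d
        - d.delta_on_a * ka.k_on * a_a * r_bb
    )
    f_b = (
        kb.p_in * aex_b
        - (lam + kb.p_out + kb.k_on * u) * a_b
        + kb.k_off * r_bb
        + q_b * r_d
        - d.delta_on_b * kb.k_on * a_b * r_ba
    )
    if sys.removal[0] is not None:
        v, krem = sys.removal[0]
        f_a = f_a - v * y * a_a / (a_a + krem)
    if sys.removal[1] is not None:
        v, krem = sys.removal[1]
        f_b = f_b - v * y * a_b / (a_b + krem)
    return f_a, f_b


def _solve_drugs(y, aex_a, aex_b, sys: PairSystem, max_iter: int = 80, a0=None):
    """Intracellular drug levels at fixed y: vectorised 2-D damped Newton.

    Finite-difference Jacobian; axes with zero external drug are frozen at
    zero.  Broadcast over any common shape of ``y``/``aex``.  ``a0`` warm
    starts the iteration (e.g. from a neighbouring growth rate).
    """
    y, aex_a, aex_b = np.broadcast_arrays(
        np.asarray(y, float), np.asarray(aex_a, float), np.asarray(aex_b, float)
    )
    ka, kb = sys.kin_a, sys.kin_b
    lam = y * sys.laws.lambda0
    u = lam / sys.laws.kappa_t

    def seed(kin, aex):
        drain = lam + kin.p_out + kin.k_on * u * lam / (lam + kin.k_off + 1e-300)
        return kin.p_in * aex / np.maximum(drain, 1e-300)

    if a0 is not None:
        a_a = np.broadcast_to(a0[0], y.shape).copy()
        a_b = np.broadcast_to(a0[1], y.shape).copy()
        a_a = np.where(aex_a > 0, np.maximum(a_a, 1e-300), 0.0)
        a_b = np.where(aex_b > 0, np.maximum(a_b, 1e-300), 0.0)
    else:
        a_a = np.where(aex_a > 0, seed(ka, aex_a), 0.0)
        a_b = np.where(aex_b > 0, seed(kb, aex_b), 0.0)
    act_a = aex_a > 0
    act_b = aex_b > 0
    tol = 1e-11

    f_a, f_b = _drug_residuals(a_a, a_b, y, aex_a, aex_b, sys)
    stalled = np.zeros(y.shape, dtype=bool)
    for _ in range(max_iter):
        # the residual is a difference of terms of size ~k_on*u*a, so its
        # attainable accuracy is bounded by the cancellation floor
        floor_a = 1e-11 + 2e-13 * (ka.p_in * aex_a + (lam + ka.p_out + ka.k_on * u) * a_a)
        floor_b = 1e-11 + 2e-13 * (kb.p_in * aex_b + (lam + kb.p_out + kb.k_on * u) * a_b)
        scale_a = 1.0 + ka.p_in * aex_a
        scale_b = 1.0 + kb.p_in * aex_b
        conv = (
            (np.abs(f_a) < tol * scale_a + floor_a)
            & (np.abs(f_b) < tol * scale_b + floor_b)
        ) | stalled
        if conv.all():
            break
        h_a = 1e-7 * (np.abs(a_a) + 1e-9)
        h_b = 1e-7 * (np.abs(a_b) + 1e-9)
        f_a1, f_b1 = _drug_residuals(a_a + h_a, a_b, y, aex_a, aex_b, sys)
        f_a2, f_b2 = _drug_residuals(a_a, a_b + h_b, y, aex_a, aex_b, sys)
        j11 = np.where(act_a, (f_a1 - f_a) / h_a, -1.0)
        j21 = np.where(act_a & act_b, (f_b1 - f_b) / h_a, 0.0)
        j12 = np.where(act_a & act_b, (f_a2 - f_a) / h_b, 0.0)
        j22 = np.where(act_b, (f_b2 - f_b) / h_b, -1.0)
        det = j11 * j22 - j12 * j21
        det = np.where(np.abs(det) < 1e-300, 1e-300, det)
        d_a = np.where(act_a, (f_a * j22 - f_b * j12) / det, 0.0)
        d_b = np.where(act_b, (j11 * f_b - j21 * f_a) / det, 0.0)
        new_a = a_a - d_a
        new_b = a_b - d_b
        # positivity: fall back to halving instead of crossing zero
        new_a = np.where(new_a <= 0, a_a * 0.5, new_a)
        new_b = np.where(new_b <= 0, a_b * 0.5, new_b)
        g_a, g_b = _drug_residuals(new_a, new_b, y, aex_a, aex_b, sys)
        worse = (np.abs(g_a) / scale_a + np.abs(g_b) / scale_b) > 2.0 * (
            np.abs(f_a) / scale_a + np.abs(f_b) / scale_b
        )
        if worse.any():
            half_a = np.where(worse, 0.5 * (a_a + new_a), new_a)
            half_b = np.where(worse, 0.5 * (a_b + new_b), new_b)
            new_a, new_b = half_a, half_b
            g_a, g_b = _drug_residuals(new_a, new_b, y, aex_a, aex_b, sys)
        # points at the floating-point floor of the residual (terms of size
        # k_on*a*r can dwarf the balance) stop when the step is negligible
        stalled = (np.abs(new_a - a_a) <= 1e-12 * (np.abs(a_a) + 1e-300)) & (
            np.abs(new_b - a_b) <= 1e-12 * (np.abs(a_b) + 1e-300)
        )
        a_a, a_b, f_a, f_b = new_a, new_b, g_a, g_b
    return a_a, a_b


def _growth_residual(y, aex_a, aex_b, sys: PairSystem, a0=None, return_drugs=False):
    """Unbound-ribosome balance h(y); fixed points of the pair model are its zeros."""
    y = np.asarray(y, float)
    a_a, a_b = _solve_drugs(y, aex_a, aex_b, sys, a0=a0)
    lam = y * sys.laws.lambda0
    u = lam / sys.laws.kappa_t
    r_ba, r_bb, _ = _pools(a_a, a_b, lam, sys)
    f_a = -sys.kin_a.k_on * a_a * u + sys.kin_a.k_off * r_ba
    f_b = -sys.kin_b.k_on * a_b * u + sys.kin_b.k_off * r_bb
    h = -lam * (sys.laws.r_min + u) + f_a + f_b + sys.laws.synthesis(lam)
    if return_drugs:
        return h, (a_a, a_b)
    return h


_Y_FLOOR = 1e-6


def _scan_grid(n_scan: int) -> np.ndarray:
    low = np.geomspace(_Y_FLOOR, 0.04, 25)
    high = np.linspace(0.045, 1.0, n_scan)
    return np.concatenate([low, high])


def _hidden_bump_refine(grid, h, y0, scalar_h, margin: float = 0.02,
                        max_rounds: int = 3):
    """Recover root pairs hiding between scan points near a fold.

    Close to a saddle-node the upper and middle roots merge; when both
    fall inside one scan interval the endpoint signs miss them.  Columns
    whose residual has an interior local maximum above the detected root
    are re-examined: the bump is maximised in a narrow bracket and, if it
    pokes above zero, the upper root it hides becomes the new topmost
    root.  Returns the corrected ``y0`` (modified in place).
    """
    from scipy.optimize import minimize_scalar

    n_y, m = h.shape
    scale_h = np.maximum(np.max(np.abs(h), axis=0), 1e-300)

    # vectorised pre-filter: a sub-grid bump crossing zero leaves a local
    # parabolic signature in the smooth residual; skip columns whose
    # extrapolated vertex stays clearly below zero
    elig = grid[:, None] > y0[None, :] + margin
    masked = np.where(elig, h, -np.inf)
    k0 = np.argmax(masked, axis=0)
    first0 = np.argmax(elig, axis=0)
    has_elig = elig.any(axis=0)
    interior = (k0 > 0) & (k0 < n_y - 1)
    cols = np.arange(m)
    hk = h[k0, cols]
    hkm = h[np.maximum(k0 - 1, 0), cols]
    hkp = h[np.minimum(k0 + 1, n_y - 1), cols]
    denom = hkp - 2.0 * hk + hkm
    with np.errstate(divide="ignore", invalid="ignore"):
        vertex = np.where(denom < 0, hk - (hkp - hkm) ** 2 / (8.0 * denom), hk)
    candidate = (
        has_elig & interior & (k0 != first0) & (vertex > -1e-5 * scale_h)
    )

    for j in np.nonzero(candidate)[0]:
        cur = y0[j]
        hj = h[:, j]
        for _ in range(max_rounds):
            eligible = np.nonzero(grid > cur + margin)[0]
            if eligible.size < 3:
                break
            k = eligible[np.argmax(hj[eligible])]
            first = eligible[0]
            if k == first or hj[k] <= hj[first] + 1e-9 * scale_h[j]:
                break
            lo = grid[max(k - 1, 0)]
            hi = grid[min(k + 1, n_y - 1)]
            res = minimize_scalar(lambda yy: -scalar_h(yy, j), bounds=(lo, hi),
                                  method="bounded", options={"xatol": 1e-12})
            if -res.fun <= 0.0:
                break
            right = hi
            while scalar_h(right, j) > 0 and right < 1.0:
                right = min(1.0, right + (hi - lo))
            cur = brentq(lambda yy: scalar_h(yy, j), res.x, right, xtol=1e-14)
            y0[j] = cur
    return y0


def _upper_growth_row(aex_a, aex_b, sys: PairSystem, n_scan: int = 150,
                      n_bisect: int = 52):
    """Largest steady-state growth root for a row of concentration pairs.

    Scans h(y) on a fixed grid, brackets the topmost sign change per
    column and refines it by vectorised bisection.  Columns with no sign
    change have no positive steady state (growth arrested) and report 0.
    """
    aex_a = np.atleast_1d(np.asarray(aex_a, float))
    aex_b = np.atleast_1d(np.asarray(aex_b, float))
    aex_a, aex_b = np.broadcast_arrays(aex_a, aex_b)
    m = aex_a.size
    grid = _scan_grid(n_scan)
    n_y = grid.size
    h = np.empty((n_y, m))
    drugs_a = np.empty((n_y, m))
    drugs_b = np.empty((n_y, m))
    seed = None
    for k in range(n_y):  # sweep y upward, warm-starting from the previous level
        h[k], seed = _growth_residual(
            np.full(m, grid[k]), aex_a, aex_b, sys, a0=seed, return_drugs=True
        )
        drugs_a[k], drugs_b[k] = seed
    sign_change = h[:-1] * h[1:] <= 0
    has_root = sign_change.any(axis=0)
    # topmost bracket per column
    idx = sign_change.shape[0] - 1 - np.argmax(sign_change[::-1], axis=0)
    cols = np.arange(m)
    lo = grid[idx]
    hi = grid[idx + 1]
    s_lo = np.sign(h[idx, cols])
    s_lo = np.where(s_lo == 0, 1.0, s_lo)
    seed = (drugs_a[idx, cols], drugs_b[idx, cols])
    for _ in range(n_bisect):
        mid = 0.5 * (lo + hi)
        hm, seed = _growth_residual(mid, aex_a, aex_b, sys, a0=seed,
                                    return_drugs=True)
        same = np.sign(hm) == s_lo
        lo = np.where(same, mid, lo)
        hi = np.where(same, hi, mid)
    y = np.where(has_root, 0.5 * (lo + hi), 0.0)
    y = np.where((aex_a == 0) & (aex_b == 0), 1.0, y)

    def scalar_h(yy, j):
        return float(_growth_residual(yy, aex_a[j], aex_b[j], sys))

    return _hidden_bump_refine(grid, h, y, scalar_h)


def pair_steady_state(a_ex, sys: PairSystem) -> tuple[float, PairState]:
    """Upper-branch steady state at extracellular concentrations ``a_ex`` (uM).

    Returns the relative growth rate and the full state.  Raises if the
    assembled state does not satisfy the kinetic equations (residual norm
    above 1e-6 relative), which would indicate a failed inner solve.
    """
    aex_a, aex_b = float(a_ex[0]), float(a_ex[1])
    y = float(_upper_growth_row([aex_a], [aex_b], sys)[0])
    if y <= 0.0:
        return 0.0, PairState(0.0, 0.0, sys.laws.r_min, 0.0, 0.0, 0.0)
    lam = y * sys.laws.lambda0
    a_a, a_b = _solve_drugs(np.array(y), aex_a, aex_b, sys)
    a_a, a_b = float(a_a), float(a_b)
    r_ba, r_bb, r_d = (float(v) for v in _pools(a_a, a_b, lam, sys))
    state = PairState(a_a, a_b, sys.laws.r_u(lam), r_ba, r_bb, r_d)
    rhs = np.array(
        pair_rhs(state.as_array(), (aex_a, aex_b), sys.kin_a, sys.kin_b,
                 sys.deltas, sys.laws, sys.removal)
    )
    scale = 1.0 + abs(sys.laws.synthesis(lam)) + sys.kin_a.p_in * aex_a + sys.kin_b.p_in * aex_b
    if np.max(np.abs(rhs)) > 1e-6 * scale:
        raise RuntimeError(
            f"pair steady state did not converge at a_ex=({aex_a}, {aex_b}): "
            f"max residual {np.max(np.abs(rhs)):.3e}"
        )
    return y, state


def pair_steady_states_all(a_ex, sys: PairSystem, n_scan: int = 400):
    """All steady-state growth roots with 1-D stability flags.

    Stability follows the slope of the reduced residual: roots where h
    crosses from positive to negative (with y increasing) are stable,
    matching the sign-of-dc/dy criterion of the single-drug model.
    """
    aex_a, aex_b = float(a_ex[0]), float(a_ex[1])
    grid = _scan_grid(n_scan)
    h = _growth_residual(grid, aex_a, aex_b, sys)
    roots = []
    for i in range(len(grid) - 1):
        if h[i] == 0.0 and grid[i] == 1.0:
            roots.append((1.0, h[i - 1] > 0))
            continue
        if h[i] * h[i + 1] < 0 or (h[i + 1] == 0.0 and h[i] != 0.0):
            f = lambda yy: float(_growth_residual(yy, aex_a, aex_b, sys))
            y0 = brentq(f, grid[i], grid[i + 1], xtol=1e-14)
            roots.append((y0, h[i] > 0))
    return sorted(roots, key=lambda t: -t[0])


@dataclass(frozen=True)
class DoseResponseSurface:
    """Relative growth on a (c_A, c_B) grid; ``y[i, j] = y(c_a[i], c_b[j])``."""

    c_a: np.ndarray
    c_b: np.ndarray
    y: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "c_a", np.asarray(self.c_a, float))
        object.__setattr__(self, "c_b", np.asarray(self.c_b, float))
        object.__setattr__(self, "y", np.asarray(self.y, float))
        if self.y.shape != (self.c_a.size, self.c_b.size):
            raise ValueError("y must have shape (len(c_a), len(c_b))")

    def transposed(self) -> "DoseResponseSurface":
        return DoseResponseSurface(self.c_b.copy(), self.c_a.copy(), self.y.T.copy(),
                                   dict(self.meta))


def surface(sys: PairSystem, c_a_grid, c_b_grid,
            a_ex_grids: bool = False) -> DoseResponseSurface:
    """Dose-response surface of the pair model under the upper-branch policy.

    Grids are in IC50 units of each drug unless ``a_ex_grids`` is set, in
    which case they are extracellular concentrations in uM.
    """
    c_a_grid = np.asarray(c_a_grid, float)
    c_b_grid = np.asarray(c_b_grid, float)
    if np.any(c_a_grid < 0) or np.any(c_b_grid < 0):
        raise ValueError("concentration grids must be >= 0")
    if a_ex_grids:
        aex_a_grid, aex_b_grid = c_a_grid, c_b_grid
    else:
        aex_a_grid = c_a_grid * sys.shape_a.ic50
        aex_b_grid = c_b_grid * sys.shape_b.ic50
    mesh_a, mesh_b = np.meshgrid(aex_a_grid, aex_b_grid, indexing="ij")
    n = mesh_a.size
    # chunk the flattened grid to bound peak memory of the y-scan
    chunk = max(1, int(4e6 // _scan_grid(150).size))
    flat = np.empty(n)
    for start in range(0, n, chunk):
        sl = slice(start, min(start + chunk, n))
        flat[sl] = _upper_growth_row(mesh_a.ravel()[sl], mesh_b.ravel()[sl], sys)
    y = flat.reshape(mesh_a.shape)
    meta = {
        "alpha_a": sys.shape_a.alpha,
        "alpha_b": sys.shape_b.alpha,
        "ic50_a": sys.shape_a.ic50,
        "ic50_b": sys.shape_b.ic50,
        "deltas": [sys.deltas.delta_on_a, sys.deltas.delta_on_b,
                   sys.deltas.delta_off_a, sys.deltas.delta_off_b],
        "lambda0": sys.laws.lambda0,
        "units": "uM" if a_ex_grids else "ic50",
    }
    return DoseResponseSurface(c_a_grid, c_b_grid, y, meta)


# ---------------------------------------------------------------------------
# Additivity under competitive binding (exact isobole theorem)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AdditivityCertificate:
    """Isobole coefficients at a target growth rate, plus the traced deviation.

    ``xi_i = k_on_i*lam / ((k_off_i + lam)*kappa_t)`` converts intracellular
    drug to bound ribosomes; ``upsilon_i`` converts extracellular to
    intracellular drug.  Under competitive binding the isobole satisfies
    ``delta_r*(1 - lam/lambda0) = aex_A*ups_A*xi_A + aex_B*ups_B*xi_B``
    exactly; ``isobole_gap`` is the maximum relative deviation of the
    numerically traced isobole from that line.
    """

    lam: float
    xi_a: float
    xi_b: float
    upsilon_a: float
    upsilon_b: float
    isobole_gap: float


def _xi(kin: DrugKinetics, lam: float, kappa_t: float) -> float:
    return kin.k_on * lam / ((kin.k_off + lam) * kappa_t)


def _upsilon(kin: DrugKinetics, lam: float, kappa_t: float) -> float:
    xi = _xi(kin, lam, kappa_t)
    return kin.p_in / (lam * (kin.k_on / kappa_t + 1.0) + kin.p_out - xi * kin.k_off)


def additivity_certificate(sys: PairSystem, lambda_target: float,
                           n_points: int = 50) -> AdditivityCertificate:
    """Verify linear isoboles of the competitive-binding pair numerically.

    Traces the isobole at growth rate ``lambda_target`` by solving the
    reduced steady-state residual for ``a_ex_B`` at each ``a_ex_A`` and
    compares with the closed-form linear relation.
    """
    if not (0 < lambda_target < sys.laws.lambda0):
        raise ValueError("lambda_target must lie in (0, lambda0)")
    if not sys.deltas.is_competitive:
        sys = replace(sys, deltas=BindingModifiers.competitive())
    lam = lambda_target
    kt = sys.laws.kappa_t
    xi_a, xi_b = _xi(sys.kin_a, lam, kt), _xi(sys.kin_b, lam, kt)
    ups_a, ups_b = _upsilon(sys.kin_a, lam, kt), _upsilon(sys.kin_b, lam, kt)
    rhs = sys.laws.delta_r * (1.0 - lam / sys.laws.lambda0)
    aex_a_max = rhs / (ups_a * xi_a)  # linear-isobole intercept on the A axis
    aex_b_max = rhs / (ups_b * xi_b)
    y_t = lam / sys.laws.lambda0
    gap = 0.0
    for t in np.linspace(0.0, 1.0, n_points):
        aex_a = t * aex_a_max
        predicted = (rhs - aex_a * ups_a * xi_a) / (ups_b * xi_b)
        f = lambda bb: float(_growth_residual(y_t, aex_a, bb, sys))
        hi = max(aex_b_max, predicted) * 1.5 + 1e-9
        traced = brentq(f, 0.0, hi, xtol=1e-14, rtol=1e-14) if f(0.0) * f(hi) < 0 else 0.0
        gap = max(gap, abs(traced - predicted) / aex_b_max)
    return AdditivityCertificate(lam, xi_a, xi_b, ups_a, ups_b, gap)


# ---------------------------------------------------------------------------
# Slow-growth analytic limit
# ---------------------------------------------------------------------------


def c_prime(c, alpha: float, laws: GrowthLaws):
    """Rescaled concentration ``c' = c*(alpha^2+1)*lambda_max/(alpha^2*lambda0)``.

    The natural drug unit in the slow-growth (rapid reversible binding)
    limit; undefined for irreversible binders (``alpha = 0``).
    """
    if alpha <= 0:
        raise ValueError("c_prime requires alpha > 0")
    c = np.asarray(c, float)
    out = c * (alpha**2 + 1.0) * laws.lambda_max / (alpha**2 * laws.lambda0)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class SlowGrowthTerms:
    """Composite factors of the slow-growth closed form."""

    c_prime_a: float
    c_prime_b: float
    phi_a: float
    phi_b: float
    phi_ab: float


def slow_growth_terms(cp_a: float, cp_b: float,
                      deltas: BindingModifiers) -> SlowGrowthTerms:
    d = deltas
    return SlowGrowthTerms(
        cp_a, cp_b,
        1.0 + cp_a * d.delta_on_a,
        1.0 + cp_b * d.delta_on_b,
        d.delta_on_a + d.delta_on_b + d.delta_on_a * d.delta_on_b * (cp_a + cp_b),
    )


def slow_growth_y(cp_a, cp_b, deltas: BindingModifiers, laws: GrowthLaws):
    """Closed-form relative growth in the slow-growth limit.

    General delta form; reduces to the Bliss-like product
    ``(lambda_max/lambda0)/((1+c'_A)(1+c'_B))`` for independent binding,
    to the Loewe form ``(lambda_max/lambda0)/(1+c'_A+c'_B)`` for
    competitive binding, to ``(lambda_max/lambda0)/(1+c'_A+c'_B+
    delta*c'_A*c'_B)`` for symmetric ``delta_on = delta``, and to 0 when
    unbinding from double-bound ribosomes is blocked.  Vectorised.
    """
    d = deltas
    cp_a = np.asarray(cp_a, float)
    cp_b = np.asarray(cp_b, float)
    if np.any(cp_a < 0) or np.any(cp_b < 0):
        raise ValueError("rescaled concentrations must be >= 0")
    phi_a = 1.0 + cp_a * d.delta_on_a
    phi_b = 1.0 + cp_b * d.delta_on_b
    phi_ab = d.delta_on_a + d.delta_on_b + d.delta_on_a * d.delta_on_b * (cp_a + cp_b)
    num = (laws.lambda_max / laws.lambda0) * (
        d.delta_off_a + d.delta_off_b
        + cp_a * d.delta_on_a * d.delta_off_b
        + cp_b * d.delta_on_b * d.delta_off_a
    )
    den = (1.0 + cp_a + cp_b) * (d.delta_off_b * phi_a + d.delta_off_a * phi_b) \
        + cp_a * cp_b * phi_ab
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(num == 0.0, 0.0, num / den)
    return float(out) if out.ndim == 0 else out


def slow_growth_surface(alpha_a: float, alpha_b: float, c_a_grid, c_b_grid,
                        deltas: BindingModifiers | None = None,
                        laws: GrowthLaws | None = None) -> DoseResponseSurface:
    """Slow-growth approximation on an IC50-unit grid (matrix indexed [c_A, c_B])."""
    laws = laws or GrowthLaws()
    deltas = deltas or BindingModifiers.independent()
    cp_a = c_prime(np.asarray(c_a_grid, float), alpha_a, laws)
    cp_b = c_prime(np.asarray(c_b_grid, float), alpha_b, laws)
    y = slow_growth_y(cp_a[:, None], cp_b[None, :], deltas, laws)
    return DoseResponseSurface(
        np.asarray(c_a_grid, float), np.asarray(c_b_grid, float), y,
        {"approximation": "slow-growth", "alpha_a": alpha_a, "alpha_b": alpha_b},
    )
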