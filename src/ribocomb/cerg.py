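"""Constitutively expressed resistance genes (CERGs).

An unregulated resistance enzyme (degrading enzyme or efflux pump) is
expressed in proportion to the growth rate, so its drug-removal flux

    j_rem = V'_max * (lambda/lambda0) * a / (a + K_rem),
    V'_max = V_max * (1 - lambda0/lambda_max),

drops as the drug slows growth — a positive feedback that steepens
dose-response curves, shifts IC50s upward and can make an otherwise
monostable response bistable.  The enzyme pool is not a dynamic variable;
its quasi-steady-state expression law is folded into the flux, and
lambda/lambda0 is part of the fixed-point system.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pair import DoseResponseSurface, PairSystem, surface as pair_surface
from .single_drug import (
    DoseResponseCurve,
    DrugKinetics,
    GrowthLaws,
    ResponseShape,
    kinetics_from_shape,
)

__all__ = [
    "CERG_K_ON",
    "CERG_P_OUT",
    "cerg_pair_system",
    "ResistanceEnzyme",
    "removal_flux",
    "cerg_growth",
    "cerg_ic50",
    "cerg_dose_response",
    "cerg_pair_surface",
    "steepness_metric",
]


#: Transport/binding presets for resistance studies: field-typical rates
#: (k_on ~ 1000 uM^-1 h^-1, p_out ~ 10 h^-1).  With fast efflux the removal
#: flux would be a minor correction; at these rates the growth-expression
#: feedback dominates, which is the regime of interest here.  All
#: resistance comparisons are internal to the kinetic model (baseline vs
#: enzyme-bearing), so the reduced-cubic correspondence is not needed.
CERG_K_ON = 1000.0
CERG_P_OUT = 10.0


def cerg_pair_system(alpha_a: float, alpha_b: float, deltas=None,
                     laws: GrowthLaws | None = None, ic50: float = 1.0) -> PairSystem:
    """Pair system with the resistance-study kinetic presets."""
    from .pair import BindingModifiers
    from .single_drug import ResponseShape

    laws = laws or GrowthLaws()
    sa = ResponseShape.from_alpha(alpha_a, laws, ic50)
    sb = ResponseShape.from_alpha(alpha_b, laws, ic50)
    return PairSystem(
        laws=laws,
        kin_a=kinetics_from_shape(sa, laws, k_on=CERG_K_ON, p_out=CERG_P_OUT),
        kin_b=kinetics_from_shape(sb, laws, k_on=CERG_K_ON, p_out=CERG_P_OUT),
        deltas=deltas or BindingModifiers.independent(),
        shape_a=sa,
        shape_b=sb,
    )


@dataclass(frozen=True)
class ResistanceEnzyme:
    """Growth-coupled removal capacity for one drug.

    ``v_max_prime`` is the nutrient-corrected maximal removal rate
    ``V_max*(1 - lambda0/lambda_max)`` in uM h^-1; ``k_rem`` the
    Michaelis constant in uM; ``target`` names the drug ("A" or "B").
    """

    v_max_prime: float
    k_rem: float
    target: str = "A"

    def __post_init__(self) -> None:
        if self.v_max_prime < 0:
            raise ValueError("v_max_prime must be >= 0")
        if self.k_rem <= 0:
            raise ValueError("k_rem must be positive")
        if self.target not in ("A", "B"):
            raise ValueError("target must be 'A' or 'B'")

    @classmethod
    def from_vmax(cls, v_max: float, laws: GrowthLaws, k_rem: float,
                  target: str = "A") -> "ResistanceEnzyme":
        """Apply the nutrient correction: expression ceases as lambda0 -> lambda_max."""
        return cls(v_max * (1.0 - laws.lambda0 / laws.lambda_max), k_rem, target)


def removal_flux(enzyme: ResistanceEnzyme, lambda_rel: float, a) -> float | np.ndarray:
    """Drug removal flux at relative growth ``lambda_rel`` and drug level ``a`` (uM)."""
    if not (0.0 <= lambda_rel <= 1.0 + 1e-12):
        raise ValueError("lambda_rel must lie in [0, 1]")
    a = np.asarray(a, float)
    out = enzyme.v_max_prime * lambda_rel * a / (a + enzyme.k_rem)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Single drug + enzyme steady states
# ---------------------------------------------------------------------------

_Y_FLOOR = 1e-7


def _h_single(y, aex, kin: DrugKinetics, laws: GrowthLaws, v: float, krem: float):
    """Reduced growth residual with the removal flux; drug level in closed form.

    At fixed y the drug balance is quadratic in a (pools eliminated), so
    the scan needs no inner iteration.
    """
    lam = y * laws.lambda0
    u = lam / laws.kappa_t
    drain = lam + kin.p_out + kin.k_on * u * lam / (lam + kin.k_off + 1e-300)
    b = drain * krem + v * y - kin.p_in * aex
    a = (-b + np.sqrt(b * b + 4.0 * drain * kin.p_in * aex * krem)) / (2.0 * drain)
    r_b = kin.k_on * a * u / (lam + kin.k_off + 1e-300)
    f = -kin.k_on * a * u + kin.k_off * r_b
    return -lam * (laws.r_min + u) + f + laws.synthesis(lam)


def cerg_growth(aex, kin: DrugKinetics, laws: GrowthLaws,
                enzyme: ResistanceEnzyme | None, n_scan: int = 400,
                n_bisect: int = 55):
    """Upper-branch growth at extracellular concentration(s) ``aex`` (uM)."""
    aex = np.atleast_1d(np.asarray(aex, float))
    v = enzyme.v_max_prime if enzyme else 0.0
    krem = enzyme.k_rem if enzyme else 1.0
    grid = np.concatenate([np.geomspace(_Y_FLOOR, 0.04, 30),
                           np.linspace(0.045, 1.0, n_scan)])
    h = _h_single(grid[:, None], aex[None, :], kin, laws, v, krem)
    sign_change = h[:-1] * h[1:] <= 0
    has_root = sign_change.any(axis=0)
    idx = sign_change.shape[0] - 1 - np.argmax(sign_change[::-1], axis=0)
    lo, hi = grid[idx], grid[idx + 1]
    s_lo = np.sign(h[idx, np.arange(aex.size)])
    s_lo = np.where(s_lo == 0, 1.0, s_lo)
    for _ in range(n_bisect):
        mid = 0.5 * (lo + hi)
        hm = _h_single(mid, aex, kin, laws, v, krem)
        same = np.sign(hm) == s_lo
        lo = np.where(same, mid, lo)
        hi = np.where(same, hi, mid)
    y = np.where(has_root, 0.5 * (lo + hi), 0.0)
    return np.where(aex == 0.0, 1.0, y)


def cerg_steady_states(aex: float, kin: DrugKinetics, laws: GrowthLaws,
                       enzyme: ResistanceEnzyme | None, n_scan: int = 2000):
    """All growth roots with slope-based stability flags (bistability probe)."""
    v = enzyme.v_max_prime if enzyme else 0.0
    krem = enzyme.k_rem if enzyme else 1.0
    grid = np.concatenate([np.geomspace(_Y_FLOOR, 0.04, 60),
                           np.linspace(0.045, 1.0, n_scan)])
    h = _h_single(grid, float(aex), kin, laws, v, krem)
    roots = []
    from scipy.optimize import brentq

    for i in range(len(grid) - 1):
        if h[i] * h[i + 1] < 0:
            y0 = brentq(lambda yy: float(_h_single(yy, float(aex), kin, laws, v, krem)),
                        grid[i], grid[i + 1], xtol=1e-14)
            roots.append((y0, h[i] > 0))
    return sorted(roots, key=lambda t: -t[0])


def cerg_ic50(kin: DrugKinetics, laws: GrowthLaws,
              enzyme: ResistanceEnzyme | None) -> float:
    """Extracellular concentration (uM) halving growth, found by bisection.

    For steep resistant curves this converges to the abrupt-drop
    concentration, the natural IC50 of a near-binary response.
    """
    hi = 1.0
    for _ in range(80):
        if float(cerg_growth(hi, kin, laws, enzyme)[0]) < 0.5:
            break
        hi *= 2.0
    else:
        raise RuntimeError("could not bracket the IC50")
    lo = 0.0
    for _ in range(70):
        mid = 0.5 * (lo + hi)
        if float(cerg_growth(mid, kin, laws, enzyme)[0]) >= 0.5:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def cerg_dose_response(shape: ResponseShape, enzyme: ResistanceEnzyme | None,
                       laws: GrowthLaws, c_grid,
                       kin: DrugKinetics | None = None):
    """Dose-response curve of the resistant strain on its own IC50 axis.

    ``c_grid`` is in units of the *resistant* IC50 (recomputed
    numerically), so curves with and without the enzyme are directly
    comparable in steepness.  Returns ``(curve, ic50_ratio)`` where
    ``ic50_ratio`` is the resistance gain relative to the enzyme-free
    drug.
    """
    kin = kin or kinetics_from_shape(shape, laws, k_on=CERG_K_ON, p_out=CERG_P_OUT)
    c_grid = np.asarray(c_grid, float)
    base_ic50 = cerg_ic50(kin, laws, None)
    ic50 = cerg_ic50(kin, laws, enzyme) if enzyme else base_ic50
    y = cerg_growth(c_grid * ic50, kin, laws, enzyme)
    branch = tuple("upper" if v > 0 else "lower" for v in y)
    curve = DoseResponseCurve(c_grid, y, shape.alpha, branch,
                              concentration_units="ic50")
    return curve, ic50 / base_ic50


def cerg_pair_surface(sys: PairSystem, enzyme_a: ResistanceEnzyme | None,
                      enzyme_b: ResistanceEnzyme | None, c_grid,
                      rescale_axes: bool = True) -> DoseResponseSurface:
    """Pair surface with one specific resistance enzyme per drug.

    With ``rescale_axes`` the grid is interpreted in units of each
    resistant strain's IC50 (recomputed per drug), mirroring how
    checkerboards of resistant strains are normalized.
    """
    rem_a = (enzyme_a.v_max_prime, enzyme_a.k_rem) if enzyme_a else None
    rem_b = (enzyme_b.v_max_prime, enzyme_b.k_rem) if enzyme_b else None
    aug = sys.with_removal(rem_a, rem_b)
    c_grid = np.asarray(c_grid, float)
    if rescale_axes:
        ic50_a = cerg_ic50(sys.kin_a, sys.laws, enzyme_a)
        ic50_b = cerg_ic50(sys.kin_b, sys.laws, enzyme_b)
    else:
        ic50_a, ic50_b = sys.shape_a.ic50, sys.shape_b.ic50
    surf = pair_surface(aug, c_grid * ic50_a, c_grid * ic50_b, a_ex_grids=True)
    meta = dict(surf.meta)
    meta.update({"ic50_a": ic50_a, "ic50_b": ic50_b, "units": "ic50-resistant",
                 "v_max_prime": [enzyme_a.v_max_prime if enzyme_a else 0.0,
                                 enzyme_b.v_max_prime if enzyme_b else 0.0]})
    return DoseResponseSurface(c_grid, c_grid.copy(), surf.y, meta)


def cerg_loewe_reference(sys: PairSystem, enzyme_a: ResistanceEnzyme | None,
                         enzyme_b: ResistanceEnzyme | None, c_grid,
                         n_tab: int = 241) -> DoseResponseSurface:
    """Loewe additive reference for a resistant pair, on the rescaled grid.

    The single-drug inverses are tabulated from the kinetic solver over
    the full summed-concentration range of the grid (so the isobole
    equation never runs off the table) and fed to the generic
    curve-based Loewe construction.
    """
    from .scoring import loewe_from_curves

    c_grid = np.asarray(c_grid, float)
    span = np.linspace(0.0, 2.0 * c_grid[-1], n_tab)
    ic50_a = cerg_ic50(sys.kin_a, sys.laws, enzyme_a)
    ic50_b = cerg_ic50(sys.kin_b, sys.laws, enzyme_b)
    curve_a = DoseResponseCurve(span, cerg_growth(span * ic50_a, sys.kin_a, sys.laws,
                                                  enzyme_a), sys.shape_a.alpha)
    curve_b = DoseResponseCurve(span, cerg_growth(span * ic50_b, sys.kin_b, sys.laws,
                                                  enzyme_b), sys.shape_b.alpha)
    return loewe_from_curves(curve_a, curve_b, c_grid, c_grid)


def steepness_metric(curve: DoseResponseCurve) -> float:
    """Max |dy/dc| over the grid on an IC50-normalized axis.

    Grid-dependent for discontinuous (step-like) curves: the metric grows
    with grid refinement there, which is the intended reading — steeper
    than any finite slope.
    """
    c = np.asarray(curve.concentrations, float)
    y = np.asarray(curve.growth, float)
    if c.size < 3:
        raise ValueError("need at least 3 points")
    return float(np.max(np.abs(np.diff(y) / np.diff(c))))
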