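"""Growth laws and the single translation-inhibitor model.

The model couples mass-action kinetics of antibiotic transport and
ribosome binding to two empirical bacterial growth laws:

* nutrient law: the concentration of working (unbound) ribosomes grows
  linearly with growth rate, ``r_u = r_min + lambda / kappa_t``;
* inhibition law: under translation inhibition the total ribosome
  concentration rises as growth falls,
  ``r_tot = r_max - lambda * delta_r * (1/lambda0 - 1/(kappa_t*delta_r))``.

At balanced growth the full kinetic system collapses onto a cubic for the
relative growth rate ``y = lambda/lambda0`` whose shape is controlled by a
single dimensionless response parameter ``alpha``: shallow Langmuir-like
curves for large ``alpha``, steep curves with a bistable concentration
window for ``alpha`` below ``2/(3*sqrt(3))``.

Concentrations are handled in IC50 units (``c = a_ex / IC50``) internally;
micromolar values are converted at the boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "GrowthLaws",
    "DrugKinetics",
    "ResponseShape",
    "SteadyStateSet",
    "DoseResponseCurve",
    "DEFAULT_KAPPA_T",
    "DEFAULT_R_MIN",
    "DEFAULT_R_MAX",
    "reduce_kinetics",
    "kinetics_from_shape",
    "inverse_dose_response",
    "steady_state_growth",
    "alpha_crit",
    "alpha_crit_numeric",
    "bistable_window",
    "dose_response_curve",
    "single_drug_rhs",
]

#: Translational capacity, uM^-1 h^-1 (E. coli).
DEFAULT_KAPPA_T = 0.06
#: Minimal ribosome concentration, uM.
DEFAULT_R_MIN = 19.3
#: Maximal ribosome concentration, uM.
DEFAULT_R_MAX = 65.8


@dataclass(frozen=True)
class GrowthLaws:
    """Growth-law constants tying ribosome concentration to growth rate.

    Parameters
    ----------
    kappa_t : float
        Translational capacity, uM^-1 h^-1.
    r_min : float
        Minimal (growth-extrapolated) ribosome concentration, uM.
    r_max : float
        Maximal ribosome concentration under full inhibition, uM.
    lambda0 : float
        Drug-free growth rate in the given nutrient environment, h^-1.
        Must not exceed ``lambda_max = kappa_t * (r_max - r_min)``.
    """

    kappa_t: float = DEFAULT_KAPPA_T
    r_min: float = DEFAULT_R_MIN
    r_max: float = DEFAULT_R_MAX
    lambda0: float = 1.0

    def __post_init__(self) -> None:
        if not (self.r_max > self.r_min > 0):
            raise ValueError("require r_max > r_min > 0")
        if self.kappa_t <= 0:
            raise ValueError("kappa_t must be positive")
        if not (0 < self.lambda0 <= self.lambda_max + 1e-12):
            raise ValueError(
                f"lambda0 must lie in (0, lambda_max={self.lambda_max:.4f}]"
            )

    @property
    def delta_r(self) -> float:
        """Dynamic range of the ribosome concentration, uM."""
        return self.r_max - self.r_min

    @property
    def lambda_max(self) -> float:
        """Fastest supported growth rate ``kappa_t * delta_r``, h^-1."""
        return self.kappa_t * (self.r_max - self.r_min)

    def r_u(self, lam):
        """Unbound-ribosome concentration at growth rate ``lam`` (nutrient law)."""
        return self.r_min + lam / self.kappa_t

    def r_tot(self, lam):
        """Total ribosome concentration at growth rate ``lam`` (inhibition law)."""
        return self.r_max - lam * self.delta_r * (
            1.0 / self.lambda0 - 1.0 / (self.kappa_t * self.delta_r)
        )

    def synthesis(self, lam):
        """Ribosome synthesis flux ``s(lambda) = lambda * r_tot(lambda)``, uM h^-1."""
        return lam * self.r_tot(lam)

    def growth_rate(self, r_u):
        """Growth rate implied by the nutrient law, clamped at zero."""
        return self.kappa_t * max(r_u - self.r_min, 0.0)


@dataclass(frozen=True)
class DrugKinetics:
    """Transport and ribosome-binding rate constants of one antibiotic.

    Attributes
    ----------
    p_in, p_out : float
        Membrane influx/efflux rates, h^-1.
    k_on : float
        Second-order forward binding constant, uM^-1 h^-1.
    k_off : float
        First-order unbinding constant, h^-1; ``k_off = 0`` models
        effectively irreversible binders such as streptomycin.
    """

    p_in: float
    p_out: float
    k_on: float
    k_off: float

    def __post_init__(self) -> None:
        if min(self.p_in, self.p_out, self.k_on, self.k_off) < 0:
            raise ValueError("rate constants must be non-negative")
        if self.k_on <= 0:
            raise ValueError("k_on must be positive")

    @property
    def k_d(self) -> float:
        """Dissociation constant ``k_off / k_on``, uM."""
        return self.k_off / self.k_on

    def influx(self, a_ex, a):
        """Net transport flux ``J = p_in*a_ex - p_out*a``, uM h^-1."""
        return self.p_in * a_ex - self.p_out * a

    def binding(self, r_u, r_b, a, r_min):
        """Net unbinding flux ``f = -k_on*a*(r_u - r_min) + k_off*r_b``."""
        return -self.k_on * a * (r_u - r_min) + self.k_off * r_b


@dataclass(frozen=True)
class ResponseShape:
    """Reduced description of a single-drug dose-response curve.

    ``alpha = lambda0_star / lambda0`` sets the curve shape;
    ``ic50`` locates it on the extracellular concentration axis (uM).
    ``lambda0_star = 2*sqrt(p_out*kappa_t*K_D)`` and
    ``ic50_star = delta_r*lambda0_star/(2*p_in)`` are the characteristic
    growth-rate and concentration scales of the kinetics.
    ``irreversible`` flags the ``alpha = 0`` (``k_off = 0``) limit, where
    ``ic50_star`` degenerates to 0 and the dose-response follows
    ``y = (1 + sqrt(1-c))/2``.
    """

    alpha: float
    ic50: float
    lambda0_star: float = 0.0
    ic50_star: float = 0.0
    irreversible: bool = False

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.ic50 <= 0:
            raise ValueError("ic50 must be positive")

    @classmethod
    def from_alpha(
        cls, alpha: float, laws: GrowthLaws | None = None, ic50: float = 1.0
    ) -> "ResponseShape":
        """Build a shape from ``alpha`` alone, placing the IC50 at ``ic50`` uM."""
        laws = laws or GrowthLaws()
        lam0s = alpha * laws.lambda0
        if alpha == 0:
            return cls(0.0, ic50, 0.0, 0.0, irreversible=True)
        ic50_star = 2.0 * alpha * ic50 / (alpha**2 + 1.0)
        return cls(alpha, ic50, lam0s, ic50_star)


def reduce_kinetics(kinetics: DrugKinetics, laws: GrowthLaws) -> ResponseShape:
    """Collapse full kinetics onto the two-parameter response shape.

    ``lambda0_star = 2*sqrt(p_out*kappa_t*K_D)``,
    ``ic50_star = delta_r*lambda0_star/(2*p_in)``,
    ``alpha = lambda0_star/lambda0`` and
    ``IC50 = ic50_star*(alpha^2+1)/(2*alpha)``.
    For an irreversible binder (``k_off = 0``) the IC50 is the
    ``alpha -> 0`` limit ``delta_r*lambda0/(4*p_in)`` and the shape is
    flagged ``irreversible``.
    """
    if laws.lambda0 <= 0:
        raise ValueError("lambda0 must be positive")
    if kinetics.p_in <= 0:
        raise ValueError("p_in must be positive to define an IC50")
    lam0s = 2.0 * math.sqrt(kinetics.p_out * laws.kappa_t * kinetics.k_d)
    alpha = lam0s / laws.lambda0
    ic50_star = laws.delta_r * lam0s / (2.0 * kinetics.p_in)
    if alpha == 0.0:
        ic50 = laws.delta_r * laws.lambda0 / (4.0 * kinetics.p_in)
        return ResponseShape(0.0, ic50, 0.0, 0.0, irreversible=True)
    ic50 = ic50_star * (alpha**2 + 1.0) / (2.0 * alpha)
    return ResponseShape(alpha, ic50, lam0s, ic50_star)


def kinetics_from_shape(
    shape: ResponseShape,
    laws: GrowthLaws | None = None,
    k_on: float = 1.0e6,
    p_out: float = 1.0e3,
) -> DrugKinetics:
    """Concrete rate constants realizing a response shape.

    The reduction ``kinetics -> (alpha, IC50)`` is many-to-one; this picks
    the remaining freedom deep in the rapid-kinetics regime
    (``k_on = 1e6`` uM^-1 h^-1, ``p_out = 1e3`` h^-1) and solves for
    ``k_off`` and ``p_in``:

    ``K_D = (alpha*lambda0/2)^2 / (p_out*kappa_t)`` and
    ``p_in = delta_r*lambda0*(alpha^2+1)/(4*IC50)``.

    Round-tripping through :func:`reduce_kinetics` recovers the shape
    exactly.  The steady-state cubic drops correction terms of relative
    size ``~lambda/p_out`` and ``~kappa_t*(k_off+p_out)/k_on`` against
    the full kinetic fixed point; the defaults keep that gap below ~1e-3
    so surfaces built from these kinetics carry the prescribed
    single-drug boundaries to within the same accuracy.
    """
    laws = laws or GrowthLaws()
    k_d = (shape.alpha * laws.lambda0 / 2.0) ** 2 / (p_out * laws.kappa_t)
    p_in = laws.delta_r * laws.lambda0 * (shape.alpha**2 + 1.0) / (4.0 * shape.ic50)
    return DrugKinetics(p_in=p_in, p_out=p_out, k_on=k_on, k_off=k_d * k_on)


# ---------------------------------------------------------------------------
# Closed-form steady state
# ---------------------------------------------------------------------------


def inverse_dose_response(alpha: float, y):
    """Concentration (IC50 units) at which growth ``y`` is a steady state.

    Exact inversion of the steady-state cubic:
    ``c(y) = (1 - y) * (4*y^2 + alpha^2) / (y * (alpha^2 + 1))``.
    Defined for all ``y`` in (0, 1]; vectorised over ``y``.
    """
    y = np.asarray(y, dtype=float)
    if np.any(y <= 0):
        raise ValueError("y must be positive")
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    c = (1.0 - y) * (4.0 * y**2 + alpha**2) / (y * (alpha**2 + 1.0))
    return float(c) if c.ndim == 0 else c


def _dc_dy(alpha: float, y):
    """Derivative of the closed-form c(y); its sign decides stability."""
    a2 = alpha**2
    return (-a2 / y**2 + 4.0 - 8.0 * y) / (a2 + 1.0)


@dataclass(frozen=True)
class SteadyStateSet:
    """Real steady-state growth roots at one concentration.

    ``roots`` is a list of ``(y, stable)`` sorted descending in ``y``;
    the cubic admits one or three real roots in (0, 1] (the irreversible
    ``alpha = 0`` limit may admit none beyond full inhibition, in which
    case the set is empty and growth is arrested).
    """

    roots: tuple[tuple[float, bool], ...]

    @property
    def upper(self) -> float:
        """Largest stable root (batch-culture observable); 0.0 if none."""
        for y, stable in self.roots:
            if stable:
                return y
        return 0.0

    @property
    def bistable(self) -> bool:
        return sum(1 for _, s in self.roots if s) >= 2


def steady_state_growth(alpha: float, c: float) -> SteadyStateSet:
    """All real steady states of the single-drug model at concentration ``c``.

    Roots of ``y^3 - y^2 + y*(alpha^2 + c*(alpha^2+1))/4 - alpha^2/4 = 0``
    in (0, 1], polished by Newton steps on the cubic; a root is stable when
    ``dc/dy < 0`` there (the middle root of three is unstable).  For
    ``alpha = 0`` the cubic degenerates and the exact quadratic limit
    ``4*y*(1-y) = c`` is used instead.
    """
    if c < 0:
        raise ValueError("c must be >= 0")
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    if alpha == 0.0:
        if c > 1.0:
            return SteadyStateSet(())
        s = math.sqrt(max(1.0 - c, 0.0))
        hi, lo = (1.0 + s) / 2.0, (1.0 - s) / 2.0
        roots = [(hi, True)]
        if lo > 0 and lo < hi:
            roots.append((lo, False))
        return SteadyStateSet(tuple(roots))

    a2 = alpha**2
    coeffs = [1.0, -1.0, (a2 + c * (a2 + 1.0)) / 4.0, -a2 / 4.0]
    raw = np.roots(coeffs)
    ys = sorted(
        (float(r.real) for r in raw if abs(r.imag) < 1e-8 * max(1.0, abs(r))),
        reverse=True,
    )
    p = np.polynomial.Polynomial(coeffs[::-1])
    dp = p.deriv()
    out = []
    for y in ys:
        for _ in range(3):  # Newton polish to ~1e-15
            d = dp(y)
            if d != 0:
                y -= p(y) / d
        if 1e-12 < y <= 1.0 + 1e-12:
            y = min(y, 1.0)
            out.append((y, _dc_dy(alpha, y) < 1e-12))
    # de-duplicate near-coincident roots at a fold
    dedup: list[tuple[float, bool]] = []
    for y, s in out:
        if dedup and abs(dedup[-1][0] - y) < 1e-9:
            continue
        dedup.append((y, s))
    return SteadyStateSet(tuple(dedup))


def alpha_crit() -> float:
    """Bifurcation threshold ``2/(3*sqrt(3))``: bistability requires alpha below it."""
    return 2.0 / (3.0 * math.sqrt(3.0))


def alpha_crit_numeric(tol: float = 1e-9, n_scan: int = 4001) -> float:
    """Bracket the bistability threshold from the monotonicity of c(y).

    Bisection on ``alpha``: the system is bistable iff the closed-form
    ``c(y)`` is non-monotonic on (0, 1).  Independent of the analytic
    fold condition; agrees with :func:`alpha_crit` to ``tol``.
    """
    ygrid = np.linspace(1e-4, 1.0 - 1e-4, n_scan)

    def non_monotone(alpha: float) -> bool:
        c = inverse_dose_response(alpha, ygrid)
        return bool(np.any(np.diff(c) > 0))

    lo, hi = 0.05, 1.0
    if not non_monotone(lo) or non_monotone(hi):
        raise RuntimeError("bisection bracket invalid")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if non_monotone(mid):
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def bistable_window(alpha: float) -> tuple[float, float] | None:
    """Concentration interval (IC50 units) with two stable growth states.

    The folds of ``c(y)`` solve ``4*y^2*(1-2*y) = alpha^2`` with the two
    roots ``y- < 1/3 < y+`` in (0, 1/2); the window is
    ``(c(y+), c(y-))``, an ascending interval since the fold at larger
    ``y`` lies at lower concentration.  Returns ``None`` for
    ``alpha >= 2/(3*sqrt(3))``.  At ``alpha = 0`` the window is (0, 1).
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    if alpha >= alpha_crit():
        return None
    if alpha == 0.0:
        return (0.0, 1.0)
    a2 = alpha**2
    f = lambda y: 4.0 * y**2 * (1.0 - 2.0 * y) - a2
    y_minus = brentq(f, 1e-12, 1.0 / 3.0, xtol=1e-15)
    y_plus = brentq(f, 1.0 / 3.0, 0.5, xtol=1e-15)
    c_lo = inverse_dose_response(alpha, y_plus)
    c_hi = inverse_dose_response(alpha, y_minus)
    return (min(c_lo, c_hi), max(c_lo, c_hi))


@dataclass(frozen=True)
class DoseResponseCurve:
    """Relative growth along a concentration grid under the upper-branch policy."""

    concentrations: np.ndarray
    growth: np.ndarray
    alpha: float
    branch: tuple[str, ...] = field(default=())
    concentration_units: str = "ic50"
    branch_policy: str = "largest-stable"

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "concentrations", np.asarray(self.concentrations, dtype=float)
        )
        object.__setattr__(self, "growth", np.asarray(self.growth, dtype=float))


def dose_response_curve(shape: ResponseShape | float, c_grid) -> DoseResponseCurve:
    """Single-drug dose-response curve on ``c_grid`` (IC50 units).

    Reports the largest stable steady state per concentration: the upper
    branch until its fold, beyond which the reported growth drops
    discontinuously to the lower branch (or to zero for an irreversible
    binder past full inhibition).
    """
    alpha = shape.alpha if isinstance(shape, ResponseShape) else float(shape)
    c_grid = np.asarray(c_grid, dtype=float)
    if np.any(c_grid < 0):
        raise ValueError("concentrations must be >= 0")
    window = bistable_window(alpha)
    ys = np.empty_like(c_grid)
    branch = []
    for i, c in enumerate(c_grid):
        ys[i] = steady_state_growth(alpha, float(c)).upper
        on_lower = window is not None and c > window[1]
        branch.append("lower" if on_lower or ys[i] == 0.0 else "upper")
    return DoseResponseCurve(c_grid, ys, alpha, tuple(branch))


# ---------------------------------------------------------------------------
# Kinetic ODE system (Eqs of motion for a, r_u, r_b)
# ---------------------------------------------------------------------------


def single_drug_rhs(state, a_ex: float, kinetics: DrugKinetics, laws: GrowthLaws):
    """Time derivatives (da/dt, dr_u/dt, dr_b/dt) of the kinetic model.

    Growth rate is read off the nutrient law, ``lambda = kappa_t *
    max(r_u - r_min, 0)``; synthesis follows the inhibition law
    ``s(lambda)``; every species dilutes at rate ``lambda``.  Fixed points
    of this system solve the steady-state cubic.
    """
    a, r_u, r_b = state
    lam = laws.growth_rate(r_u)
    f = kinetics.binding(r_u, r_b, a, laws.r_min)
    da = -lam * a + f + kinetics.influx(a_ex, a)
    dru = -lam * r_u + f + laws.synthesis(lam)
    drb = -lam * r_b - f
    return (da, dru, drb)
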