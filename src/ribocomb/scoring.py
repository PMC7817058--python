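"""Loewe/Bliss reference surfaces and the Loewe interaction (LI) score.

The additive reference treats the two drugs as dilutions of each other:
along each of its isoboles ``c_A/C_A(y) + c_B/C_B(y) = 1``, where
``C_i(y)`` is the concentration at which drug i alone permits growth
``y``.  The LI score is the natural log of the ratio of the volumes under
the modelled (or measured) surface and the additive reference; negative
means synergy, positive antagonism.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pair import BindingModifiers, DoseResponseSurface, PairSystem, surface as pair_surface
from .single_drug import (
    DoseResponseCurve,
    GrowthLaws,
    ResponseShape,
)

__all__ = [
    "InteractionScore",
    "PhaseDiagram",
    "loewe_additive_surface",
    "loewe_from_curves",
    "bliss_surface",
    "li_score",
    "phase_diagram",
]

#: Half-width of the |LI| band classified as additive on default grids.
ADDITIVE_TOLERANCE = 0.01


@dataclass(frozen=True)
class InteractionScore:
    li: float
    label: str
    tolerance: float = ADDITIVE_TOLERANCE


def _classify(li: float, tolerance: float) -> str:
    if li < -tolerance:
        return "synergy"
    if li > tolerance:
        return "antagonism"
    return "additive"


def _solve_additive(conc_of_y_a, conc_of_y_b, c_a_grid, c_b_grid,
                    n_scan: int = 200, n_bisect: int = 60) -> np.ndarray:
    """Solve the isobole equation per grid point (vectorised over rows).

    ``conc_of_y_i`` maps an array of growth values to concentrations
    (IC50 units of the respective drug).  Takes the topmost root in
    (0, 1); points beyond both drugs' reach get 0.
    """
    y_scan = np.linspace(1e-9, 1.0 - 1e-12, n_scan)
    cap_a = np.maximum(conc_of_y_a(y_scan), 1e-300)
    cap_b = np.maximum(conc_of_y_b(y_scan), 1e-300)
    c_b = np.asarray(c_b_grid, float)
    out = np.empty((len(c_a_grid), c_b.size))
    for i, ca in enumerate(np.asarray(c_a_grid, float)):
        if ca == 0.0:
            g = ca / cap_a[:, None] + c_b[None, :] / cap_b[:, None] - 1.0
        else:
            g = ca / cap_a[:, None] + c_b[None, :] / cap_b[:, None] - 1.0
        # G < 0 below the root, +inf as y -> 1 (for c > 0); topmost sign change
        sign_change = g[:-1] * g[1:] <= 0
        has_root = sign_change.any(axis=0)
        idx = sign_change.shape[0] - 1 - np.argmax(sign_change[::-1], axis=0)
        lo, hi = y_scan[idx], y_scan[idx + 1]
        s_lo = np.sign(g[idx, np.arange(c_b.size)])
        s_lo = np.where(s_lo == 0, -1.0, s_lo)
        for _ in range(n_bisect):
            mid = 0.5 * (lo + hi)
            gm = (ca / np.maximum(conc_of_y_a(mid), 1e-300)
                  + c_b / np.maximum(conc_of_y_b(mid), 1e-300) - 1.0)
            same = np.sign(gm) == s_lo
            lo = np.where(same, mid, lo)
            hi = np.where(same, hi, mid)
        row = np.where(has_root, 0.5 * (lo + hi), 0.0)
        row = np.where((ca == 0.0) & (c_b == 0.0), 1.0, row)
        out[i] = row
    return out


def loewe_additive_surface(shape_a: ResponseShape | float, shape_b: ResponseShape | float,
                           c_a_grid, c_b_grid) -> DoseResponseSurface:
    """Additive expectation built from the closed-form single-drug inverses.

    The isobole condition ``c_A/C_A(y) + c_B/C_B(y) = 1`` with the
    analytic inverses clears denominators into a quintic in ``y``, which
    is solved exactly per grid point (batched companion-matrix
    eigenvalues); the topmost real root in (0, 1] is reported, consistent
    with the upper-branch policy for bistable shapes.  Points beyond both
    drugs' reach (possible only for irreversible binders) get 0.  All
    isoboles of the result are straight lines by construction.
    """
    alpha_a = shape_a.alpha if isinstance(shape_a, ResponseShape) else float(shape_a)
    alpha_b = shape_b.alpha if isinstance(shape_b, ResponseShape) else float(shape_b)
    c_a_grid = np.asarray(c_a_grid, float)
    c_b_grid = np.asarray(c_b_grid, float)
    ca = c_a_grid[:, None]
    cb = c_b_grid[None, :]
    a2, b2 = alpha_a**2, alpha_b**2
    # (1-y)(4y^2+aA^2)(4y^2+aB^2) - cA(aA^2+1)y(4y^2+aB^2) - cB(aB^2+1)y(4y^2+aA^2)
    shape = np.broadcast_shapes(ca.shape, cb.shape)
    coef = np.zeros(shape + (6,))  # powers y^5 .. y^0
    coef[..., 0] = -16.0
    coef[..., 1] = 16.0
    coef[..., 2] = -4.0 * (a2 + b2) - 4.0 * ca * (a2 + 1.0) - 4.0 * cb * (b2 + 1.0)
    coef[..., 3] = 4.0 * (a2 + b2)
    coef[..., 4] = -a2 * b2 - ca * (a2 + 1.0) * b2 - cb * (b2 + 1.0) * a2
    coef[..., 5] = a2 * b2
    y = np.zeros(shape)
    flat = coef.reshape(-1, 6)
    yf = y.reshape(-1)
    # batched companion matrices for all grid points at once
    comp = np.zeros((flat.shape[0], 5, 5))
    comp[:, 1:, :-1] = np.eye(4)
    comp[:, :, -1] = -flat[:, 5::-1][:, :5] / flat[:, [0]]
    roots = np.linalg.eigvals(comp)
    real = (np.abs(roots.imag) < 1e-9) & (roots.real > 1e-13) & (roots.real <= 1.0 + 1e-12)
    cand = np.where(real, roots.real, -np.inf)
    yf[:] = np.clip(cand.max(axis=1), 0.0, 1.0)
    yf[np.isinf(cand.max(axis=1))] = 0.0
    both_zero = (ca == 0.0) & (cb == 0.0)
    y = np.where(np.broadcast_to(both_zero, shape), 1.0, y)
    return DoseResponseSurface(c_a_grid, c_b_grid, y, {"reference": "loewe"})


def _curve_inverse(curve: DoseResponseCurve):
    """Monotone numeric inverse c(y) of a tabulated non-increasing curve."""
    c = np.asarray(curve.concentrations, float)
    y = np.asarray(curve.growth, float)
    order = np.argsort(y)
    y_s, c_s = y[order], c[order]
    # collapse ties in y so np.interp sees strictly increasing support
    y_u, idx = np.unique(y_s, return_index=True)
    c_u = c_s[idx]

    def conc_of_y(yy):
        yy = np.asarray(yy, float)
        out = np.interp(yy, y_u, c_u, left=c_u[0], right=0.0)
        return out

    return conc_of_y


def loewe_from_curves(curve_a: DoseResponseCurve, curve_b: DoseResponseCurve,
                      c_a_grid, c_b_grid) -> DoseResponseSurface:
    """Additive reference from tabulated single-drug curves (e.g. measured data)."""
    y = _solve_additive(_curve_inverse(curve_a), _curve_inverse(curve_b),
                        c_a_grid, c_b_grid)
    return DoseResponseSurface(np.asarray(c_a_grid, float), np.asarray(c_b_grid, float),
                               y, {"reference": "loewe-numeric"})


def bliss_surface(curve_a: DoseResponseCurve, curve_b: DoseResponseCurve) -> DoseResponseSurface:
    """Bliss independence: the product of the individual relative responses."""
    y = np.outer(curve_a.growth, curve_b.growth)
    return DoseResponseSurface(curve_a.concentrations, curve_b.concentrations, y,
                               {"reference": "bliss"})


def li_score(surf: DoseResponseSurface, y_add: DoseResponseSurface,
             tolerance: float = ADDITIVE_TOLERANCE) -> InteractionScore:
    """Log-ratio of trapezoidal volumes under the surface and its additive reference."""
    if surf.y.shape != y_add.y.shape:
        raise ValueError("surfaces must share a grid")
    vol = np.trapezoid(np.trapezoid(surf.y, surf.c_b, axis=1), surf.c_a)
    vol_add = np.trapezoid(np.trapezoid(y_add.y, y_add.c_b, axis=1), y_add.c_a)
    if vol_add <= 0:
        raise ValueError("additive reference has zero volume")
    li = float(np.log(vol / vol_add))
    return InteractionScore(li, _classify(li, tolerance), tolerance)


@dataclass(frozen=True)
class PhaseDiagram:
    """LI score over a grid of response-parameter pairs."""

    alpha_a: np.ndarray
    alpha_b: np.ndarray
    li: np.ndarray


def phase_diagram(alpha_values, deltas: BindingModifiers | None = None,
                  laws: GrowthLaws | None = None, c_max: float = 3.0,
                  n_grid: int = 41) -> PhaseDiagram:
    """LI for every response-parameter pair on ``alpha_values`` x ``alpha_values``.

    Symmetric binding modifiers make the diagram symmetric about the
    diagonal, which is exploited to halve the work.  ``n_grid`` controls
    the concentration grid per surface (use 121 for production numbers,
    smaller for quick looks).
    """
    laws = laws or GrowthLaws()
    deltas = deltas or BindingModifiers.independent()
    alphas = np.asarray(alpha_values, float)
    if np.any(alphas <= 0):
        raise ValueError("phase diagram requires alpha > 0")
    grid = np.linspace(0.0, c_max, n_grid)
    symmetric = deltas == deltas.swapped()
    li = np.full((alphas.size, alphas.size), np.nan)
    for i, aa in enumerate(alphas):
        for j, ab in enumerate(alphas):
            if symmetric and j < i:
                continue
            sys = PairSystem.from_alphas(aa, ab, deltas, laws)
            surf = pair_surface(sys, grid, grid)
            ref = loewe_additive_surface(aa, ab, grid, grid)
            li[i, j] = li_score(surf, ref).li
    if symmetric:
        iu = np.triu_indices(alphas.size, 1)
        li[(iu[1], iu[0])] = li[iu]
    return PhaseDiagram(alphas, alphas.copy(), li)
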