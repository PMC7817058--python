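"""Starvation-mimicking antibiotics (SMAs) combined with translation inhibitors.

An SMA (e.g. mupirocin) blocks tRNA charging and thereby mimics a poor
nutrient environment: its only effect in the model is to rescale the
drug-free growth rate by its own dose-response ``g(c_s)``.  Because
``alpha`` is inversely proportional to the drug-free growth rate, the
translation inhibitor's response parameter steepens to
``alpha_F / g(c_s)`` and its IC50 shifts by the fold-change

    psi = (alpha_F^2 + g^2) / ((alpha_F^2 + 1) * g),

which is non-monotonic in the inhibition for ``alpha_F <= 1`` (minimum
``2*alpha_F/(1+alpha_F^2)`` at ``g = alpha_F``) and monotonically
increasing for ``alpha_F > 1``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .pair import DoseResponseSurface
from .single_drug import steady_state_growth

__all__ = ["SMAResponse", "psi", "sma_surface", "tabulated_g", "parametric_g"]


def tabulated_g(c_s, g) -> Callable[[np.ndarray], np.ndarray]:
    """SMA dose-response from a table, linearly interpolated (monotone-preserving)."""
    c_s = np.asarray(c_s, float)
    g = np.asarray(g, float)
    if c_s[0] != 0.0 or g[0] != 1.0:
        raise ValueError("g must be tabulated from c_s = 0 with g(0) = 1")
    if np.any(np.diff(c_s) <= 0) or np.any(np.diff(g) > 1e-12):
        raise ValueError("c_s must increase and g must be non-increasing")
    return lambda x: np.interp(np.asarray(x, float), c_s, g)


def parametric_g(alpha_s: float) -> Callable[[np.ndarray], np.ndarray]:
    """SMA dose-response as an upper-branch single-drug curve with its own alpha."""

    def g(x):
        x = np.atleast_1d(np.asarray(x, float))
        out = np.array([steady_state_growth(alpha_s, float(c)).upper for c in x])
        return out if out.size > 1 else float(out[0])

    return g


@dataclass(frozen=True)
class SMAResponse:
    """Translation inhibitor shape paired with an SMA dose-response ``g``.

    ``alpha_f`` and ``ic50_f`` describe the inhibitor in the absence of
    the SMA; ``g`` maps SMA concentration to relative drug-free growth.
    """

    alpha_f: float
    g: Callable
    ic50_f: float = 1.0

    def __post_init__(self) -> None:
        if self.alpha_f < 0:
            raise ValueError("alpha_f must be >= 0")


def psi(alpha_f: float, g_value) -> float | np.ndarray:
    """IC50 fold-change of a translation inhibitor at SMA inhibition level ``g``.

    Limits: ``psi -> g`` as ``alpha_f -> 0`` and ``psi -> 1/g`` as
    ``alpha_f -> inf``.
    """
    g_value = np.asarray(g_value, float)
    if np.any(g_value <= 0) or np.any(g_value > 1.0 + 1e-12):
        raise ValueError("g must lie in (0, 1]")
    out = (alpha_f**2 + g_value**2) / ((alpha_f**2 + 1.0) * g_value)
    return float(out) if out.ndim == 0 else out


def sma_surface(response: SMAResponse, c_grid, cs_grid) -> DoseResponseSurface:
    """Two-way surface of a translation inhibitor (rows) against an SMA (columns).

    Per SMA concentration the inhibitor responds with effective parameter
    ``alpha_F/g`` at rescaled concentration ``c/psi``, on a background
    growth ``g``:  ``y(c, c_s) = g * f(alpha_F/g, c/psi)`` with ``f`` the
    upper-branch single-drug solution.  ``c`` is in units of the
    SMA-free IC50.
    """
    c_grid = np.asarray(c_grid, float)
    cs_grid = np.asarray(cs_grid, float)
    if np.any(c_grid < 0) or np.any(cs_grid < 0):
        raise ValueError("grids must be >= 0")
    g_vals = np.atleast_1d(np.asarray(response.g(cs_grid), float))
    if np.any(g_vals <= 0):
        raise ValueError("g(c_s) must stay positive on the grid")
    y = np.empty((c_grid.size, cs_grid.size))
    for j, g in enumerate(g_vals):
        alpha_eff = response.alpha_f / g
        shift = psi(response.alpha_f, g)
        for i, c in enumerate(c_grid):
            y[i, j] = g * steady_state_growth(alpha_eff, float(c / shift)).upper
    return DoseResponseSurface(
        c_grid, cs_grid, y,
        {"alpha_f": response.alpha_f, "ic50_f": response.ic50_f, "axes": ("ti", "sma")},
    )
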