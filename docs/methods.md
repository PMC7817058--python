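# Methods

## Model

The package models bacterial growth under ribosome-targeting antibiotics
through two empirical growth laws. Unbound (working) ribosome
concentration rises linearly with growth rate when nutrients vary,
`r_u = r_min + λ/κ_t`; under translation inhibition at fixed nutrients
the total ribosome pool is up-regulated as growth falls,
`r_tot = r_max − λ·Δr·(1/λ₀ − 1/(κ_t Δr))`. Antibiotic transport
(`p_in`, `p_out`), mass-action ribosome binding (`k_on`, `k_off`,
acting only on the translating fraction `r_u − r_min`), dilution of all
species at rate λ, and ribosome synthesis `s(λ) = λ·r_tot(λ)` close the
system. Growth is slaved to the working pool, `λ = κ_t·max(r_u − r_min,
0)`; negative growth (killing) is not modelled — the model describes
inhibition.

At balanced growth the single-drug system collapses onto

    c(y) = (1 − y)(4y² + α²) / [y(α² + 1)],   α = 2√(p_out κ_t K_D)/λ₀,

with `c` in IC50 units and `y = λ/λ₀`. All single-drug analysis
(steady-state roots, stability, bistable window, bifurcation threshold
`α_crit = 2/(3√3)`) runs on this closed form; stability uses the sign of
dc/dy (the middle of three roots, where dc/dy > 0, is unstable), which
tests cross-check against the eigenvalues of the full kinetic Jacobian.

For a drug pair, single-bound pools `r_b,A`, `r_b,B` and a double-bound
pool `r_d` interconvert with the second binding step scaled by the four
modifiers `δ_on,i`, `δ_off,i`. The growth law's bound pool is taken to
include `r_d` (`r_tot = r_u + r_b,A + r_b,B + r_d`): synthesis is the
same function of λ as in the single-drug model, and double-bound
ribosomes are still ribosomes. This identity holds automatically at
every fixed point (the summed pool equations give
`Σpools = s(λ)/λ = r_tot(λ)`), and is asserted in tests.

### Exactness of the reduced description

The steady-state cubic is the rapid-kinetics reduction of the kinetic
ODE system, not its literal fixed-point equation: eliminating the pools
exactly (verified symbolically) gives

    p_in a_ex / [Δr(1−y)] = (λ+p_out)(λ+k_off)κ_t/(k_on λ) + λ,

which reduces to the cubic when the terms `λκ_t/k_on` and
`κ_t(k_off+p_out)/k_on` are negligible — i.e. when binding is fast
compared to transport and growth (`k_on ≫ κ_t(k_off+p_out)/λ`,
`p_out ≫ λ`). The default kinetic presets used when a drug is specified
by its shape alone (`kinetics_from_shape`: `k_on = 10⁶ µM⁻¹h⁻¹`,
`p_out = 10³ h⁻¹`, with `k_off` and `p_in` solved from α and the IC50)
sit deep in this regime, keeping the gap between the kinetic fixed point
and the cubic below ~10⁻³ in y away from folds. Near a saddle-node the
gap is amplified by the diverging susceptibility dy/dc; this is visible
as an O(grid-step) displacement of the abrupt drop and is why the LI of
a competitively bound pair evaluates to ~10⁻⁴ rather than ~10⁻¹⁶.

## Steady-state numerics

Pair steady states use a one-dimensional reduction rather than 6-D
continuation: for trial growth `y` the three pool balances are linear
and eliminated in closed form; the two drug balances are solved by a
vectorised damped 2-D Newton iteration (finite-difference Jacobian,
positivity by step-halving, warm starts along the scan; convergence at
|F| < 10⁻¹¹·(1 + p_in·a_ex) plus a cancellation-floor allowance of
2·10⁻¹³ times the largest constituent term, since the residual is a
difference of terms of size ~k_on·u·a). The remaining scalar residual
h(y) — the unbound-ribosome balance — vanishes exactly at the fixed
points of the full system. Per concentration pair, h is scanned on a
fixed grid (25 log-spaced points below y = 0.04 plus 150 uniform points
up to 1), the topmost sign change is refined by 52 bisection steps, and
the largest root is reported.

**Branch policy.** The largest root is the observable in batch culture:
below the fold it is the upper branch; past the fold only the lower
branch remains, so the reported curve drops discontinuously. All roots
with 1-D stability flags are available (`pair_steady_states_all`,
`cerg_steady_states`) for bistability studies.

**Hidden folds.** Near a saddle-node the upper and middle roots approach
each other and can both fall inside one scan interval, leaving no
endpoint sign change. A refinement pass detects the parabolic signature
such a bump leaves in the smooth residual (vectorised pre-filter on the
extrapolated vertex), maximises the bump in a narrow bracket, and if it
pokes above zero takes the upper root it hides. The same machinery
serves the resistance-gene solver, whose inner problem is a closed-form
quadratic.

The Loewe additive reference for analytic shapes clears denominators of
`c_A/C_A(y) + c_B/C_B(y) = 1` into a quintic solved exactly per grid
point (batched companion-matrix eigenvalues); the topmost real root in
(0, 1] keeps the reference consistent with the branch policy, and the
analytic `C_i(y)` — defined on all of (0, 1] even for bistable shapes —
keeps it smooth where the observable curve jumps. For tabulated
(measured) curves, `C_i(y)` is a monotone linear interpolant; below the
curve's tabulated range the concentration is clamped at the largest
tabulated dose, so references for checkerboards whose corners exceed the
single-drug range are conservative there (supply curves covering the
summed dose range to avoid this, as `cerg_loewe_reference` does).

LI integrals are 2-D trapezoids on the stored grid (dense, smooth
integrands; no adaptive quadrature), with natural log and an "additive"
classification band of |LI| < 0.01 — the numerical noise floor of the
default pipeline, configurable.

**Degenerate inputs.** Irreversible binders (`k_off = 0`, α = 0) bypass
the cubic: the exact quadratic limit `4y(1−y) = c` is used, growth is
reported as arrested (y = 0) beyond full inhibition, and the IC50 is the
α→0 limit `Δr·λ₀/(4 p_in)`. The slow-growth rescaling c′ is undefined
at α = 0 and raises.

## Parameters and defaults

| parameter | default | units | rationale |
|---|---|---|---|
| κ_t | 0.06 | µM⁻¹h⁻¹ | standard growth-law fit |
| r_min, r_max | 19.3, 65.8 | µM | standard growth-law fits (Δr = 46.5) |
| λ₀ | 1.0 | h⁻¹ | mid-range drug-free growth; must be ≤ λ_max = κ_tΔr ≈ 2.79 |
| k_on, p_out (shape presets) | 10⁶, 10³ | µM⁻¹h⁻¹, h⁻¹ | rapid-kinetics regime (see above) |
| k_on, p_out (resistance presets) | 10³, 10 | µM⁻¹h⁻¹, h⁻¹ | field-typical rates; lets the removal flux dominate efflux |
| IC50 placement | 1.0 | µM | arbitrary scale; c-units are canonical |
| default grid | 121×121 on [0, 3]² | IC50 units | dense-grid evaluation standard for these surfaces; quick-look analyses (δ sweeps, phase diagrams, resistance pairs) use 41–61 points per axis |
| additive band | 0.01 | — | noise floor of LI on default grids |

Resistance comparisons use the field-typical preset because all their
quantities (baseline vs resistant curves and surfaces, rescaled axes,
numeric Loewe references) are computed within the kinetic model itself —
the cubic correspondence is not involved — and with fast efflux the
growth-coupled removal flux would be a minor correction rather than the
dominant feedback under study.

## Three-drug consistency

The occupancy-state solver builds the master-equation generator over the
(up to eight) ribosome occupancy states with binding rates c′_i and unit
unbinding rates, under the slow-growth assumptions (growth proportional
to unblocked ribosomes, near-zero dilution, transport-dominated drug
levels). Its stationary distribution reproduces the closed forms
`(λ_max/λ₀)/[(1+c′_A)(1+c′_B)(1+c′_C)]` (independent) and the
restricted-partition forms under pairwise competition. The maxent
composition formula matches these exactly only when the `λ_max/λ₀`
prefactor is 1 (applied to marginals carrying a prefactor κ it returns
`3κ² − 2κ³ ≠ κ`), so consistency checks run at `λ₀ = λ_max`; this is
the implicit normalization under which the responses `y_i = 1/(1+c′_i)`
are extracted.

## What the presets emulate, and what they do not

Drugs specified by α alone stand for idealized translation inhibitors
on the growth-law backbone: deterministic, population-averaged, with
binding/transport split chosen for numerical fidelity rather than fitted
to a particular compound. Reference α values are shipped for
chloramphenicol (1.04) and streptomycin (0.46), and the resistance
presets (`V′_max = 1000 µM h⁻¹`, `K_rem = 0.1 µM`; activity sweep
{0, 100, 950} µM h⁻¹) reproduce the qualitative resistance phenomenology
(steepening, IC50 gain, interaction shift) rather than any specific
enzyme — the transport parameters behind a real resistant strain are not
determined by α, so quantitative resistance gains are preset-dependent.
Passing tests therefore demonstrate the model's internal mathematics and
its qualitative predictions, not agreement with any particular
experimental strain.

## Known limitations

- Suppression (growth increased by adding a drug) requires mechanisms
  outside this model and is not produced.
- The translation cycle and ribosome assembly are not resolved; fully
  assembled ribosomes are the only target.
- α is an input; fitting it to measured dose-response curves is out of
  scope.
- The full kinetic system is solved for at most two drugs; triples are
  handled only in the slow-growth approximation.
- The steepness metric `max|Δy/Δc|` is grid-dependent for discontinuous
  curves (it grows with refinement at an abrupt drop) — intended, but
  comparisons must use a common grid.
- Time-course hysteresis and single-cell stochastic dynamics are not
  modelled.
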