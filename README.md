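# ribocomb

Predicting the combined action of ribosome-targeting antibiotics from
bacterial growth laws.

## The problem

When two antibiotics are combined, bacterial growth can be suppressed
more (synergy) or less (antagonism) than an additive expectation built
from the drugs' individual dose-response curves. Measuring every pair at
every dose is combinatorially hopeless, and the molecular mechanisms
behind most drug interactions are unknown. For translation inhibitors,
however, the physiological feedback between ribosome content and growth
is described quantitatively by two empirical *growth laws*, which makes
a predictive, essentially parameter-free biophysical model possible.

`ribocomb` implements that model for computational biologists and
quantitative pharmacologists: from single-drug response parameters it
predicts full two-drug dose-response surfaces, classifies the interaction
with the Loewe interaction score, and extends the picture to
starvation-mimicking antibiotics (SMAs) and constitutively expressed
resistance genes (CERGs).

## The model

Growth laws (concentrations in µM, rates in h⁻¹):

- nutrient law: `r_u = r_min + λ/κ_t`
- inhibition law: `r_tot = r_max − λ·Δr·(1/λ₀ − 1/(κ_t·Δr))`

with the standard constants `κ_t = 0.06 µM⁻¹h⁻¹`, `r_min = 19.3 µM`,
`r_max = 65.8 µM`, `Δr = 46.5 µM`. A single drug enters the cell
(`J = p_in·a_ex − p_out·a`), binds translating ribosomes
(`f = −k_on·a·(r_u − r_min) + k_off·r_b`), and every species dilutes at
rate λ. At balanced growth the system reduces to a cubic for the
relative growth rate `y = λ/λ₀` whose shape is set by one dimensionless
number, the response parameter

    α = λ₀*/λ₀,   λ₀* = 2·√(p_out·κ_t·K_D),   K_D = k_off/k_on,

with the exact inverse dose-response

    c(y) = (1 − y)(4y² + α²) / [y(α² + 1)]      (c in IC50 units).

Large α gives shallow Langmuir-like curves (`y → 1/(1+c)`); below
`α_crit = 2/(3√3) ≈ 0.385` the curve folds and growth is bistable, with
an abrupt drop at the upper edge of the bistable concentration window.

For two drugs, ribosomes can also be double-bound; the second binding
step is scaled by modifiers `δ_on,i`, `δ_off,i` (1 = independent
binding, `δ_on = 0` = competitive binding). Competitive binding provably
yields linear isoboles — additivity — for any pair; double-bound
ribosomes are what generate synergy and antagonism. The interaction is
scored as

    LI = ln( ∫∫ y dc_A dc_B / ∫∫ y_add dc_A dc_B ),

negative for synergy, positive for antagonism, with the Loewe additive
reference `y_add` solving `c_A/C_A(y) + c_B/C_B(y) = 1`.

Extensions: an SMA rescales λ₀ by its own dose-response `g(c_s)`,
shifting the partner inhibitor's IC50 by
`ψ = (α_F² + g²)/((α_F²+1)·g)`; a CERG removes drug at rate
`V′_max·(λ/λ₀)·a/(a + K_rem)`, a growth-coupled positive feedback that
steepens dose-response curves and pushes interactions toward antagonism.
A three-drug occupancy model in the slow-growth limit reproduces the
entropy-maximization composition formula
`y_ABC = y_A y_BC + y_B y_AC + y_C y_AB − 2 y_A y_B y_C` exactly.

## Worked example

Two steep antibiotics (`α = 2⁻⁵`), independent binding, via the CLI:

```sh
$ cat steep_pair.yaml
drugs:
  - name: drugA
    shape: {alpha: 0.03125}
  - name: drugB
    shape: {alpha: 0.03125}
grid: {c_max: 3.0, n: 61}
output_dir: out

$ ribocomb surface --config steep_pair.yaml
LI=+0.3026 (antagonism) -> out/surface.csv
```

`LI = +0.30` classifies the pair as antagonistic: two steep (nearly
irreversibly binding) drugs protect the cell from each other because
ribosomes inactivated by one drug soak up the other. Repeating with
`alpha: 4.0` gives `LI = −0.55` (synergy), and setting the `deltas`
block to zero `on` values gives `LI ≈ 0.000` (competitive binding is
additive). The same objects are available as a library:

```python
>>> import ribocomb as rc
>>> rc.alpha_crit()
0.3849001794597505
>>> rc.bistable_window(0.2)        # IC50 units
(0.6873962308391968, 1.001678911788905)
>>> rc.psi(0.46, 0.46)             # strongest IC50 drop for alpha_F = 0.46
0.7593265103994717
```

Other CLI commands: `curve`, `score` (LI of an external checkerboard
CSV), `phase-diagram`, `triple`, `sma`, `cerg`.

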