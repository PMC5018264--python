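# Methods

## Model

The cell is three pooled populations: precursors P (the amino-acid pool),
metabolic enzymes/transporters T, and ribosomes R. Food import and
conversion produce P at rate `K_P` per transporter; ribosomes consume P at
rate `k·(P/V)` each and split the resulting protein synthesis between the
two sectors according to the allocation `f_R` (ribosomal) and
`f_T = 1 − f_R` (metabolic), with `m_T` and `m_R` residues per finished
molecule. T and R degrade at first-order rates `d_T`, `d_R`; P degradation
is taken as exactly zero (it is biologically negligible and is not a
parameter). Units are hours and cubic micrometres throughout; there is no
unit-conversion layer.

The load-bearing structural assumption is the volume law
`V = v_P P + v_T T + v_R R`: making V a linear function of the populations
(i) turns the exponential ansatz into an exact solution and (ii) eliminates
absolute population sizes, leaving a closed equation for the growth rate.
Because the equations are written for populations rather than
concentrations there is no dilution term; the model describes a growing
culture (or a non-dividing growing cell) and contains no division events.

## Analytic steady state

Substituting `P,T,R ∝ e^{μt}` gives the ratios P/V, T/R, P/R in closed form
and a quadratic `α μ² − β μ + γ = 0` with `a = ν f_T − d_T`,
`b = ρ f_R − d_R`, `γ = ab`, `β = a + b + ε₂`, `α = 1 − ε₁`, where
`ν = K_P/m_T` and `ρ = k/(m_R v_P)` are the nutritional and ribosomal
efficiencies and

```
ε₁ = (f_T/m_T)(v_T/v_P) + (f_R/m_R)(v_R/v_P)
ε₂ = (f_T/m_T)(v_T/v_P) d_R + (f_R/m_R)(v_R/v_P) d_T
```

are volume corrections of order `1/m`. The smaller root μ₋ is the physical
one; the suite verifies this three ways (simulated trajectories converge to
μ₋ and its ratios; μ₋ → 0 in both allocation limits at zero degradation;
μ₊ implies negative populations at large equal m).

## Numerical choices

* **Quadratic solve.** Cancellation-free form (larger-magnitude root from
  the formula, the other from `γ/α·root`), followed by two Newton polish
  steps — near a root collision the closed form loses half its digits.
  `|α| < 1e−12` falls back to the linear equation `βμ = γ` (ε₁ → 1 is
  unphysical but must not crash). Complex roots are reported as an
  infeasible state, never an exception, so sweeps can traverse them.
* **P/R conditioning.** The bracket `K_P f_T/(m_T(μ+d_T)) − 1` in P/R
  cancels catastrophically near marginal feasibility (precursor pool almost
  empty). It is evaluated in 80-bit extended precision, and when the given
  μ is — to double rounding — a root of the characteristic quadratic, μ is
  first re-polished at that precision so that the float hand-off does not
  limit the ratios. Back-substitution residuals of the balance equations,
  normalised per equation by its largest flux, then stay below 1e−10 for
  random growing parameter sets.
* **Feasibility.** `bracket ≥ −1e−9·(1+|scale|)` counts as feasible:
  bracket = 0 is the legitimate marginal state P/R = 0. At μ = 0 with
  `d_R = 0` the P/R expression divides by zero; the state is reported
  infeasible with an explanatory reason rather than assigned a limit value.
* **Integration.** `scipy.integrate.solve_ivp` with LSODA, `rtol = 1e−8`
  and per-species `atol = 1e−12 ×` initial population: the pools span ~4
  orders of magnitude (`m_R = 1e4`), and the initial precursor relaxation
  is much faster than growth, so a stiff-capable method is required.
  Populations are never clipped. Default initial state `P = 10·m_R`,
  `T = R = 10`; the dynamics are scale invariant (degree-1 homogeneous), so
  this only sets the transient, and tests confirm insensitivity to seeded
  random starts.
* **Growth-rate extraction.** OLS log-slope per species on the last 25% of
  the time span (≥10 points required), pooled by averaging; the maximum
  pairwise slope discrepancy is the convergence diagnostic with threshold
  1e−4 /hr. Species identically zero along the whole trajectory (an empty
  Q sector) are excluded; any other nonpositive tail value is an error.
* **Optimization over f_R.** 256-point interior grid scan (infeasible
  points get −∞ in the reported scan and a large finite penalty inside the
  refiner, whose parabolic steps NaN on infinities) followed by bounded
  scalar maximization in the bracketing cells, `xatol = 1e−10`. Plateau
  ties resolve to the smallest f_R. The large-m closed forms are always
  reported alongside the numeric optimum, never silently substituted.

## The approximation structure near the optimum

A finding the test suite leans on: for `v_T, v_R > 0` the two quadratic
roots cannot cross as f_R varies — they exhibit an avoided crossing of gap
`~2√(ε₁ab)` at the allocation where `a = b`. Since the optimum sits exactly
there, the numeric optimum differs from the large-m closed forms by
`O(√ε₁) = O(1/√m)`, not `O(1/m)`: with all three molecular volumes equal
(`m_T = 500`) the optimized growth rate is ~2% below `μ_max` and the
economy residual at the numeric optimum is ~0.1. The closed forms are
*exact* when the precursor dominates the volume (`v_T = v_R = 0`, where
`μ₋ = min(a,b)` identically — the same limit the linear model uses).
Studies therefore pick the volume law matching the claim under test:

* convergence of the numeric optimum to the closed forms is demonstrated
  under the bulk-volume law `V = v_P(P+R)` (transporters live in the
  membrane, not the interior), which gives a clean monotone `O(1/√m)`
  approach reaching ~5e−4 relative at `m = 1e5`;
* recovery of the growth-law constants and of the cellular-economy
  identity at the optimum is demonstrated in the precursor-dominated
  regime, where it is exact to optimizer tolerance;
* simulation↔analytic agreement uses unrestricted random volumes — the
  quadratic is exact for any volume constants.

## Growth laws

`MediumModel` maps food concentration to ν either linearly (`ν = k₁[F]`)
or with transport-limited Michaelis–Menten saturation
(`ν = ν₀[F]/(K+[F])`); which is appropriate is medium-dependent, so both
are provided. Monod constants are implemented only for `d_T = d_R = 0`
(`μ_max = ρν/(ρ+ν)` holds only there); with degradation the Monod-like
curve is produced numerically by the medium-quality sweep instead.
Sweeps default to 12 log-spaced qualities in [0.5, 64] and 8 halvings of
k; each row carries both the numeric and the closed-form optimum, and rows
without an optimum are flagged rather than dropped. Growth-law constants
are recovered by OLS of Φ_R on μ_max, mapping slope and intercept to
(Φ_R^min, κ_t) or (Φ_R^max, κ_n).

## Extensions

The Q sector (fixed proteome fraction, allocation `f_Q`, `f_T+f_R+f_Q=1`)
is implemented for `d_T = d_R = 0` only; other degradation values raise an
explicit unsupported-case error rather than guessing formulas. Its numeric
cross-check optimizes the 4-species ODE by grid + bounded search where each
evaluation is a simulation with log-slope extraction; because μ(f_R) is
flat (quadratic) at the optimum, f_R resolves only to roughly the square
root of the μ accuracy — tolerances in the tests are 1e−2 relative on μ
and a few e−2 on f_R. The linear model (`V ≈ v_P P`) uses the closed
triangular spectrum {0, −d_T, b} rather than a numeric eigensolver; it is
meaningful only for `f_R ≤ f_max` (beyond, its eigenvector P turns
negative while the full model remains well behaved).

## Random parameter generation

`generate_fixtures` draws scale parameters (rates, residue counts, v_P)
log-uniformly and bounded quantities (degradations, allocation, v_T, v_R)
uniformly, over ranges bracketing an enteric-bacterium regime
(`K_P ∈ [50, 1000]`, `k ∈ [1e−4, 2e−3]`, `m_T ∈ [100, 2000]`,
`m_R ∈ [2e3, 5e4]`, `d_T ≤ 0.2`, `d_R ≤ 0.02` /hr). With the growth filter
on, sets are rejection-sampled until μ₋ > 0 with feasible ratios; more than
1e4 consecutive rejections abort with an explicit error. What this
generator emulates is *parameter* diversity around the balanced-growth
regime; it does not emulate measurement noise, cell-to-cell variability,
division, or regulation dynamics, so passing tests validate the
deterministic pooled-population model, not single-cell data.

## Problem sizes

The default validation batch is 100 random growing parameter sets, each
simulated for 30/μ₋ hours at 256 output points (~1.5 s total); the
convergence study spans m ∈ {1e2, 1e3, 1e4, 1e5}; sweeps use 4–8 points;
the Q-sector ODE cross-check uses a 12-point grid plus refinement (~30
simulations). These sizes were chosen to keep the whole suite interactive
while leaving every tolerance comfortably resolved.

## Known limitations

* Cell size, division timing and single-cell stochasticity are out of
  scope; the model is deterministic and population-pooled.
* The optimization *assumption* stands in for regulation; no mechanistic
  feedback (ppGpp-style) is modelled.
* Unimodality of μ₋(f_R) is observed on all tested parameter sets but not
  proven; the optimizer guards with a configurable grid and flags rather
  than assumes.
* With comparable molecular volumes the large-m formulas carry `O(1/√m)`
  corrections near the optimum (see above); quantitative use of the closed
  forms at `m_T ≈ 500` incurs ~2% error in μ_max and ~10% in f_max.
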