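# Methods

## Model and assumptions

`avibind` models one bivalent, monospecific antibody binding antigens on the
membrane of a single target cell, by mass action in a well-mixed system.
State variables are per-cell molecule numbers: free antigens `r(t)`, free
antibodies `A0(t)`, monovalently bound `A1(t)` and bivalently bound `A2(t)`
antibodies. Assumptions that define the scope:

- The two antibody arms are identical and independent; statistical factors of
  2 therefore multiply first-arm association (`2·k1·r·A0`, either arm can
  bind) and bivalent dissociation (`2·koff·A2`, either arm can release).
- Antigens are uniformly distributed and mobile; cross-linking is limited by
  antigen diffusion toward the bound antibody's free arm.
- Antigen internalization, antigen dimerisation, spatial gradients,
  stochasticity in molecule numbers and effector-function pharmacology are
  all outside the model. Occupancy and bound-antibody counts are reported as
  proxies for effector potency, not as a response model.
- Dynamics are deterministic and continuous; molecule counts are real-valued.

Conservation (`A0+A1+A2 = Atot`, `r+A1+2A2 = rtot`) reduces the dynamics to
`(A1, A2)`; the four-variable system is retained for testing.

## Parameters

| symbol | meaning | default | units |
|---|---|---|---|
| `kon` | solution association rate | 1e5 | s⁻¹M⁻¹ |
| `koff` | per-arm dissociation rate | 1e-4 | s⁻¹ |
| `D` | antigen membrane diffusion coefficient | 1e-14 | m²s⁻¹ |
| `rtot` | antigens per cell | 1e4 | molecules |
| `Ainit` | antibody dose | — | M |
| `Vwell` | assay well volume | 150e-6 | l |
| `T0` | target cells per well | 2e5 | cells |
| `Trad` | target cell radius | 8e-6 | m |
| `rAb` | antibody arm-to-arm reach | 12.5e-9 | m |

Defaults are literature values for human cancer lines and anti-tumour IgG
(trastuzumab-like). Derived quantities: `σ = Vwell·Na/T0` (molecules of
antibody available per cell and molar unit, ≈4.52e14; quoted as 4.5e14),
`Atot = Ainit·σ`, `k1 = kon/σ`, and `k2 = D/(4π·Trad²)` (diffusion-limited
first-hitting estimate, ~1e-6..1e-4 s⁻¹ over the literature span of D). An
alternative `k2` estimator for immobile antigens — proximity-limited,
`38e3·kon/(π·Na·Trad²·rAb)` — is selectable (`k2_mode="proximity"`) but not
the default: the swept-disc area of an IgG arm is only ~6e-7 of the cell
surface, so for realistic antigen densities (1e4–1e6 per cell) diffusion, not
static proximity, is rate limiting.

## Equilibrium solution

With `K1 = k1/koff`, `K2 = k2/koff` and hat scaling `Â1 = K2·A1*` etc., the
cross-linking balance gives `Â2 = Â1(r̂−Â1)/(2(1+Â1))` and substitution into
the monovalent balance yields the cubic

```
(1−K21)x³ + 2(1−Â−K21)x² + (2Â(r̂−1) − K21 − r̂² − 2r̂)x + 2Âr̂ = 0,
```

where `K21 = K2/K1 = k2σ/kon` and `Â = K2·Atot`. The cubic was re-derived
symbolically from the steady-state conditions (sympy-checked) rather than
transcribed. For `K21 ≫ 1` — which holds across the entire default parameter
space — the coefficient sequence has one sign change, so by Descartes' rule
there is exactly one positive root: the unique stable equilibrium.

Numerics: closed-form roots (`numpy.roots`), selection of the positive root
respecting both conservation bounds, three Newton polishing steps, and a
residual check of both rate balances at 1e-8 relative. If selection or the
residual check fails (e.g. `K21 ≈ 1`, or deep tight binding where
`A0 = Atot−A1−A2` suffers catastrophic cancellation), the solver falls back
to a free-pool parametrization: writing `a1 = 2K1·r·a0`, `a2 = K1K2·r²·a0`
makes both balances hold identically, antibody conservation gives `a0(r)` in
closed form, and antigen conservation becomes a bracketed scalar root problem
in `r` with no subtractive cancellation in any term. Degenerate inputs
(`Atot = 0`, `rtot = 0`, `k2 = 0`) short-circuit to the trivial or monovalent
solution; the monovalent model solves its quadratic in the numerically stable
form `A1 = 2c/(b+√(b²−4ac))`.

Equilibrium (not transient) values feed all metrics: for most doses binding
equilibrates in under a second, far faster than effector-function time
scales; at the very lowest doses equilibration is slow but the equilibrium
value remains the relevant summary.

## Steady-state integration (the ODE oracle)

`integrate_to_steady_state` integrates the reduced system (BDF, analytic
Jacobian, rtol 1e-10) on geometrically growing horizons. Convergence demands
both a derivative-norm criterion and a plateau criterion (state change below
1e-10 relative over the last horizon doubling). The derivative threshold
(default 1e-12 molecules/s) is floored at `64·eps·‖J‖·max(rtot, Atot)`:
because free pools are differences against the totals, a float64 evaluation
of the right-hand side cannot be more accurate than that, and demanding more
would loop forever on perfectly converged states. The integrator exists as an
independent cross-check of the cubic solver (they agree to better than 1e-6
relative over the sampled parameter space; typically 1e-12) and for
trajectory output; all production paths use the algebraic solver.

## Dose-response and ΔEC50 conventions

The default dose grid is 121 log-spaced points over 1e-13..1e-3 M
(configurable). EC50 is defined directly on the model curve: the first dose,
log-linearly interpolated within its grid interval, at which the signal
crosses half of the maximum attained on the grid. The bivalent bound-count
curve is biphasic (bivalent plateau near `rtot/2`, then a monovalent-driven
rise toward `rtot`), so both the "first crossing" rule and the upper dose
bound are part of the EC50 definition and materially affect ΔEC50 for that
signal; reported map values should be read with the grid convention in mind,
and orderings across parameter cells are the robust content. The affinity
axis of avidity maps is traversed by fixing `kon = 1e5 s⁻¹M⁻¹` and setting
`koff = KD·kon`, which propagates `KD` into `K2 = k2/koff` as the
cross-linking physics requires; traversing via `kon` instead would leave `K2`
unchanged and describe a different experiment.

## Sensitivity analysis

Sobol first-order (`S_i`) and total-order (`ST_i`) indices are estimated with
the Saltelli cross-sampling design on a scrambled Sobol sequence
(`scipy.stats.qmc`; base size N a power of two, default 1024, giving
`N(n+2)` model evaluations without second-order blocks and `N(2n+2)` with
them). Estimators: Saltelli-2010 for `S_i`, Jansen for `ST_i`, with outputs
centred before estimation — essential when an output nearly saturates and its
variance is tiny. Bootstrap resampling of the base sample (100 draws) gives
standard errors. An inert dummy parameter rides through the full design; its
indices estimate the noise floor (observed ST < 1e-3 at N=1024).

Parameters are sampled log-uniformly over their literature ranges (`kon`
1e4–1e6, `koff` 1e-6–1e-3, `rtot` 1e4–1e6, `D` 1e-15–1e-13; each spans ≥2
decades, for which a linear-uniform prior would concentrate nearly all mass
in the top decade). Linear-uniform sampling is selectable; it changes the
indices materially — at high dose it even reverses the kon/koff ordering —
which is worth remembering when comparing against analyses whose sampling
scale is unreported. Failed equilibrium rows abort the analysis rather than
being imputed; none occur within the default ranges.

Observed behaviour (N=1024, occupancy): at low dose (≤1e-9 M) `rtot`
dominates (`ST ≈ 0.95–0.98`); at high dose the binding rates take over with
`koff` above `kon`. At the extreme high dose of 1e-5 M the converged indices
are `ST(kon) ≈ 0.57`, `ST(koff) ≈ 0.81`, with a large interaction component
(the residual unoccupancy depends on `koff/kon`, which is not additive in the
log-uniform factors); N=1024 estimates at this dose carry noticeable
design-to-design spread (±0.1) because the output variance is dominated by
the weak-binder corner of parameter space.

## Synthetic-data scope

The package generates all of its own inputs: parameter sweeps and
quasi-random designs over literature ranges. Defaults encode a standard
in-vitro binding assay (150 µl well, 2e5 cells, 8 µm cell radius) and
IgG-like kinetics. What this does not emulate: measurement noise, antigen
internalization or turnover, heterogeneous antigen distribution, steric
hindrance of the second arm, and cell-to-cell variability. Passing tests
demonstrate internal consistency of the model and its solvers over these
idealised conditions, not agreement with any particular experimental trace.

## Known limitations

- ΔEC50 magnitudes for biphasic signals depend on the dose-grid convention
  (see above); only orderings are convention-free.
- The proximity `k2` estimator is implemented with its published prefactor
  (38e3) taken verbatim; its unit provenance is not re-derived here.
- The `K21 ≈ 1` regime bypasses the cubic and is handled only by the
  numerical fallback.
- No stochastic (SSA) or spatial variant; low-copy antigen numbers (<~100)
  stretch the continuum assumption.
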