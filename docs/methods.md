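# Methods

## Model and procedure

`ggflux` treats GG salvage as a constraint-based modeling problem. A
stoichiometric model (metabolites, reactions with bounds, a biomass
objective) is extended with seven GG reactions — exchange, two transport
steps, leakage, a storage sink, and the two candidate Slr1670 cleavage
chemistries — and interrogated with flux balance analysis: maximize the
biomass flux subject to steady state S·v = 0 and lb ≤ v ≤ ub. The
assumptions are the standard FBA ones: balanced exponential growth,
optimality of the flux distribution for growth, and time-invariant
constraints within each analysis interval. Light limitation enters only
through a fixed photon-uptake bound; no explicit photophysiology, salt
regulation or osmotic mechanics is modeled.

Fitness comparisons are ratios of growth optima. The GG supply is imposed
as an equality (lb = ub) on the supplying reaction — the exchange flux for
exogenously fed GG, the synthesis flux for endogenous scenarios — so that
the numerator and denominator of a ratio see the same carbon availability
and differ only in whether a utilization route may carry flux. The storage
sink keeps utilization-blocked configurations feasible: GG that cannot be
cleaved is banked rather than rendering the LP infeasible. Because the sink
contributes nothing to biomass, banked GG confers no advantage, which is
the intended semantics ("GG available but optionally unused").

Mutant genotypes are constraint sets: ΔggpS removes synthesis, ΔglpK the
glycerol kinase, Δslr1670 removes hydrolase *and* phosphorylase (one gene,
two candidate activities), the double mutant the union. Knockouts never
touch the objective reaction; attempting to is an error.

## Parameters that matter

| parameter | unit | default | rationale |
|---|---|---|---|
| photon bound P | mmol·gDW⁻¹·h⁻¹ | 100 (toy) | sets the growth scale; full models use their shipped bound |
| qGG supply | mmol·gDW⁻¹·h⁻¹ | interval-measured 0.008/0.015/0.014/0.009/0.003 | the five per-interval uptake rates derived from glycerol production of a GG-fed, synthesis-deficient strain |
| cleavage mode | — | `both` | hydrolysis, phosphorolysis or both open; the chemistry of Slr1670 is unresolved, so it is a switch, not a constant |
| sweep grid | mmol·gDW⁻¹·h⁻¹ | 50 log-spaced points, 1e-4…1.5 | spans well below the measured range up to ~100× its maximum, since "very high" supply is otherwise unquantified |
| dw_per_od | g·L⁻¹ per OD₇₃₀ | 0.2 | dry-weight conversion for biomass-specific rates |
| volume_per_dw | µL·mg⁻¹ | 1.0 | intracellular-volume conversion for concentrations |
| LP feasibility | — | 1e-9 | primal/dual tolerance passed to HiGHS |

Default flux bounds when a source file omits them are ±1000 (reversible)
and 0/1000 (irreversible) mmol·gDW⁻¹·h⁻¹, the de-facto convention of the
model family. Ratio tables are rounded to 0.1 percentage points for
display; raw values are kept in all returned objects.

## The toy model

The synthetic model is a deliberately minimal photoautotroph: photons →
ATP (1:1), CO₂ fixation at 2 ATP per generic fixed-carbon unit (`ch2o`),
biomass = 1 ch2o + 1 ATP. GG costs 9 ch2o + 1 ATP to synthesize; salvage
returns its glucose as 6 ch2o (minus 1 ATP at glucokinase, spared by the
phosphorolytic route) and its glycerol as 3 ch2o (minus 1 ATP at glycerol
kinase, otherwise excreted). All coefficients are small integers, so the
optima are exact rationals derivable by hand:

    BOFmax(closed)              = P/3
    BOFmax(hydrolysis + GlpK)   = (P + 16 q)/3
    BOFmax(phosphorolysis+GlpK) = (P + 17 q)/3
    BOFmax(hydrolysis, ΔglpK)   = (P + 11 q)/3

These closed forms are frozen in the tests and cross-checked against two
independent routes: a brute-force vertex-enumeration LP oracle and the
cobrapy/GLPK stack reading the serialized model. The toy model's ABC uptake
carries no ATP cost (one fewer coupling to keep the closed forms short);
consequently it slightly overstates the salvage benefit relative to a model
that charges for transport. Species that are pure bookkeeping (photon, the
lumped ATP, glycerol 3-phosphate) deliberately carry no formula, and the
balance checker reports them as `unknown` rather than pretending balance;
all carbon-carrying reactions of the extension balance exactly in C, H, O
and P using neutral (fully protonated) formulas.

## The culture simulator

Simulated cultures grow exponentially at `mu_true` from `od0` until a
self-shading onset OD (default 1.0), then linearly with the slope matched
at the switch — the exponential-then-linear shape of dense
photoautotrophic batch cultures. Extracellular glycerol is the analytic
integral of biomass times the generating qGG (0.2 gDW/L per OD, 24 h/day,
one glycerol per GG). Noise is multiplicative log-normal (measurements are
positive), 2% on OD and 5% on glycerol by default, loosely matching
replicate scatter of such experiments — not a fitted claim. Default
sampling is every 0.5 d over 0–10 d: the qGG estimator's trapezoidal
biomass mean has O(h²) discretization bias, ~12% at 2-day spacing for
μ = 0.6 d⁻¹ but <1% at 0.5 d, and the finer grid keeps the estimator's
noiseless error below the 1% contract. What the generator does *not*
emulate: day/night cycling, salt-dependent regulation of GG synthesis,
glycerol re-uptake, the transient OD drops seen in real cultures, or any
coupling of growth rate to GG utilization. Passing the parameter-recovery
tests therefore demonstrates that the estimators invert the stated
generative model under realistic noise — not that real cultures satisfy
that model.

## Numerical choices

* LP solver: HiGHS via `scipy.optimize.linprog`, feasibility 1e-9.
  Optimal flux vectors are degenerate in general (e.g. the cost-free
  leakage/uptake cycle of the GG extension); only objective values are
  contractual, and tests assert only those.
* `fitness_ratio` at qGG = 0 compares two identical LPs and returns exactly
  100%; a denominator optimum below 1e-8 raises an undefined-ratio error
  instead of dividing.
* The vertex-enumeration oracle fixes n − rank(S) variables at bounds,
  solves the equality system by least squares, and rejects candidates whose
  residual exceeds 1e-8; it requires finite bounds, which the random-model
  generator guarantees (and keeps v = 0 feasible in most draws so that
  infeasibility is the exception, not the rule).
* qGG estimation uses the trapezoidal mean OD over the interval
  (endpoint-mean selectable); decreasing glycerol returns qGG = 0 with a
  `glycerol_decreased` flag, since re-uptake is outside the model.
* Negative growth rates (declining OD) are reported as-is; ratio tables
  carry them unchanged because masking them would hide real culture
  behavior, but they are not meaningful as growth comparisons.
* Degenerate inputs: empty models are valid containers (S is 0×0) and only
  fail at FBA time; a model with reactions but no declared objective is
  rejected at load.

## Design decisions

* Seven reactions ship with `add_if_absent` semantics: applying the
  extension to a reconstruction that already contains GG synthesis or
  exchange does not duplicate them, and re-applying the extension is a
  no-op.
* Id canonicalization stores BiGG-style ids internally and applies SBML
  escaping (`_DASH_`, `_LPAREN_`, `_RPAREN`) only at serialization; ids
  matching a bundled alias table case-insensitively are normalized, which
  reconciles the all-caps spellings found in figure legends with canonical
  BiGG form.
* The cleavage chemistry (hydrolysis/phosphorolysis/both) and the GG supply
  route (exchange vs synthesis flux) are configuration switches with
  defaults `both` and exchange-fed, because the underlying biology is
  unresolved; every analysis is runnable under each assumption.
* The strain-comparison and sweep problem sizes (5 intervals × ≤5 strains,
  50-point grids, 200 recovery cultures, 50 random oracle models) were
  chosen so the entire suite solves a few hundred small LPs; each is
  milliseconds, keeping the full analysis interactive.

## Known limitations

* FBA predicts growth only: intervals where the measured OD declines have
  no meaningful simulated counterpart.
* A constant photon-uptake bound understates the benefit of GG salvage in
  light-limited (late, dense) culture phases, where a fixed per-cell energy
  subsidy buys relatively more growth.
* The toy model's single lumped energy currency ignores redox (NADPH)
  bookkeeping; cleavage-mode comparisons on it reflect ATP stoichiometry
  only.
* Full-scale conclusions require the published genome-scale reconstruction;
  this package ships the machinery (loaders, strain remapping via
  `id_overrides`, sweeps, ratio tables) but no third-party model file, and
  records model provenance in the run manifest instead of assuming a
  version.
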