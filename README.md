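# ggflux

Constraint-based analysis of glucosylglycerol (GG) salvage in the
cyanobacterium *Synechocystis* sp. PCC 6803.

Under mild salt stress *Synechocystis* accumulates GG, a C9 osmolyte
(glucose α-glycosidically linked to glycerol) whose synthesis costs the
fixation of 9 CO₂. When the osmotic pressure relaxes, cells that can salvage
those carbons — cleaving GG via the Slr1670 glycoside hydrolase into a
glucose moiety that re-enters metabolism and a glycerol moiety that is
largely excreted — should hold a fitness advantage. `ggflux` quantifies that
advantage with flux balance analysis (FBA) and estimates the underlying
uptake fluxes from batch-culture measurements. It is aimed at
systems-biology practitioners who work with genome-scale metabolic models of
cyanobacteria and at experimentalists converting OD₇₃₀/HPLC time series into
specific rates.

## What it computes

**FBA.** For a stoichiometric matrix S, flux vector v with bounds
lb ≤ v ≤ ub, the growth optimum is the LP

    BOFmax = max { c·v : S·v = 0, lb ≤ v ≤ ub }

with c selecting the biomass objective (h⁻¹). Fluxes are in
mmol·gDW⁻¹·h⁻¹, uptake negative by the BiGG exchange convention.

**The GG extension.** Seven reactions wire GG salvage into a host model:
`EX_glcglyc(e)`, `GLCGLYCtex`, `GLCGLYCABCpp_syn` (GgtABCD uptake),
`glcglyctpp` (leakage), `GLCGLYCstorage` (cytosolic sink, so osmotic
accumulation is representable at steady state), and the two candidate
cleavage chemistries assigned to *slr1670*:

    GLCGLYCHyd:             h2o_c + glcglyc_c → glc__D_c + glyc_c
    GLCGLYCPhosphorylase:   pi_c  + glcglyc_c → g1p_c    + glyc_c

**Fitness ratio.** With the GG supply flux fixed at a measured qGG, the
benefit of a utilization route U is

    ratio = 100 × BOFmax(U ∈ [0, ∞)) / BOFmax(U = 0)   [%]

Mutant genotypes (ΔggpS, ΔglpK, Δslr1670, the double mutant) are constraint
sets (lb = ub = 0 on the corresponding reactions).

**Culture analysis.** From (time, OD₇₃₀, extracellular glycerol) series:
μ = ln(OD₁/OD₀)/Δt; qGG = Δ[glycerol] / (0.2·⟨OD⟩·Δt·24) in
mmol·gDW⁻¹·h⁻¹ (0.2 gDW·L⁻¹ per OD unit, one glycerol per GG cleaved);
intracellular concentrations assume 1 µL cell volume per mg dry weight.

Every stage runs without downloads: `ggflux.synthetic_data` provides a toy
photoautotroph whose LP optima have closed forms (BOFmax = P/3 at photon
bound P) and a seeded batch-culture simulator. Full-scale models
(SBML L3+fbc or BiGG JSON) drop into the same pipeline.

## Worked example

```python
import ggflux as gf

model = gf.make_toy_model()                      # photon bound 100
print(gf.solve_fba(model).objective_value)       # 33.33333333333333  (= 100/3)

# growth benefit of GG cleavage at the largest measured uptake rate
print(gf.fitness_ratio(model, {"GLCGLYCHyd", "GLCGLYCPhosphorylase"}, 0.015))
# 100.255  -> a 0.26% growth advantage at qGG = 0.015 mmol/gDW/h

# phosphorolysis vs hydrolysis across supply rates
sweep = gf.sweep_cleavage_modes(model)
print(round(sweep.max_ratio, 3))                 # 101.21  (only at qGG ~ 1.5)

# recover an uptake rate from a simulated culture
s = gf.simulate_culture(gf.CultureSimParams(qGG_true=0.01, seed=1))
print(gf.estimate_qGG(s, (0, 4)).qGG)            # 0.009996...
```

The first number is the photon-limited growth optimum; the ratios say that
GG cleavage helps little at physiological uptake rates and that the
ATP-sparing phosphorolytic route only pays off at supply rates two orders
of magnitude above the measured range; the last line shows the glycerol
bookkeeping inverting the generator within a few percent despite noise.

The numbered drivers under `analysis/` run the full study
(`python analysis/01_build_extended_model.py` … `04_culture_recovery.py`)
and write their tables under `results/`. `ggflux --help` exposes the same
stages as a CLI (`synth`, `table5`, `sweep`, `qgg`, `ratios`, `run`).

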