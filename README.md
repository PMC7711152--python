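# deepamend

Tools for analysing *in situ* colonization experiments in deep, low-energy
aquifers: what happens to a starved subsurface microbial community when a
pulse of complex organic matter arrives, and how fast can it burn that carbon?

The package serves researchers running borehole incubation experiments
(mineral cartridges suspended in a static water column, retrieved over a
multi-incubation timetable, profiled by 16S amplicon sequencing). It has two
halves:

1. **An organic-carbon amendment model.** A bundle of natural sea sponges
   (essentially pure spongin, C = 47.44%, N = 16.15% by mass) degrades at a
   fixed depth in a narrow well. With no vertical flow, transport of the
   solubilised carbon is one-dimensional molecular diffusion from a plane
   source — the thin-film (Gaussian) solution of Fick's second law:

   C(x, t) = N / (2·√(πDt)) · exp(−x² / 4Dt)

   where N (mol C/m²) is the moles of sponge carbon per unit well
   cross-section, D is the diffusion coefficient, and x the distance from the
   release plane. Integrating C over the cartridge window and scaling by the
   surrounding water volume bounds the carbon delivered to the experiment;
   dividing by an oxidation window read off the incubation timetable and by
   the standing cell inventory (cells/ml × liters) yields a
   community-averaged per-cell oxidation rate in fmol C·cell⁻¹·day⁻¹.

2. **OTU-table processing and community statistics.** The standard
   low-biomass amplicon chain — dataset-wide singleton removal, a 0.01%
   relative-abundance threshold, removal of OTUs at ≥0.05% relative abundance
   in any negative control, relative-abundance closure and fourth-root
   transform — followed by Shannon/Chao1 alpha diversity, Bray-Curtis
   dissimilarity, non-metric multidimensional scaling with Kruskal stress-1,
   permutation ANOSIM (exhaustive when feasible), SIMPER decomposition,
   one-way ANOVA, and the two-sample variance F-test. Filters are
   sklearn-style transformers; `NMDS` is a fit estimator with `embedding_`
   and `stress_`.

A seeded Dirichlet-multinomial generator (`deepamend.synth`) emulates the
statistical structure such studies produce — low diversity, a dominant OTU,
substrate-linked effects, a perturbation bloom with recovery across five
incubations, planted control contaminants, library sizes of 5,000–47,000
reads — so the whole pipeline is testable without any sequencing download.

## Worked example

```python
from deepamend import (
    ActivityInputs, IncubationSchedule, PlaneSourceModel, SpongeAmendment,
    areal_source_strength, diffused_carbon_report, per_cell_rate,
    scenario_duration, sponge_budget,
)

c_g, n_g, c_mol = sponge_budget(SpongeAmendment())   # 5 sponges × 0.37 g
print(f"carbon {c_g:.3f} g, nitrogen {n_g:.3f} g")
# carbon 0.878 g, nitrogen 0.299 g

N = areal_source_strength(c_mol, well_diameter=0.086)
print(f"N = {N:.2f} mol C/m^2")
# N = 12.58 mol C/m^2

model = PlaneSourceModel(N=N)                        # D = 1.06e-9 m^2/s
for days in (37, 74):
    rep = diffused_carbon_report(model, days)
    print(days, f"closed-form {rep['closed_form_mol']*1e3:.3f} mmol,",
          f"coarse trapezoid {rep['trapezoid_mol']*1e3:.3f} mmol")
# 37 closed-form 0.159 mmol, coarse trapezoid 0.378 mmol
# 74 closed-form 2.118 mmol, coarse trapezoid 3.041 mmol

schedule = IncubationSchedule()
slow = scenario_duration(schedule, "midpoint3_to_midpoint5")        # 177 days
fast = scenario_duration(schedule, "deploy3_to_mid_recovery3_4")    # 120 days
low  = per_cell_rate(ActivityInputs(0.160e-3, slow, 4.1e6, 10.6))
high = per_cell_rate(ActivityInputs(3.01e-3, fast, 4.1e6, 10.6))
print(f"per-cell rate: {low:.2f} - {high:.3f} fmol C/cell/day")
# per-cell rate: 0.02 - 0.577 fmol C/cell/day
```

The bounding carbon estimates (0.160–3.01 mmol reaching the cartridge window)
and oxidation windows (177 and 120 days) bracket the community-averaged
activity between 0.02 and 0.577 fmol C per cell per day — fast for the deep
biosphere, where rates of 0.002–0.0067 fmol C/cell/day are measured by direct
methods, but the same order of magnitude at the lower bound.

On the community side:

```python
from deepamend import (apply_filter_chain, to_relative_abundance,
                       fourth_root_transform, bray_curtis_matrix, anosim, nmds)
from deepamend.synth import succession_fixture

table, meta = succession_fixture()          # 45 samples × 60 OTUs, seeded
filtered, ledger = apply_filter_chain(table)
rel = fourth_root_transform(to_relative_abundance(filtered))
dm = bray_curtis_matrix(rel)
print(nmds(dm, k=2, seed=0).stress)         # 0.1456  (< 0.2: acceptable fit)
sids = [m.sample_id for m in meta if m.incubation == 1]
res = anosim(dm.filter(sids), [m.substrate_bin for m in meta if m.incubation == 1],
             seed=1)
print(res.R, res.p)                         # 1.0 0.0036  (exhaustive, 1,680 relabelings)
```

A `deepamend` console command exposes the same stages
(`simulate`, `filter`, `stats`, `diffusion`, `activity`, `run`); see
`deepamend --help`.

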