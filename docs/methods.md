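# Methods

## The amendment model

### Carbon/nitrogen budget

Five sea sponges of mean mass 0.37 g, taken as pure spongin (mass fractions
C = 0.4744, N = 0.1615), give total carbon and nitrogen masses

- m_C = 5 × 0.37 g × 0.4744 ≈ 0.878 g,  m_N ≈ 0.299 g,

and n_C = m_C / 12.011 g·mol⁻¹ ≈ 0.0731 mol of carbon. Spread over the well
cross-section (diameter 0.086 m), the plane-source strength is
N = n_C / (π·(d/2)²) ≈ 12.58 mol C/m².

### Plane-source diffusion

With no detectable vertical flow, dispersal of the solubilised carbon is
modelled as one-dimensional molecular diffusion from an instantaneous plane
source (thin-film solution of Fick's second law):

    C(x, t) = N / (2·√(πDt)) · exp(−x²/(4Dt))     [mol/m³]

The full-line integral ∫C dx equals N exactly (mass conservation, tested to
1e-9 relative), so a one-sided window captures at most N/2. The default
diffusion coefficient is that of lactose at 55 °C, D = 1.06 × 10⁻⁹ m²/s, a
proxy for small organic solutes at the borehole temperature; it is a model
parameter, not a fitted value. Elapsed diffusion times of 37 and 74 days
bracket the release-time ambiguity (organics released at deployment of the
incubation versus only after its first half).

**Window scaling conventions.** The carbon credited to the cartridge bundle
is the line integral of C over the single-sided window x ∈ [0.25, 2.0] m
(the bundle extent below the source). Two scalings are implemented and always
labelled in output:

- `paper_volume` (default): line integral × water volume (10.6 L as m³).
  This is the procedure stated with the study design ("integrating C(x) over
  the distance and multiplying by the volume"). Dimensionally it is a
  line-integral (mol/m²) times a volume; it reproduces the published lower
  endpoint (≈160 µmol at t = 37 d) with closed-form quadrature.
- `cross_section_area`: line integral × π(d/2)², the dimensionally consistent
  alternative that yields moles directly. The two differ by the constant
  factor volume/area for any parameters (a tested invariant).

**Quadrature.** The closed form uses the error function,
∫ₐᵇ C dx = N/2·[erf(b/2√(Dt)) − erf(a/2√(Dt))]. A uniform-grid trapezoid mode
exists because the published upper endpoint is grid-sensitive: at t = 74 d
the closed form gives ≈2.12 mmol, while coarse uniform trapezoid grids with
spacing in the 0.1–0.125 m range give 2.77–3.17 mmol. The 15-interval grid
(Δx = 1.75/15 ≈ 0.117 m, the midpoint of that range and the default
`trapezoid_dx`) gives 3.04 mmol, matching the published 3.01 mmol to ~1%;
the coarse grid overweights the steep near edge of the Gaussian at x = 0.25 m.
Reports always carry both the closed-form and the configured-trapezoid
values, so the convention behind any quoted number is explicit. The fine-grid
trapezoid (Δx = 1e-4 m) agrees with the closed form to <0.1% (tested).

**Water volume.** 10.6 L is taken as stated rather than recomputed from
geometry (π·0.043²·1.75 m ≈ 10.2 L; the exact length/diameter behind the
stated figure is not recoverable).

### Oxidation windows and per-cell rates

The incubation timetable (five sequential deployments, 2014-11-03 through
2016-05-11, actual calendar dates including the 2016 leap day) defines two
oxidation scenarios:

- `midpoint3_to_midpoint5`: temporal midpoint of incubation 3 to midpoint of
  incubation 5 → 176.5 → **177 days** (slow scenario: methanogens on formate,
  recovery complete by mid-incubation 5);
- `deploy3_to_mid_recovery3_4`: incubation-3 deployment to halfway between
  the recoveries of incubations 3 and 4 → 119.5 → **120 days** (fast
  scenario: hydrogenotrophic methanogenesis marks carbon exhaustion).

Midpoints are computed at half-day resolution and rounded half-up (the
half-up choice is what makes 176.5 print as 177).

The community-averaged rate divides carbon (mol) by the window (days) and by
the standing cell inventory (4.1 × 10⁶ cells/ml × 10.6 L), expressed in
fmol C·cell⁻¹·day⁻¹: 0.160 mmol/177 d → 0.02, and 3.01 mmol/120 d → 0.577.
The rate is linear in carbon and inversely linear in duration, cell density
and volume (tested invariants).

## OTU-table processing

Filters act on membership only; surviving counts are never altered, and each
filter returns the identifiers it removed so a full removal ledger is
reproducible. Order: singletons → abundance threshold → contaminants.

- **Singletons**: dataset-wide total count exactly 1 (the standard reading,
  not per-sample).
- **Abundance threshold** (default 0.01%): an OTU is retained iff its share
  of the grand total count is ≥ the threshold (boundary kept). A
  `per_sample_max` mode retains OTUs reaching the threshold in at least one
  sample, since the dataset-wide reading is a convention choice.
- **Contaminants** (default 0.05%): an OTU is removed iff its relative
  abundance within *any single* control sample reaches the cutoff (the
  stricter max-over-controls reading; a mean-over-controls mode is
  available). Control relative abundances are computed against the full
  control composition even when the main table was already filtered.
- **Transforms**: counts are closed to per-sample relative abundances
  (zero-total samples become all-zero rows with a warning), then fourth-root
  transformed before ordination; the transform flag prevents accidental
  double application.
- **Alpha diversity**: Shannon H = −Σ pᵢ ln pᵢ in natural-log units (no base
  was mandated; nats are the information-theoretic default), and Chao1 =
  S_obs + F1²/(2F2), falling back to the bias-corrected S_obs + F1(F1−1)/2
  when no doubletons exist.

Rarefaction is deliberately not implemented: relative-abundance analysis was
the study design's stated choice and discarding reads impedes differential
abundance detection.

## Community statistics

All dissimilarity statistics operate on Bray-Curtis,
d(u,v) = Σ|uᵢ−vᵢ|/Σ(uᵢ+vᵢ), computed on fourth-root-transformed relative
abundances (transform first, then distance). Ties everywhere use mid-ranks.

- **NMDS** is SMACOF-style majorization with isotonic regression of
  configuration distances on the rank order of the input dissimilarities;
  disparities are rescaled to the configuration's sum of squared distances
  each iteration and fit is Kruskal stress-1. Stress is non-increasing
  across iterations (tested). Default 20 restarts: one from classical
  (Torgerson) metric scaling, the rest from seeded Gaussian starts;
  tolerance 1e-6 on the stress decrease, 300 iterations per restart.
  Non-convergence is reported on the result, never silent. On 4-point
  instances the best-of-restarts stress matches a dense Nelder-Mead direct
  minimisation to 1e-4.
- **ANOSIM**: R = (r̄_between − r̄_within)/(M/2) on mid-ranked distances,
  M = n(n−1)/2. When the number of distinct relabelings is ≤ 10,000 the
  permutation distribution is enumerated exactly and p is the tail
  proportion (identity included); otherwise p uses the (b+1)/(m+1)
  estimator over seeded random permutations (default 999, consistent with
  p-value floors of 0.001). Type-I error at α = 0.05 is calibrated within
  [0.03, 0.07] over 1,000 null simulations (tested).
- **SIMPER**: for each between-group sample pair, OTU i contributes
  |x_ij − x_ik| / Σ_m(x_mj + x_mk); per-OTU means over all between-group
  pairs sum exactly to the mean between-group Bray-Curtis (identity tested
  to 1e-9; values cross-checked against vegan's simper during development).
  Multi-group input dispatches all pairwise comparisons.
- **ANOVA / variance F-test**: classical mean-square ratio with an
  F-distribution p-value, and the two-sided variance-ratio test
  F = s²ₓ/s²ᵧ. Significance convention α = 0.05.

## Synthetic data

`SyntheticCommunitySpec` draws each sample from a Dirichlet-multinomial:
the baseline composition gives OTU 0 the `dominance` share (default 0.20;
the emulated system has a dominant OTU above 15% in most samples) with a
geometric rank-abundance tail (`decay`, default 0.85); substrate and
incubation effects multiply the mean and renormalise (so arbitrary effect
combinations stay valid compositions); the Dirichlet `concentration`
(default 100) sets replicate overdispersion; library sizes are uniform on
5,000–47,000 reads. All generators are bit-reproducible for a fixed seed.

Negative controls are fixed-depth (2,000 reads) samples containing only the
planted contaminant OTUs, each guaranteed ≥0.05% relative abundance; at that
depth a single read of any other OTU would already cross the contaminant
cutoff, so non-contaminants are zero rather than "trace".

The packaged succession fixture (45 samples × 60 OTUs, shipped as TSV and
regenerated bit-identically from its seed) uses three substrate bins
(background water, carbonate, silica) with dense substrate preferences on
abundant OTUs, a bloom of two heterotroph OTUs in incubation 3 that decays
through incubation 4 alongside a methanogen spike, and near-recovery by
incubation 5. Its parameters are deliberately tighter than the generic
defaults — rank-abundance decay 0.7 (a very low-diversity community) and
concentration 2,000 (duplicate cartridges cluster tightly in ordination) —
because fourth-root transformation amplifies sampling noise in the
1e-4–1e-3 abundance band, and a fixture dominated by that noise has no
faithful two-dimensional embedding. As configured, the filtered fixture
ordinates at stress ≈ 0.146 and shows significant substrate structure
(ANOSIM p < 0.01) within each unperturbed incubation.

**What the generator does not emulate:** taxon-taxon correlations, phylogeny
and taxonomy (labels are opaque), chimeras and sequencing error, depth-
dependent extraction bias, and temporal autocorrelation beyond the specified
per-incubation fold-changes. Passing tests therefore demonstrate that the
statistics recover planted structure under Dirichlet-multinomial sampling,
not that they are robust to every artefact of real amplicon data.

## Problem sizes and numerical choices

Simulation-based tests use deliberately modest sizes chosen to give stable
Monte-Carlo estimates: 1,000 null simulations (999 permutations each) for
ANOSIM calibration, 100 seeded replicates for the planted-effect power check
(6 samples per bin, exhaustive permutation distribution), 500 replicates
against the analytic power of the variance F-test, 100 random tables for the
SIMPER identity, and 500 replicates for generator mean convergence (3
standard errors). Degenerate inputs fail loudly: all-zero count vectors,
zero-variance denominators, groups of size one, non-symmetric distance
matrices and double transforms all raise validation errors naming the
violated condition.

## Known limitations

- The diffusion model ignores advection, sorption, reaction and the
  two-sided plume beyond reporting only the single-sided window; it is an
  order-of-magnitude bound, and the 74-day endpoint is quadrature-dependent
  (both values are always reported).
- Per-cell rates average over the whole standing community; they say nothing
  about the activity distribution across taxa.
- The published OTU counts of the original sequencing dataset (e.g. the
  number of OTUs surviving filtering) depend on the deposited raw reads and
  are outside the scope of the synthetic fixtures.
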