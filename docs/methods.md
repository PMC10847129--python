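# Methods

This note documents the models behind `fireshed`: what each stage assumes,
which parameters matter, what the synthetic data do and do not emulate, and
the numerical choices a user should know before trusting (or changing) the
defaults.

## Synthetic landscape generator

The generator replaces real inventory data and GIS layers with a seeded,
structurally faithful stand-in. The grid is abstract planar (no projection),
100 m cells by default so one cell is one hectare and areas in hectares equal
cell counts.

**Terrain and covariates.** Elevation is a broad ramp rising to the north
(row 0) plus spatially correlated relief (Gaussian-filtered noise), rescaled
into the configured range (default 1900–3700 m). Slope (percent) comes from a
central-difference gradient with one-sided differences at the borders; aspect
is the downslope direction, with flat cells assigned a random aspect. TRASP
is (1 − cos(aspect − 30°))/2: 0 at the coolest aspect (NNE), 1 at the hottest
(SSW). Spectral covariates stand in for tasseled-cap bands: linear transforms
of the true AGC field plus configurable noise (`spectral_noise`, default
0.3), which is what makes them informative predictors for imputation.

**Zones.** Three elevation zones crossed with six spatially blocky soil
classes give up to 18 ecoregions (`ecoregion = (zone−1)·6 + soil`); the three
elevation zones double as fire regions.

**Cover and ground truth.** Forest types follow elevation bands
(piñon-juniper low, ponderosa mid, mixed-conifer high) perturbed by a smooth
noise field; aspen occurs as rare patches in the mid/high zones (default ≤ 3%
of forested area — deliberately rare and patchy so that under-sampling of a
minor type is a reproducible phenomenon, not an accident of one seed); shrub
(resprouting and non-resprouting) and non-forest cells carry no cohorts.
Each forested cell's true state is 1–3 species–age cohorts whose total AGC is
lognormal with a type-specific median (25/65/95/55 Mg C ha⁻¹ for PJ /
ponderosa / mixed-conifer / aspen, sigmas 0.40–0.55) modulated by ±25% per
standardized elevation unit. The elevation modulation gives covariate
selection something real to find.

**Inventory designs.** The exact-coordinate network (FIA-like, default 68
plots) is drawn quasi-uniformly by picking one forested cell per block of a
√n × √n partition of the grid. The stand-exam set (CSE-like, default 111
stands) is drawn inside a biased sub-rectangle (default the northern half,
i.e. the ponderosa / mixed-conifer uplands), 90% of centroids on
ponderosa/mixed-conifer cells; each stand holds a uniform 3–31 plots measured
on forested cells within 3 cells of the centroid, but **every plot records
the stand centroid as its coordinate** — the georeferencing limitation whose
consequences the experiments quantify. The true measurement cell of each plot
is kept in a provenance record used only by recovery tests. Measurement
noise is multiplicative lognormal on cohort AGC (σ = 0.1 by default).

What the generator does *not* emulate: variable-radius (prism) plot
expansion, real spectral signatures, map projections, species-level
ecology. Passing tests therefore demonstrate the *propagation machinery* —
imputation semantics, risk statistics, ledger accounting, experiment
arithmetic — on data with the right structure, not calibrated realism for
any particular landscape.

## Imputation

Plots are classified into the generalized type holding the plurality of
their AGC (Douglas-fir, spruce-like and limber-pine-like species count as
mixed-conifer); exact ties go to the earlier category in the fixed order
(pinyon_juniper, ponderosa, mixed_conifer, aspen). Imputation is
per-type nearest-donor: covariates standardized over the type's cells,
Euclidean distance in the (optionally selected) covariate subspace, k = 1
donor, ties broken by smallest plot id — fully deterministic and independent
of plot input order. The optional covariate selection is greedy backward
elimination that drops a covariate while the leave-one-out 1-NN prediction
RMSE of plot AGC does not increase (the parsimonious-model analogue; a type
with one donor skips it). Forest types with zero donors are reported as
uncovered, never filled from other types. FIA-like and CSE-like plots are
pooled into a single donor set per type.

Because CSE plots of one stand share the centroid coordinate, they have
identical covariates; the smallest-id tie-break means at most one plot per
stand can ever be a cell's donor — which is exactly why the experiments
select one plot per stand explicitly.

A consequence worth stating precisely: donor closure guarantees that the
imputed values of a type are a subset of its donor pool, so the *attainable*
AGC span shrinks monotonically under nested donor subsets. The span or IQR
of the *imputed cell values* need not shrink monotonically — removing a
donor can reassign its cells to a surviving extreme donor. The sampling-
intensity experiment therefore draws its levels nested (each level
subsampled from the previous) and reports both the imputed distributions and
the donor-pool spans; the monotonicity claims are made about the latter.

## Forest/fire simulator

A contract-defined stand-in for a full disturbance-and-succession stack.
Per year and cell, in order:

1. **Growth** — logistic increment of cell total AGC toward an
   ecoregion-specific carrying capacity (45/95/130 Mg C ha⁻¹ by elevation
   zone, scaled ±15% across soils), rate 0.12 yr⁻¹, multiplied by the
   year's climate growth modifier; the gain is distributed over cohorts
   proportionally to their AGC and booked as photosynthesis. Cells imputed
   above capacity simply stop growing.
2. **Aging** (+1 yr) and **background mortality** — 0.8% of AGC moves to the
   surface-fuel pool (booked as mortality loss from the AGC pool); surface
   fuel decomposes at 3% yr⁻¹, slow enough that fuel accumulates for decades
   under fire exclusion.
3. **Wildfire** — per fire region, a Poisson number of ignitions (mean 1.2
   yr⁻¹); each fire grows as a contiguous random patch (4-neighbour
   stochastic fill) to a size drawn from a lognormal (median 40 cells,
   σ = 0.9). Burned-cell severity discretizes `weather × (3·fuel + AGC)`
   into classes 1–5 at thresholds (50, 90, 140, 200); the weather multiplier
   is lognormal with a per-decade median from the climate forcing. The 3×
   fuel weight encodes that surface and ladder fuels, not standing biomass,
   drive severity — it is what makes fuel treatments effective in the model,
   and severity remains monotone in both load components. Classes 4–5 kill
   80% of cohort AGC (booked as wildfire loss) and consume 90% of fuel;
   classes 1–3 consume 60% of fuel plus 3% of AGC.
4. **Management** — thin-zoned cells are thinned once in year 1: exactly 30%
   of AGC removed youngest-cohorts-first, with the crossing cohort split so
   the fraction is exact. Prescribed burns recur on the zone's return
   interval starting year 1 (years 1, 1+i, 1+2i, …), consuming 80% of
   surface fuel and 2% of AGC, and never produce severity classes 4–5.

**Ledger.** All fluxes are in Tg C. The AGC identity
`ΔAGC = photosynthesis − (wildfire + thinning + rx burn + mortality)` closes
to numerical precision on every run and is asserted in the tests; surface-
fuel consumption is tracked in its own column outside that identity, and
NECB uses only wildfire + thinning + rx-burn losses (mortality is an
internal transfer to the fuel pool, not an export).

**Climate forcings.** Five deterministic synthetic series spanning cool-wet
to hot-dry: growth modifiers trend by −10%…+10% over the horizon with a
small decadal oscillation, and fire-weather medians (0.85–1.20) step up each
decade (2–9% per decade). They provide structure — five named forcings,
decadal weather updates — not downscaled climate realism.

Default constants were chosen once, on domain grounds, to emulate a
fire-excluded dense southwestern conifer landscape: stands near carrying
capacity, decades of accumulated surface fuel, conditional high-severity
probabilities of ~0.3–0.5 in the densest untreated forest, and a management
scenario that repays its thinning carbon debit in the middle of a 50-year
horizon.

## Risk mapping and zoning

The conditional high-severity probability pools all replicate-years into one
numerator (years at severity ≥ 4) and denominator (years at severity ≥ 1)
per cell; per-replicate averaging is available behind a flag but is not the
default because the pooled ratio is the statistic as defined. Never-burned
cells are undefined and never treated. Zoning applies three predicates on
one grid: probability > 0.3, ponderosa + Douglas-fir ≥ 65% of cell AGC
(evaluated on the year-1 layer, since zoning precedes the management runs),
and slope < 30% for mechanical thinning. Douglas-fir "co-dominance" is
operationalized as ≥ 20% of the pair's carbon (configurable; it selects the
15-yr rather than 10-yr burn interval).

## Experiments and campaign

Within-stand: as many one-plot-per-stand layers as the largest stand has
plots, each pooled with the exact-coordinate network; one scheduled run per
layer × climate; the designated reference draw is compared against the mean
across draws (median, IQR, and hectares with |difference| > 20 Mg C ha⁻¹).
Sampling intensity: nested halvings subsampled proportionally to forest-type
area by largest-remainder apportionment (capped types' excess re-allocated
proportionally; every present type keeps ≥ 1 plot unless the target is
smaller than the number of types, which relaxes the floor with a warning).
Significance mapping: independent two-sample Student t-tests (Welch behind a
flag) per cell at years 10, 20, …; cells with an undefined statistic count
as not significant. The campaign pairs per-replicate seeds across the
management and no-management scenarios so treatment effects are estimated
against identical stochastic draws; a master seed spawns every per-run seed
deterministically from the run identity, so runs are order-free and
individually reproducible.

Problem sizes used by the shipped analyses and the acceptance script — a
100×100 grid (10 000 ha), 5 replicates × 2 climates × 50 years for the
paired ensembles, and the full 31 × 5 within-stand schedule — were chosen as
the smallest campaigns on which every qualitative pattern of interest is
stable across seeds.

## Known limitations

* The simulator has no establishment, dispersal, soil pools, or fire-spread
  physics; fires stop at nothing but their drawn size, and severity is a
  static function of load and weather.
* High-severity mortality is partial (80% of cohort AGC) and configurable;
  the true fraction for "majority of the overstory killed" is not
  identified by anything in the pipeline.
* Thinned material leaves the system entirely (no residue to the fuel pool),
  which flatters thinning slightly in the severity accounting.
* Imputed-value IQRs are not monotone under donor-set nesting (see the
  imputation section); only donor-pool spans are.
* The abstract coordinate system means nothing here validates against real
  geography; the pipeline's claims are about propagation structure, not
  about any particular fireshed.
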