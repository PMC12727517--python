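# Methods

This note documents the model, the numerical choices and the synthetic
study conditions behind `ecoflow`, and what the test suite does and does
not demonstrate about real data.

## Energy-flow model

The unit of analysis is the species × cell pair on a nested lattice of
1/12° analysis cells (identified with the ~8 km cell at which intactness
is mapped), 1/2° blocks (6×6 cells, the grain of range maps) and 1°
squares (12×12 cells, the grain of spatially independent natural
variability). Grid dimensions must be divisible by 12 so the three
resolutions nest exactly.

**Density.** Published density estimates arrive as a median with a 95%
interval. Assuming a log-normal, the implied log-scale sd is
`σ = (ln CI_hi − ln CI_lo) / (2·1.959964)` (the full-precision normal
quantile, not 2) and the mean is `median·exp(σ²/2)`. The mean exceeds
the median whenever the interval has width — species with very uncertain
densities (intervals span up to 2.5 orders of magnitude) contribute
disproportionately to mean flows, which is a property of the model, not
a bug. Densities are range-wide constants per species; a per-cell
density raster can override this for sensitivity analyses.

**Ranges.** Raw range grids are filtered by historical biome at the fine
(1/12°) grain, then aggregated to 1/2° blocks: a block is occupied if at
least one fine cell of compatible habitat survives, and block occupancy
is broadcast back to its analysis cells. If filtering would empty a
species' entire range, the unadjusted range is used instead.

**Energetics.** Daily energy expenditure is a field-metabolic-rate power
law `a·M^b` per taxonomic class; defaults are the classic values
(mammals 4.82·M^0.734, birds 10.5·M^0.681 kJ day⁻¹, M in grams,
residual scatter 0.15 in log10) but they are run-config values, meant to
be replaced by the equations a given study uses. Gross intake treats
diet fractions as shares of *assimilated* energy, so intake is
`Σ p_i·DEE/AE_i`. The alternative convention `DEE/Σ p_i·AE_i`
(arithmetic-mean AE) differs by at most a few percent for mixed diets
and is available via `per_food=False`; the per-food form is the default
because energy bookkeeping then closes exactly per food type.
Assimilation efficiencies resolve per species with family → order →
class precedence. The year is 365 days.

**Intactness.** The response-group × land-use table applies
categorically to strict protected areas, near-natural land and timber
plantations; for gradient classes (croplands, rangelands, settlements)
the factor interpolates linearly in land-use intensity between the
group's *near-natural* mean at intensity 0 and the tabled class mean at
intensity 1. Near-natural (not 1.0) is the anchor because it is the
lowest-intensity non-protected state in the nine-class scheme. Factors
above 1 are legitimate (disturbance winners). Cell biodiversity
intactness averages factors with equal species weight, clamped at 1 by
default (the usual intactness-index convention); clamping is a config
switch because the upstream convention is not fixed, and the unclamped
variant is needed for exact BII-equals-energetics identities in tests.

**Aggregation.** Guild totals partition species totals exactly;
functional groups double-count multi-function species by design, so
function sums exceed community totals. Stratum means are unweighted over
cells (an area-weight column can be added for real-world grids where
cell area varies with latitude); fynbos/thicket and mosaic biomes are
excluded from biome strata. Stratum-level energetic intactness is the
ratio of summed flows, not the mean of per-cell ratios: the ratio of
sums is what "percent of historical flow remaining" means for a region,
and it is defined even when individual cells have zero flow. The
per-cell ratio is what the cell-diagnostics table carries. Dominance
shares use ceil(top·n) and floor(bottom·n) ranks to stay deterministic.

## Monte Carlo design

Six variables are uncertain: mass (truncated normal, sd 15% of the mean,
floor 1 g), density (log-normal centred on the published median),
the DEE equation (log10-normal multiplier with the regression's residual
se), AE (beta, moment-matched to the tabled mean/sd), diet (symmetric
beta(2,2) over ±0.1 windows per nonzero component, renormalized) and
intactness (beta moment-matched after rescaling by an upper bound of 2,
which accommodates means above 1).

Each variable's variance is split between a natural component, redrawn
independently per (species × 1° square × simulation), and an absolute
component drawn once per (species × simulation); cells within a square
share draws. The split is implemented through a shared standard-normal
score `z = √(1−v)·z_abs + √v·z_nat` fed into each sampler's quantile
transform (a Gaussian copula). This keeps every marginal distribution
exact for any split fraction `v` — the split only controls how much of
the variance decorrelates across squares — and makes `v = 0` exactly
invariant to the number of squares (absolute and natural streams are
separate seeded generators, so the absolute draw sequence does not
depend on the spatial decomposition). The upstream analyses state the
half/half split but not its scale; the link-scale (log / beta-quantile)
split here is this package's choice, exposed as `variance_split`.

Per simulation, flows are recomputed per (species, square), averaged
over the cells of each stratum, summed over group members, and the
2.5th/97.5th percentiles over simulations (linear interpolation, for
cross-language reproducibility) give 95% CIs. Intactness CIs divide
current by historical *within* each simulation, so draws shared by both
cancel and the interval reflects genuine intactness uncertainty.
Infeasible beta moment pairs (sd² ≥ m(1−m)) are clamped to 99% of the
feasible bound and logged, never dropped. Fewer than 40 simulations
triggers a warning (the 2.5th percentile is then not estimable).

The default simulation count is 10,000. The test-suite and the
acceptance script run 1,000–4,000 simulations on worlds of ~50 species
and 9–64 squares — sizes chosen so percentile CIs are stable to ~1%
while the whole suite runs in seconds; the calibration checks below
justify the reduced counts.

## Synthetic study conditions

The generator's defaults define the conditions every test runs under:
30 bird + 20 mammal species on a 36×36-cell grid (nine 1° squares).
Body masses are log-uniform (birds 5 g–20 kg, mammals 5 g–5,000 kg);
latent true densities follow a Damuth-style density–mass law
(log10 D = intercept − 0.75·log10 M, intercept 4.0 mammals / 3.2 birds,
0.5 dex scatter); diets are sparse simplex vectors with one dominant
food (share 0.45–0.95) and up to two minors; observed density medians
perturb truth by 0.3 dex and intervals have log10 half-widths uniform on
[0.2, 2.5], the upper end matching the widest published intervals.
Biomes are drawn per 1/2° block (forest 0.35 / grassy 0.40 / arid
0.20 / excluded 0.05); land uses are drawn per cell from a nine-class
mix dominated by rangeland and near-natural land, with gradient classes
receiving uniform intensities. Intactness means decline with land-use
severity, with ~15% of group × cropland/rangeland cells drawn above 1
("winners"); strict protected areas are the intact reference (mean 1).
Ranges are random rectangles from one block up to the whole grid, so
restricted and widespread species both occur.

For interval-calibration tests the generator can instead tie each
species' median error to its own reported interval
(`noise_from_ci=True`), making the observation model exactly consistent
with the claimed uncertainty; coverage of the 95% CIs is then a genuine
check of the propagation machinery (93–97% observed over 500 replicate
worlds).

What the synthetic worlds do *not* emulate: real biogeography (gradients,
spatial autocorrelation of ranges beyond rectangles), density–habitat
covariation, trait covariances beyond the large-herbivore flag, and the
empirical response-group structure (17 bird / 76 mammal groups are
scaled down to 5 / 8). Passing tests therefore demonstrate correctness
of the computation and calibration of the uncertainty machinery under
the stated generative model, not fidelity of any continental-scale
estimate.

## Classification rules

Guild and function rules are shipped data (`src/ecoflow/data/*.csv`),
not code: a species' guild is decided by taxonomic class, dominant diet
(argmax with a 50% specialist threshold; below it the species is an
omnivore; exact ties break by a fixed food-priority order that puts
animal matter first), lifestyle and the large-herbivore flag, with
integer priorities resolving overlaps; the validator proves totality and
uniqueness over any pool. The 23 function rules (11 bird, 12 mammal,
mapping onto 10 aggregate functions) use 25% diet thresholds, lifestyle
sets, strict mass bounds (megafauna > 65 kg), the grass/leaf split at
0.5 (a 50/50 mixed feeder both grazes and browses) and a herd-size
threshold of 10 for nutrient dispersal. These defaults name the
standard functions (seed dispersal, pollination, granivory, invertivory
by lifestyle, carnivory, scavenging, grazing, browsing, nutrient
dispersal, soil disturbance, canopy/cavity engineering, megafauna
impacts); a study with its own membership criteria replaces the tables
without touching code. Size classes use strict bounds: < 3 kg small,
> 65 kg megafauna, boundary masses medium.

## Proxy diagnostics

Ordinary least squares (free intercept, unweighted cells, NaN cells
dropped and counted) relates cell biodiversity intactness to energetic
intactness and richness to total flow. Proxy quality is labelled from
the fit: *strong* if |slope−1| ≤ 0.15 and R² ≥ 0.7, *noisy* if the
slope is near 1 but R² is low, otherwise *poor*. "Non-linear slope" has
no operational definition upstream; the threshold rule is this package's
approximation, and the thresholds are config. Regressions on degenerate
predictors (e.g. a fully intact world) are flagged rather than fitted.

## Numerical and I/O choices

Rasters are Esri ASCII grids (text, north-up, row-major) with the grid
origin and cell size in the header; `repr` float formatting makes
write/read round trips exact. Diet simplex violations beyond 1e-6 are
rejected at I/O; internal generators hold 1e-9. All stochastic
operations take explicit seeds; world generation uses named substreams
per operation so adding an operation never shifts another's draws.
Oracle-equivalence tests demand 1e-9 relative agreement between the
vectorized pipeline and naive per-cell loops; observed agreement is at
machine precision (~1e-16).

## Known limitations

- No temperature- or season-dependent metabolic scaling; flows in cold
  regions would be underestimated.
- Functional efficiency (dispersal distance, pollen deposition) is not
  modelled: flow is the sole weight of a species' contribution.
- The intensity gradient is linear by assumption.
- Flat per-species densities ignore intra-specific competition and
  habitat-driven density variation (the override hook exists, but no
  variable-density data ship with the package).
- Cells are treated as equal-area; supply weights for latitude-correct
  real-world grids.
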