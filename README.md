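# ecoflow

Trophic energy flows through bird and mammal communities under land-use
change.

`ecoflow` is for macroecologists and conservation scientists who want to
translate species composition into ecosystem function. It converts a
species pool (traits, diets, lifestyles), population-density estimates
and land-use-driven intactness factors into annual trophic energy flows,
in kJ m⁻² yr⁻¹, through trophic guilds and ecosystem-function groups —
comparing a historical (pre-industrial) baseline against the current,
human-modified landscape, with Monte Carlo confidence intervals and
diagnostics that relate biodiversity intactness to energetic intactness.

## The model

For each species *s* present in a grid cell, annual energy flow per unit
area is

```
flow_s = D_s · I_s · 365 / 10⁶        [kJ m⁻² yr⁻¹]
I_s    = Σ_i p_si · DEE_s / AE_si     [kJ day⁻¹, gross intake]
DEE_s  = a · M_s^b                    [kJ day⁻¹, field metabolic rate]
```

where `D_s` is population density (ind km⁻²; the log-normal mean derived
from a published median and 95% interval, `D = median · exp(σ²/2)` with
`σ = (ln CI_hi − ln CI_lo)/(2·1.959964)`), `p_si` the diet fraction of
food type *i*, `AE_si` the assimilation efficiency (resolved with family
→ order → class precedence) and `a·M^b` a class-specific
field-metabolic-rate power law (defaults: mammals `4.82·M^0.734`, birds
`10.5·M^0.681`, M in grams).

Current flows multiply historical flows by a per-species proportional
intactness factor looked up from a response-group × land-use table
(linearly scaled with land-use intensity for gradient classes; factors
may exceed 1 for species that benefit from conversion). Guilds partition
the pool (flows sum exactly); functional groups may overlap (a species
contributes its full flow to every function it performs). *Energetic
intactness* of a group is the ratio of summed current to summed
historical flow; the *biodiversity intactness* of a cell is the
equal-weight mean of its species' factors.

Uncertainty in six variables (body mass, density, the DEE equation,
assimilation efficiency, diet composition and intactness) is propagated
by seeded Monte Carlo. Each variable's variance is split half/half
(configurable) between *natural* variability, redrawn independently in
every 1° square a species occupies, and *absolute* uncertainty about the
species mean, shared across its range — so confidence intervals shrink
with area for the natural component only. CIs are 2.5th/97.5th
percentiles of per-simulation spatial means.

A synthetic-world generator fabricates complete, statistically realistic
input bundles (log-normal densities with wide intervals, simplex diets,
nested 1/12° → 1/2° → 1° lattices) plus a brute-force oracle, so the
entire pipeline is testable without continental datasets.

## Worked example

```python
import ecoflow
from ecoflow import synthetic, classification, aggregation

spec = synthetic.WorldSpec(n_bird_species=30, n_mammal_species=20,
                           grid_rows=36, grid_cols=36, seed=42)
world = synthetic.generate_world(spec)
layer = ecoflow.compute_energy_layers(world)

guilds = classification.assign_guilds(world.species)
summary = aggregation.flow_summary(layer, guilds, world.landscape)
print(summary.query("stratum == 'all'")
             .nlargest(3, "historical_mean_flow")
             [["group", "historical_mean_flow", "current_mean_flow",
               "energetic_intactness"]].to_string(index=False))

mc = ecoflow.run_monte_carlo(world, ecoflow.MonteCarloConfig(n_sims=1000, seed=42))
row = mc.summary.query("grouping == 'total' and stratum == 'all'").iloc[0]
print(f"community intactness: {row.point_intactness:.2f} "
      f"(95% CI {row.intactness_ci_low:.2f}-{row.intactness_ci_high:.2f})")
```

prints

```
                      group  historical_mean_flow  current_mean_flow  energetic_intactness
small_terrestrial_herbivore           5344.529653        4483.007839              0.838803
large_terrestrial_herbivore            838.544418         607.261057              0.724185
         mammal_insectivore            810.344593         680.435420              0.839687
community intactness: 0.82 (95% CI 0.74-0.89)
```

Small terrestrial herbivores carry the largest mean flow in this world
(kJ m⁻² yr⁻¹, averaged over all cells); large terrestrial herbivores are
the least intact of the three (72% of historical flow remains), and the
whole community retains 82% of its historical energy flow, with the 95%
interval reflecting uncertainty in all six Monte Carlo variables.

A CLI wraps the same stages (`ecoflow simulate | flows | classify |
aggregate | uncertainty | relate | all`); every stage reads and writes
CSV tables and Esri ASCII grid rasters, so synthetic and real-data runs
share one code path.

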