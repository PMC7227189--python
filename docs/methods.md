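# Methods

This note documents the model, its parameters and defaults, what the
synthetic-data generators do and do not emulate, and the numerical and
design choices behind `standclim`.

## The projection model

The simulator is a cohort model: each plot carries a list of cohorts
(species, trees/ha, DBH, height, establishment year and establishment
climate) plus a pool of standing-dead records. Time advances in 10-year
cycles over a 100-year horizon (2016–2116 by default). Each cycle
applies, in a fixed order that configuration cannot change:

1. advance climate to the cycle-end year;
2. dClim mortality (whole-cohort, skipped when the rule is off);
3. viability-envelope mortality (density ramp);
4. stochastic disturbance events (harvest → fire → stress);
5. diameter/height growth;
6. density-dependent mortality against the effective maximum SDI;
7. planting if stocking < 40%;
8. snag decay.

The order guarantees regeneration sees post-mortality stocking, and
growth competes against the capacity implied by the current climate.
Holding the order fixed keeps runs reproducible and comparable.

### Climatic niches and viability

A species' viability at climate vector `x` is
`v(x) = ∏_k exp(-½((x_k − μ_k)/σ_k)²)` over the configured metrics
(default: mean annual temperature, °C; mean annual precipitation, mm).
Two metrics are used rather than a longer list because they are the two
quantities a forest inventory report typically characterizes sites by;
the metric set is configurable. The 0.5 threshold encodes the
observation that tree species rarely occur where their climatic
suitability drops below half. Below the threshold a cohort's per-cycle
survival is `v/0.5`, a linear ramp to zero: gradual attrition, in
deliberate contrast with the sudden die-offs of the dClim rule.

### Carrying capacity and self-thinning

Stand density is measured as summation SDI,
`Σ N·(DBH/25.4 cm)^1.605`. Each species carries a base maximum SDI; the
plot's base capacity is the basal-area-weighted mean over its cohorts
(pool mean when empty), scaled by the basal-area-weighted mean
viability, floored at 0.2 to avoid a zero-capacity singularity (the
floor is config-visible). When SDI exceeds 85% of the effective maximum
— the usual convention that mortality begins below the absolute maximum
— all cohort densities are scaled by one factor returning the stand to
exactly that ceiling; the killed density becomes snags.

### The dClim rule

Per metric, the tolerated climate change is
`τ_k = m · |γ_k| · (300 + 150) m`, the change associated with a +300 m /
−150 m elevation window (about one seed zone) under gradient `γ_k`,
times the severity multiplier `m ∈ {off, 2.0, 1.0, 0.5}`. A cohort dies
whole (to snags) when `|x_k(now) − x_k(establishment)| > τ_k` for ANY
metric. ANY-semantics is the conservative reading when several metrics
enforce the rule without a stated combination law; an ALL variant is
available (`dclim_require_all`). Replanted cohorts record the planting
climate as their new baseline and are immune until the climate moves a
further full window. With the default lapse rate (−0.0065 °C/m) the
temperature threshold at `m = 1` is 2.925 °C; halving `m` halves the
tolerance and so accelerates mortality.

Under the default warming trajectory (+2.2 °C by 2116, see below) the
rule at `m ≥ 1` never fires — 2.2 °C < 2.925 °C — so the warming-driven
decline in those cells is carried by the envelope and carrying-capacity
pathways, while dClim 0.5 (τ = 1.4625 °C) fires around year 70 and
produces markedly lower end-of-horizon carbon. Sensitivity orderings
across dClim levels therefore contain exact ties (Off = 2.0 = 1.0)
under common random numbers, which the monotonicity checks permit.

### Growth, regeneration, snags, carbon

Annual diameter increment is
`Δ = i_max · (1 − DBH/DBH_max) · max(0, 1 − 0.7·SDI/SDI_max)`, applied
for ten one-year steps per cycle with the competition ratio held at its
cycle-start value. Height follows a saturating height–diameter curve
hard-capped at a per-species maximum (caps emulate the practice of
limiting simulated heights to regionally observed maxima). Stocking is
SDI relative to the effective maximum (the operational stocking measure
of the original simulator is not reproducible; this proxy is the
package's documented choice). When stocking falls below 40%, up to four
species with viability ≥ 0.5 are planted — highest score first, ties by
code — at 1,235 trees/ha total, split equally ("total" being the
conservative reading of the planting density, consistent with a
conservative reforestation density); planting recurs in every cycle the
trigger holds. No seed source is required, so species can migrate into
plots. Snag densities decay by a retention factor (default 0.7 per
decade, a 10–20-year half-life typical of standing dead trees) with
dimensions frozen at death.

Tree carbon is `0.5 · ρ · c · f · (π/4)(DBH/100)² · h` (form factor
`f = 0.42`, crown expansion `c ≈ 1.2`, wood density `ρ`): a deliberately
simple stand-in for operational volume-library allometrics, declared
per species in `species.csv` so tests can pin it. Forest totals multiply
per-hectare plot values by plot expansion factors; composition is
expanded per-species basal area.

### Disturbance regime

Per class, the 10-year probability is exactly
`n_disturbed / n_remeasured` over unique plots, and magnitudes are kept
as the sorted observed vector (right-continuous ECDF; a class with no
events gets probability 0 and a point mass at 0). Probabilities are
held constant over the century. Sensitivity multipliers scale
probabilities only (`p' = min(1, m·p)`), never magnitudes. Events are
drawn per cycle (the natural reading of a 10-year probability), classes
independently; a plot can burn and be harvested in the same decade,
applied in the fixed order harvest → fire → stress. Mortality is
applied proportionally across cohorts because magnitude is defined at
plot level (proportion of plot basal area); uniform thinning reproduces
it exactly. Harvested trees leave the plot; fire- and stress-killed
trees become snags. Reserved plots are never harvested.

`fit()` reports Clopper–Pearson intervals for the class probabilities
(statsmodels `proportion_confint(method="beta")`).

## Randomness and reproducibility

Every draw comes from a PCG64 generator seeded by
`SeedSequence((master_seed, cell_tag, replicate, cycle, plot_index))`.
Under common random numbers (default) `cell_tag = 0`, so all factorial
cells sharing a replicate index see identical disturbance uniforms —
six per plot-cycle, always consumed in fixed order, so occurrence
indicators are nested across probability multipliers and comparisons
across cells are paired. Setting `common_random_numbers: false` derives
`cell_tag` from a CRC of the cell labels for independent runs.
Everything else in a run is deterministic, so replicates differ only
through disturbance draws, and a full factorial is bit-reproducible
from (master seed, config, inventory).

## Synthetic data: what it does and does not emulate

`make_landscape` places plots uniformly over 200–2,000 m elevation;
normals follow the regional base climate (6 °C, 1,000 mm at 1,000 m)
through a lapse-rate gradient (−0.0065 °C/m, +0.5 mm/m). Initial
cohorts (2–5 per plot) are drawn only from species viable at the plot,
at 45–80% of supported density; 34% of plots are reserved (the scale of
wilderness set-asides on a large western National Forest); every plot
represents 2,400 ha. `make_species_pool` tiles the landscape's
temperature range — extended 3.5 °C warm / 1 °C cold so warm-adapted
migrants exist — with evenly spaced Gaussian niches wide enough that
every climate on the elevational transect has a viable species;
precipitation niches are broad (temperature is the selective axis).
Growth/allometry parameters are drawn from ranges typical of
northwestern-US conifers. `make_remeasurement_data` disturbs plots
independently per class at the supplied truth, with class-specific
magnitude mixtures: harvests always remove trees (occasionally all of
them), fire kills nothing 30% of the time, stress 40% of the time and
is never stand-replacing. `make_climate_scenario` produces constant,
linear or logistic trajectories; the default warming is +2.2 °C (the
RCP6.0 ensemble mean within the quoted 1.4–3.1 °C range) and +50 mm by
2116.

Not emulated: spatial structure (fire spread, seed dispersal,
autocorrelated disturbance), inter-annual climate variability,
species-specific disturbance susceptibility, and the empirical
messiness of real inventories (measurement error, partial plots,
nonresponse). Passing tests therefore demonstrate that the machinery is
correct and that the qualitative responses (carbon rise-then-decline
under warming, composition turnover toward warm-adapted species,
sensitivity orderings) follow from the mechanisms — not that absolute
carbon magnitudes for any real forest are reproduced, which would
require the real inventory, fitted viability models and operational
allometrics.

## Numerical choices

- Conservation of basal area through disturbance and self-thinning holds
  to 1e-9 relative; tests assert it.
- Cohorts thinner than 0.01 trees/ha are culled to snags so the
  envelope's geometric decay cannot accumulate numerically dead cohorts.
- The magnitude sampler is the generalized inverse of the ECDF
  (`x_(⌈u·n⌉)`), the standard right-continuous convention; ties and
  duplicates need no special handling.
- `results.csv` floats are written as shortest round-tripping decimals
  and read back with round-trip parsing, so write→read is bit-exact and
  byte-level determinism checks are meaningful.
- Problem sizes used by the test suite and the acceptance script — a
  300-plot landscape for trajectory-shape and composition checks, a
  60-plot landscape for the 320-run factorial, 150 plots for the
  reported summaries — were chosen so the full suite completes in well
  under a minute per heavy check on a single CPU while keeping Monte
  Carlo noise far below the effect sizes examined.

## Known limitations

- Growth and allometry are simplified stand-ins; absolute carbon levels
  are indicative only.
- Disturbance probabilities are constant in time and independent of
  climate, stand structure and history.
- The dClim window is species-blind; species-specific windows are a
  known direction (genetic data suggest tolerated elevation shifts
  differ several-fold between species).
- Stocking is an SDI ratio, not an operational stocking percent.
- Composition stability under no change is a statistical property of
  the replicate mean: single replicates on small landscapes can drift a
  few tenths of a °C in niche-optimum terms through disturbance
  lottery effects.
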