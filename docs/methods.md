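# Methods

## Scope and state variables

`pipsim` is a deliberately minimal, process-based stand model built to study
biotic disturbance pathways, not a general land-surface scheme.  The stand is
a single even-aged cohort described by a continuous stem density (stems/ha)
and one representative tree with four carbon pools (kgC): leaf, fine root,
stem and nonstructural storage, plus DBH.  Stand-scale state comprises
plant-available soil water (mm, single bucket) and a soil organic matter
(SOM) pool (kgC/m²).  Default initial conditions are an even-aged 10 cm DBH
stand at 700 stems/ha with pools at their allometric capacities, storage
full, and the bucket at 120/150 mm.

Two clocks drive the model.  Photosynthesis, conductance and hydrology run on
the half-hourly forcing step; carbon allocation, turnover, disturbance
events, mortality and SOM run once per simulated day; reproduction converts
to stem density once per year.  A 4-year run is 70,080 half-hour steps and
completes in about half a second because the leaf-level coupled solution
depends only on the forcing and is precomputed for the recycled base year in
one vectorised pass.

## Meteorology generator

The generator emulates a cool, summer-dry temperate conifer site: mean annual
temperature 7.3 °C, 550 mm annual precipitation with 70 % falling in the
winter half-year, at latitude 44.45° N.  Temperature is a seasonal sinusoid
(minimum 15 January, half-amplitude 9 °C) plus a diurnal sinusoid (maximum
15:00, half-amplitude 5 °C) plus AR(1) noise (ρ = 0.95, stationary σ = 2 °C),
re-centred exactly on the target mean.  PAR is clear-sky photon flux from
solar geometry (1800 µmol m⁻² s⁻¹ at overhead sun) times a stochastic daily
clearness index reduced on rain days.  Precipitation is Bernoulli occurrence
per half-hour with gamma depths (shape 0.7, scale 1.5 mm) and a cosine
seasonal event-rate modulation; the year is rescaled exactly to the annual
target, so generated precipitation always sums to it.  Relative humidity is
anticorrelated with the temperature cycles, boosted during rain, floored at
0.2; VPD follows from Tetens saturation pressure.  CO₂ is constant at
380 ppm.  One base year is generated per seed and recycled, eliminating
interannual variability from severity sweeps.

What the generator does *not* emulate: weather fronts and multi-day storm
persistence, snow (winter precipitation enters the bucket as liquid), frozen
soil, radiation/temperature covariance beyond the rain-day clearness drop.
Tests passing under this climate show the model's responses to a plausible
seasonal water and light regime, not to any specific observed year.

## Physiology and hydrology

Assimilation uses the standard two-limitation enzyme-kinetic model with the
tobacco-derived kinetic constants (Kc₂₅ = 40.49 Pa, Ko₂₅ = 27.84 kPa,
Γ*₂₅ = 4.275 Pa) and Arrhenius temperature scaling; electron transport uses a
non-rectangular hyperbola with curvature θ = 0.7 and quantum yield 0.3.
Canopy defaults are temperate-conifer literature values: Vcmax₂₅ = 45,
Jmax₂₅ = 1.67·Vcmax₂₅ µmol m⁻² s⁻¹, g1 = 2.35 kPa^0.5, g0 = 0.01 mol m⁻² s⁻¹,
SLA = 6 m² (kgC)⁻¹, Beer extinction k = 0.5.  Leaf temperature equals air
temperature (boundary-layer conductance neglected).  The conductance model is
floored at VPD = 0.05 kPa to avoid its singularity; the coupled
assimilation–conductance–diffusion system is solved per step for Ci by damped
fixed-point iteration with a guaranteed bisection fallback (both paths solve
the same scalar root problem; residuals are below 10⁻³ µmol m⁻² s⁻¹).

The bucket (capacity 150 mm) receives precipitation and loses transpiration,
soil evaporation (wetness- and radiation-scaled, 0.03 mm per half-hour
maximum) and overflow runoff; extraction is capped at available water,
split pro-rata between transpiration and evaporation.  Water supply is
`k_supply · water · root-carbon-per-m²` with the xylem pathway removing a
fraction of the rate; when demand (canopy conductance × VPD/P converted to
depth) exceeds supply, GPP and transpiration are multiplied by
supply/demand within the same half-hour step.  The per-step (rather than
daily) coupling lets diurnal stress emerge.

## Carbon economy

Stem biomass is `0.08·DBH^2.5` kgC; leaf capacity is `0.07·DBH^1.8` kgC; root
and storage capacities equal leaf capacity.  Net leaf export
(GPP − leaf maintenance respiration) passes the phloem, where a phloem
feeder intercepts a fraction of any *positive* flow; deficits are charged to
storage untaxed.  Maintenance respiration is pool-proportional
(leaf 0.008, fine root 0.002, stem 0.0005 × 0.3 sapwood fraction, per day at
25 °C) with a shared Arrhenius response (Ea = 46.39 kJ mol⁻¹).  Baseline
turnover is 1/3 yr⁻¹ for foliage (three-year needles) and 0.3 yr⁻¹ for fine
roots; the root pathway multiplies the root rate.  Allocation follows the
priority ladder described in the README with f_min = 0.5, a 30-day
maintenance reserve, 25 % growth respiration and 10 % of the residual to
reproduction; reproduction converts to recruits at 250 kgC per established
stem, a survival-discounted cost that keeps control recruitment below
background mortality.  Recruitment adds stems carrying full per-tree pools
without debiting stand carbon — a bookkeeping asymmetry inherited from the
cohort formulation — and the imbalance is logged as a run diagnostic and
included explicitly in the carbon-closure identity rather than hidden.

Mortality risk is `m_max · exp(−c·f)` with `c = ln(m_max/m_background)`, so a
tree at full storage dies at `m_background` = 0.005 yr⁻¹ and a tree with
empty reserves at `m_max` = 4.5 yr⁻¹.  The rate is an annual hazard applied
daily to the continuous density (deaths move whole-tree carbon to SOM);
`m_max` > 1 is what allows a fully starved 700-stem stand to collapse below
1 stem/ha (≈ 6.5 e-foldings) within a few years, matching the delayed but
complete die-offs severe outbreaks produce.  Stand die-off is declared when
density crosses 1 stem/ha (config-exposed); the simulation continues and the
full tail is retained in the output tables.

SOM decomposes at 1.0 yr⁻¹ at 10 °C with Q10 = 2 — the pool is an active
litter layer whose disturbance anomalies decay over one to a few years — and
starts at 0.45 kgC/m², near input/output equilibrium for the control stand
(drift < 5 % over four years).

## Calibration note

Free parameters were fixed once, before the acceptance computations, against
three declared calibration targets:

1. **Background demography** — control annual mortality ≈ 0.5 %/yr (storage
   stays full in the control, so this pins `m_background`).
2. **Carbon-budget partition** — maintenance-plus-tissue-replacement overhead
   consumes ≈ half of annual phloem export in the control, the canonical
   NPP:GPP ≈ 0.5 partition for temperate conifers.  This partition is what
   makes woody growth the residual claimant: each unit of intercepted export
   costs roughly two units of stem growth, and growth ceases when about half
   the export stream is lost, whatever the pathway.  Within the overhead,
   foliage maintenance respiration is deliberately the largest term
   (~30–40 % of GPP): when a severe xylem disruption collapses assimilation,
   leaf respiration persists and net export turns negative, which starves
   storage faster than an equally severe phloem tax on a still-positive
   flow — the mechanism behind the distinct mortality timings of the two
   transport pathways.
3. **Hydraulic regime** — `k_supply` = 0.0011 places the growing-season
   supply rate only modestly above typical midday demand (a rate-limited,
   not storage-limited, regime).  The control then shows moderate late-summer
   stress (daily-mean stress-index minima ≈ 0.63–0.65), small fractional
   supply cuts already shave growth, successive cuts bite progressively
   harder, and complete xylem disruption starves the canopy within the first
   season.  In a storage-limited regime (larger `k_supply`) the bucket
   buffers any fractional cut — the same water is simply extracted later —
   and the xylem pathway becomes implausibly harmless at every severity.

## Numerical choices

* Ci solver tolerance 10⁻⁵ Pa (fixed point) / 60 bisection halvings
  (vectorised path); both verified against the residuals of the two
  constraint equations.
* Carbon is conserved identically: per-day allocation arithmetic is exact,
  and a whole-run ledger (GPP − respiration − heterotrophy − interception −
  reproduction + recruitment) closes to < 10⁻⁸ kgC/m² over four years.
* Water closes to < 10⁻¹⁰ mm per step by construction of the bucket update.
* Zero-severity schedules multiply state by exactly 1.0 (or add exactly 0.0),
  so a zero-severity run is bit-identical to the control — used as a test.
* Degenerate inputs: β = 1 when demand is zero; supply 0 on a dry bucket;
  respiration demand is cut to available carbon when storage empties (the
  shortfall is logged and the reduced flux recorded, preserving closure);
  turnover is capped at the pool; non-finite state aborts with a diagnostic
  dump of the offending day.
* Growth-reduction metrics use the per-tree stem increment (the biomass-pool
  view); the stand-scale (per-area) increment is used where density loss
  must count, e.g. monotonicity across the stem pathway, since killing stems
  *raises* per-tree growth through reduced light competition.
* Growth-cessation thresholds are measured on stem growth accumulated after
  disturbance onset (day 120); the ~4–5 % of four-year growth that accrues
  before onset is common to every run and would otherwise mask cessation.

## Problem sizes

All shipped experiments use 4-year runs (70,080 half-hour steps, 1,460 daily
substeps) of the 700-stems/ha cohort; a full five-pathway sweep (46 runs) is
under a minute on one core.  The test suite regenerates every input
programmatically; nothing is read from disk except round-trip fixtures the
tests themselves write.

## Known limitations

* One cohort, one species, no size structure, competition or succession;
  recruitment feeds the same cohort.
* Isohydric water response only; no hydraulic failure mortality, so
  xylem-disruption death acts purely through carbon starvation.
* No leaf energy balance, phenology, nitrogen, snow, or multi-layer soil.
* The storage-mortality closure (negative exponential, boundary-anchored) is
  a one-parameter-family assumption; observed mortality–reserve relations
  constrain its sign and monotonicity, not its exact shape.
* Evergreen phenology: defoliation recovery relies on storage-funded leaf
  rebuilding, not on a budburst schedule.
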