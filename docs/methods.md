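# Methods

`oysterfilt` estimates the water-filtration service of restored oyster reef
in a gridded estuary and ranks candidate restoration cells by marginal
gain. This note documents the model, its assumptions, the numerical
choices, and what the synthetic test estuary does and does not represent.

## Clearance-rate model

The per-oyster clearance rate (volume of water stripped of particles per
unit time) is an allometric optimum scaled by abiotic modifiers:

    CR [L h⁻¹] = 8.02 · W^0.58 · f_T(T) · f_S(S) [· f_DO(DO) · f_TSS(TSS)]

* `W` — dry tissue weight in grams, obtained from shell height `L` (mm)
  via `W = 0.0001·L^2.1`, an allometry fitted on wild northern
  Gulf-of-Mexico reefs. A 1-g oyster under optimal conditions clears
  8.02 L h⁻¹.
* `f_T(T) = exp(−0.015·(T−27)²)` — unimodal thermal response, maximal at
  27 °C and symmetric about it.
* `f_S(S) = 0.5·(1 + tanh(S − 7.5))` — filtration collapses below ~7.5 ppt
  (the half-point of the response) and saturates at marine salinities; at
  36 ppt the modifier is 1 to machine precision.
* `f_DO(DO) = 1/(1 + exp((2.11 − DO)/0.7))` — logistic hypoxia response.
  The behavioural contract is firm (clearance collapses below ~2 mg/L and
  is essentially unaffected above), while published transcriptions of the
  functional form are unreliable; the midpoint (2.11 mg/L) and scale
  (0.7 mg/L) used here satisfy that contract and are stated as package
  constants so they can be re-parameterized.
* `f_TSS` — piecewise seston response: 0.1 below 5 mg/L, 1 on 5–25 mg/L,
  0.2 on (25, 100] mg/L, 0 above 100 mg/L.

Temperature and salinity are always applied. DO and TSS are implemented
but **off by default** (`use_optional_modifiers`), because the reference
configuration of this model class drives clearance with the two fields a
hydrodynamic model supplies per cell — temperature and salinity — and
treats DO/TSS effects as screened out upstream (habitat-suitability maps
already exclude hypoxic areas). Turning the flag on applies them wherever
the environment series carries those columns.

Negative temperatures are accepted (the Gaussian is defined everywhere);
negative salinity, DO or TSS raise `ValueError`.

Reef-level ("areal") clearance sums over the size classes of a
`DemographicScenario`: Σ density·CR(W_class), in L h⁻¹ per m² of reef. The
abiotic modifiers factor out of this sum, so the areal rate is a scenario
constant times a state-dependent modifier product — the engine computes
the constant once and vectorizes the modifiers over all cells and steps.

### Demographic scenario

The packaged default (`successful_restoration_scenario()`) represents a
successfully restored reef in the northern Gulf of Mexico: spat
(16 mm, 61 m⁻²), seed (56 mm, 125 m⁻²), market (98 mm, 34 m⁻²), 220
oysters m⁻² in total. `build_demographic_scenario` reconstructs such
scenarios from survey records: sites with density strictly above the
success threshold (default 15 m⁻², the 50-per-m² / 30%-cover criterion
averaged over a reef) qualify; the scenario density is the arithmetic mean
of qualifying sites split by their mean size-class proportions. When
integer densities are requested they are truncated (floor), the convention
under which a 221 m⁻² mean with proportions 61:125:34 reproduces the
packaged table exactly. Scenarios are static: no growth, mortality or
recruitment within a run.

## Restorable-area projection

Habitat-suitability mapping gives per-cell areas of high and medium
suitability; reefs are patchy, so only a fraction of suitable area carries
reef. That fraction is fitted per class against historical reef mapping as
the least-squares proportionality constant through the origin,
`p = Σ(aᵢ·mᵢ)/Σ(aᵢ²)` over cells i with suitability area aᵢ and mapped
reef mᵢ, clamped to [0, 1]. Cells where the historical mapping recorded no
oysters must be excluded by the caller before fitting. The alternative
reading — the mean of per-cell ratios — is available as
`method="ratio-mean"`; the two differ on heterogeneous cells and
through-origin is the default because it is the least-squares estimator of
a single proportionality constant. One `p_high` and one `p_medium` are
fitted for the whole domain; the projected footprint of every cell is then
`p_high·area_high + p_medium·area_medium` (zero-footprint cells are
retained). Polygon overlay is out of scope: suitability areas arrive as
precomputed tables.

## Filtration engine

Inputs are hourly Lagrangian particle tracks (dense cell occupancy per
particle, with an `OUTSIDE` sentinel beyond the model boundary), per-cell
temperature/salinity series, and cell geometry. Step indices are 0-based;
step k covers hours [k·Δt, (k+1)·Δt) and forcing is piecewise-constant
within a step (Δt = 1 h by default).

Each particle carries a dimensionless load, initially 1. In a restored
cell the load decays by `exp(−F·Δt)` per step, where the cell's rate
constant follows from assuming the particle's load is instantly mixed
through the cell volume:

    F [h⁻¹] = areal rate [L h⁻¹ m⁻²] × reef area [m²] × 10⁻³ / volume [m³]

This dimensional closure — clearance capacity over cell volume — is the
one under-determined step of the published model class and is therefore
stated here explicitly. Removal uses the load at step start; the removed
amount is credited to the occupied cell, making per-cell attribution
order-dependent (a deliberate match to step-wise bookkeeping) while the
final load depends only on total exposure. `OUTSIDE` steps and
zero-footprint cells leave the load unchanged; re-entry is permitted.

Outputs per run: the cumulative clearance curve (fraction of initial total
load removed, per step); per-cell contribution (load removed, summed over
particles); the time-mean volumetric clearance capacity (m³ h⁻¹ = mean
areal rate × reef area; capacity-based, well-defined regardless of
particle supply) and the same per m² of reef (L h⁻¹ m⁻²); plus a
secondary realized-removal rate (contribution × cell volume / run
duration) for users who want the supply-limited reading. Conservation —
Σ contributions + Σ final loads = n_particles — holds to better than 1e−9
and is asserted in the test suite.

### Exposure-matrix reformulation

Because log-load losses are additive and F is independent of which other
cells are restored, the final load of particle p under restored set R is
`exp(−Σ_{c∈R} E[p,c])` with `E[p,c] = Σ_{steps p in c} F_c(t)·Δt`. The
engine accumulates E once; it reproduces step-by-step final loads to
1e−10 (tested) and turns every what-if restoration subset into one
matrix-vector product.

## Greedy restoration ranking

The planning objective is end-of-run total filtration
`f(R) = Σ_p (1 − exp(−Σ_{c∈R} E[p,c]))`, which is monotone and submodular
in R. Starting from an empty estuary, the greedy ranking repeatedly
restores the candidate with the largest marginal gain
`Σ_p exp(−B_p)·(1 − exp(−E[p,c]))` given accumulated exposures B. Ties
are broken by lexicographically smallest cell id (the candidate axis is
kept sorted, so argmax on equal floats lands there deterministically).
Restoring a cell restores its full projected footprint — no partial
restoration. Stopping rules: a cell count, or a cumulative-reef-area goal
(the crossing cell is included), or exhaustion of candidates. Submodularity
makes greedy marginal gains non-increasing, which the tests assert with a
1e−9 absolute slack for float accumulation.

A brute-force greedy that re-runs the full simulation for every candidate
at every step (`greedy_restoration_order_bruteforce`, CLI `--bruteforce`)
serves as the verification oracle; on fixtures with ≤5 candidates the two
agree exactly.

Rank order is *not* contribution order: under full restoration, upstream
reefs strip particles before they reach downstream cells, so a
high-capacity downstream cell can rank high while contributing little (and
vice versa). `filtration_contribution_at_full_restoration` reports the
contribution view so both can be compared.

## Synthetic estuary

`synthetic.generate_estuary` / `simulate_particles` fabricate the four
inputs a hydrodynamic + GIS toolchain would supply. The default
configuration: a 30×12 grid of 600-m cells, depths uniform on
2–8 m (volume = area × depth), salinity rising monotonically 5→36 ppt from
river to ocean end with the gradient sliding on a 12.4-h tidal cycle,
temperature 27 ± 2 °C on a diel cycle (a spring-bloom-season run, near the
thermal optimum) with fixed per-cell offsets, 2000 particles over 336
hourly steps. Suitability areas go preferentially to shallow cells, and
optional "historically mapped reef" areas are drawn around true coverage
proportions 0.177 (high) and 0.110 (medium) with lognormal noise, absent
in ~35% of suitable cells — so the proportion fit can be exercised against
known truth.

Particles hop cell-to-cell (the filtration model consumes only occupancy):
per step, an advective hop of ±1 cell along the estuary axis with
probability `tidal_amplitude·|sin(2πt/12.4)|` (seaward on ebb, riverward
on flood) plus an isotropic one-cell dispersal hop with probability
`dispersal_scale`. Moves over the river end or the banks are rejected
(the particle stays), which keeps the pure-dispersal walk doubly
stochastic — its stationary occupancy over a closed grid is uniform, a
property the tests check with a chi-square. Crossing the ocean edge sends
a particle `OUTSIDE`; it may re-enter at the ocean edge on flood steps
with fixed probability. All randomness derives from the single config
seed through `numpy` `SeedSequence` spawning (independent streams per
component, no global state), so identical configs are bit-identical.

**What the generator does not emulate:** momentum, stratification, wind,
realistic residence times, or any map-specific geography. Passing tests
demonstrate the correctness and invariances of the *model machinery* —
conservation, exposure equivalence, submodular ranking, curve shape — not
the realism of any particular estuary's filtration forecast. Applying the
package to a real system means supplying tracks and environments from a
calibrated hydrodynamic model through the `transport` formats.

## Numerical choices and degenerate inputs

* Removal per step uses `−expm1(−F·Δt)` for accuracy at small F.
* `salinity_modifier(7.5) = 0.5` exactly; `temperature_modifier(27) = 1`
  exactly.
* Empty candidate lists yield empty rankings; a scenario with all-zero
  densities or a run with no footprints yields an identically zero curve
  and unit final loads.
* Domain validation (tracks vs geometry vs environment coverage) runs
  before any computation; inconsistencies raise rather than silently
  dropping particles. Missing (particle, step) rows in a track table are a
  format error, never treated as `OUTSIDE`.
* Float comparisons in tests: conservation 1e−9, exposure equivalence
  1e−10, IO round-trips 1e−12 relative.

## Problem sizes

Default runs (2000 particles × 336 steps × 360 cells, ~170 candidates)
complete in seconds on one core; the vectorized engine scales linearly in
particles × steps and the greedy in candidates² × particles. The
conservation and oracle-equivalence test batteries use 50 and 6 seeded
estuaries respectively at reduced size (12×5 cells, 120 particles, 48
steps; 8×3 cells for the brute-force comparisons), sizes at which the
asserted properties are exact and the brute-force oracle is affordable.

## Known limitations

* No feedback of filtration on hydrodynamics, particle positions, or
  ambient seston; no seston-depletion coupling to the TSS modifier.
* No nitrogen-removal or denitrification estimation.
* The DO logistic's parameterization is a documented behavioural fit, not
  a literature-transcribed curve (see above).
* Contribution attribution is step-order-dependent by construction;
  alternative attributions (e.g. proportional to instantaneous exposure
  when cells share a step) do not arise here because a particle occupies
  exactly one cell per step.
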