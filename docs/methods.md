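# Methods

`seapatch` models the short-term exploitation of a spatially aggregated,
sedentary benthic stock — the Yucatan sea cucumber (*Isostichopus
badionotus*) fishery of 2013 is the packaged parameterisation — as three
coupled subsystems stepped daily: a depletion population model, a
technological model (density-dependent catchability and fleet dynamics), and
a fishery economics model. This note records the model equations, the
parameter choices and their rationale, the parts of the system that had to
be reconstructed, and what the synthetic data do and do not exercise.

## Stock assessment stage

The assessment stage consumes a gridded density field (individuals m⁻²),
the kind of surface produced by ordinary kriging of transect counts.

- **Patch delineation.** A patch is a maximal connected component of cells
  with density at or above a delineation threshold (default 0.05 ind m⁻²,
  the smallest isoline that closes around the aggregations in the source
  survey). Connectivity is 8-neighbour by default and configurable.
  Components that touch the raster border are returned but flagged: whether
  the bounding isoline is truly closed is a sampling-coverage judgement the
  caller must make, not something computable from the grid.
- **Density levels.** Within a patch, cells are binned into half-open
  density intervals `[threshold + k·Δ, threshold + (k+1)·Δ)` with Δ = 0.05
  ind m⁻² by default; the lower edge is inclusive so a cell exactly at the
  threshold belongs to the lowest level (deterministic, no double
  counting). Each occupied bin becomes a *density level* — the spatial unit
  of the whole simulation — with area `area_i` (cells × pixel area),
  abundance `N_i` (pixel-wise density × pixel area, summed), mean density
  `D_i = N_i / area_i`, and the catchability scale constant
  `c_i = area_i · w` in kg, where `w` is the mean individual wet weight.
  `D_i` is reported as abundance over area (the area-weighted cell mean)
  because that is the identity the published level table satisfies row by
  row.
- **Pixel geometry.** The pixel area is an explicit raster parameter, never
  inferred: survey products are sometimes published with a nominal pixel
  area different from the squared linear resolution. The packaged fixture
  bypasses rasters entirely and encodes the published level table directly,
  so the simulation results cannot drift with binning choices.
- **Biomass** is abundance × `w`, reported in tonnes.

## Population dynamics

Each level is a closed unit — no recruitment, immigration or movement
between levels, and level areas never change. Abundance follows the
depletion recursion

    N[i, t] = (N[i, t-1] − Y[i, t-1]) · exp(−m_step)

with `Y` the fished removals and `m` the instantaneous natural mortality
(0.58 yr⁻¹ for the packaged stock). The model is stepped daily with
`m_step = m / 365`, the continuous-mortality convention under which 365
daily steps compose exactly to `exp(−m)`; the source material gives `m` per
year and simulates daily without stating the conversion. Abundance and
effort are continuous (fractional animals and trips): the recursion is a
continuous-state model and rounding would distort calibration. Removals are
clamped at available abundance with a logged warning — reaching the clamp
means the catch equation over-drew a level.

## Catchability and catch

Catchability — the fraction of a level's population removed by one trip —
is density dependent:

    q(D) = (a·D + b) / (c_i · D),  clamped below at 0,  q(0) = 0

with a = 1527.7 and b = −15.3 (the table of parameters prints 15.3; the
equation text and every downstream anchor require the negative sign).
Because `c_i = area_i·w` and `B_i = N_i·w`, the per-trip wet catch is

    q · B_i = a·D + b   (kg per trip),

a rectangular hyperbola in CPUE–density space: the catch rate barely
declines while density is high (hyperstability — CPUE masks depletion) and
collapses to zero below `D = −b/a ≈ 0.010` ind m⁻². At the densest level of
the packaged fixture (D = 0.425) one trip lands 634 kg wet. Daily catch per
level is `Y = q·f·N`, capped at `N`.

## Economics

- **Ex-vessel price.** A linear inverse demand in the day's total landings:
  `price = max(0, 5486 − 10.4·L) / 1000` US$ per kg *gutted*. The quantity
  `L` is in tonnes per day of *wet* (whole) landed weight by default:
  evisceration at sea is prohibited in this fishery, so what reaches the
  buyers — and saturates the market — is whole animals, while the price is
  quoted for the gutted product. A config switch (`price_quantity_basis`)
  puts the slope on gutted tonnes instead; the wet basis reproduces the
  published end-of-season price (5.12 US$/kg) and season NPV, the gutted
  basis overshoots both.
- **Gutted conversion.** gutted = 0.6 × wet. The parameter table's label
  ("percentage loss… 60%") literally implies 0.4, but the body text states
  gutted weight *accounts for* 60% of wet weight, and only 0.6 is
  consistent with the published depletion depth. Config-overridable.
- **Trip cost.** `cost(D) = α + β/D + other` with α = 52.5 and β = 5.2
  US$/trip. The 1/D search term is the simplest two-parameter form that is
  strictly decreasing in density — at low density the time and distance
  spent searching grow — and it places the zero-profit density near
  0.05 ind m⁻², where the fishery's effort actually ceased. `other`
  (crew meals + ice) is not printed anywhere; 40 US$/trip makes the
  opening-day maximum per-trip quasi-profit land in the published ~1000 US$
  range and the break-even density at the zero-supply price equal
  0.049 ind m⁻², the density at which all levels are observed to converge.
  The exact functional forms live in an unavailable supplement; both cost
  constants are documented reconstruction choices, not printed values.
- **Quasi-profit** (variable costs only, the short-run decision signal):
  `π_i = f_i · (price · 0.6 · q_i · B_i − cost(D_i))`, possibly negative.
- **NPV.** Daily quasi-profits discounted at 10% yr⁻¹ with daily
  compounding: `Σ_t π_t / 1.1^(t/365)`.

## Fleet dynamics

Two decisions are modelled separately: *how many* trips happen (entry-exit)
and *where* they go (spatial allocation).

- **Entry-exit (Smith dynamics).** Total fleet size follows
  `F[t+1] = clamp(F[t] + φ·s[t], 0, F_max)` where the signal `s` is the
  realized mean per-trip quasi-profit minus the opportunity cost of the
  best alternative fishery (85 US$/trip). `F_max` equals the initial fleet
  (691 trips day⁻¹): the entire fleet was deployed at the opening, so entry
  is capped and φ acts mainly through exit.
- **Spatial allocation (gravity).** Tomorrow's trips are split across
  levels in proportion to an attraction weight = previous day's per-trip
  income × available biomass. The stock-size factor is the standard gravity
  form of spatially explicit effort allocation; without it the model sends
  a fifth of the 691 daily trips to the 0.8-km² densest core and strips it
  in under a week, which crowding and interference prevent in reality (and
  which the observed per-level density trajectories rule out: all levels
  converge to 0.05 ± 0.01 ind m⁻², none is driven far below).
- **Income basis.** While any level is profitable, "income" means per-trip
  quasi-profit and loss-making levels get no effort. Once *no* level covers
  its variable costs, the still-active fleet allocates by gross revenue
  while the entry-exit dynamic unwinds participation: fishers do not vanish
  the first day margins go negative — sluggish exit is the premise of the
  Smith model — and the observed endgame (fishing continuing down to
  0.04 ind m⁻², below any break-even consistent with the printed cost
  parameters) requires some fishing at negative quasi-profit. All three
  bases are config options (`allocation_basis`).
- **Opening day.** No landings have reached the market yet, so the day-one
  allocation is priced at the zero-supply intercept of the demand line.

### Calibration

The two fleet constants that the source analysis itself estimated by
fitting — initial effort F₀ and the entry-exit responsiveness φ — are
calibrated, not measured. F₀ = 691 trips day⁻¹ is kept as published. φ is
re-calibrated to 0.10 trips US$⁻¹ day⁻¹ under this package's reconstructed
price/cost sub-models, anchored to the observed date on which fishing
effort ceased (day 191; the model gives 192): φ converts a dollar signal
into trips, so its scale is only meaningful relative to the profit scale of
the sub-models it multiplies, and the reconstructed forms shift that scale.

`calibrate()` repeats this kind of fit generically: given (day, abundance)
observations it minimises the sum of squared relative abundance errors over
(F₀, φ) with a deterministic coarse grid followed by bounded trust-region
least squares in log-parameter space. With only a pre-fishing and a single
post-fishing observation the two parameters are not jointly identified (a
one-dimensional ridge of near-exact fits exists — the day-0 point is
insensitive to both); the function warns in that case. A handful of
intermediate abundances identifies both parameters to machine precision on
self-generated data.

## Scenario engine

`compare_scenarios` runs the status quo plus one run per daily trip cap;
the cap binds total daily trips before spatial allocation. Summaries are
reported over a 148-day season window — the interval between the two
surveys that bracket the fishing season (1 April–26 August) and the window
over which the published comparison table is computed (its capped-scenario
trip totals are exactly cap × 148) — while the effort-cessation day is read
from the full 240-day horizon. Per-boat income assumes the published
equal-sharing convention across 691 boats. `find_cap_for_catch_fraction`
bisects over integer caps for the smallest cap whose season catch reaches a
target fraction of the virgin wet biomass.

## Synthetic data

The kriged survey rasters are not public, so the generator produces fields
with the structure the pipeline assumes: sums of anisotropic Gaussian
kernels (peaks ≤ 0.5 ind m⁻², defaults around 0.3–0.4, matching the
observed peak range) over a background below the 0.05 threshold, plus
optional smooth noise (blurred white noise), clipped at zero and
deterministic given the seed. Gaussian kernels rather than a geostatistical
simulation: the downstream model consumes only the binned level table, so
smooth unimodal patches are sufficient, and a variogram-based simulator
would add machinery the pipeline never reads. `make_assessment_scenario`
inverts the assessment: it builds a nested-ring raster whose binned level
table reproduces a target table to within one cell per level, used for
round-trip testing. What the synthetic fields do *not* emulate: kriging
error and its smoothing artefacts, transect-sampling noise, anisotropy of
real habitat, patch fragmentation. Tests passing on them show the pipeline
arithmetic is right, not that a real survey would be unbiased.

The published per-level table (eight levels, 51.7 M individuals,
329.1 km²) and parameter set ship as plain CSV/YAML inside the package;
their row sums match the published totals to within 1–2 units in the last
printed digit (the source table rounds its rows).

## Numerical choices and degenerate inputs

- Everything is double precision and deterministic; there is no RNG
  anywhere in the simulation loop, so identical configs give bit-identical
  trajectories.
- q is clamped at 0 below the CPUE root; catch is capped at abundance;
  price is clamped at 0; fleet size at [0, F_max]. Zero-density levels
  yield −inf per-trip profit and can never attract effort.
- The cessation day is the first day of the terminal zero-trip run; brief
  price-recovery flickers (a day of no landings raises the price enough to
  tempt one more day of fishing) therefore do not count as cessation.
- Non-finite state aborts the run with the offending day in the message.
- Empty rasters, all-nodata regions and sub-threshold fields yield empty
  patch lists; nodata inside an integration region contributes zero with a
  warning.

## Known limitations

- Price, fuel-cost and entry-exit functional forms are reconstructions
  under stated anchors (the supplement defining them is unavailable); the
  simulated day-one price (2.15 US$/kg) is below the published 2.90 — no
  income-proportional allocation of 691 trips over the published level
  table can land the ~249 t/day the demand line needs for 2.90 — while the
  season-end price, NPV, catch, trips and abundance anchors are met.
- Under a 31-trip cap the model's season catch runs ~3% above the published
  1384 t: capped effort concentrates on the densest grounds, and the
  gravity exponent that would flatten it further is not separately
  identifiable from the published aggregates.
- One patch, no recruitment, no growth, no movement: the model is a
  short-horizon depletion analysis. Multi-year projection, stock-recruit
  dynamics and Allee effects are out of scope.
- Fractional trips and animals; management quantities (trip quotas, TACs,
  season windows) beyond the daily trip cap are not enforced in the core
  loop, mirroring the source analysis.
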