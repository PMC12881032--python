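# Methods

This document describes the model structure, the main parameters with
units and defaults, the numerical choices, and the known limits of the
synthetic data generators. Everything here is the package's own design;
problem sizes (64 unions, 36 archetypes, 62 runs, 2000–2050) are
choices made for tractability on a single CPU, not external givens.

## 1. Scenario drivers (`deltasim.scenario`)

All series use a 365-day no-leap calendar and run 2000–2050 (or any
requested end year).

**Climate.** Daily temperature and precipitation are drawn from a
seasonal climatology plus noise, then perturbed by a linear ramp that
is zero through 2015 and reaches its full scenario delta in 2050.
Temperature deltas are additive; precipitation deltas are
multiplicative with separate monsoon/dry-season factors. The ramp
coefficients are *window-normalised*: the scale constants
`c_T = 1/(r̄_mid − r̄_base)` and `c_P = 1/(Δr − p_annual·r̄_base)` are
chosen so that the contrast between the 2040–2055 and 2000–2015 window
means equals the configured scenario delta **exactly** (e.g. +1.8 °C
and −22% annual precipitation in the positive world). This makes the
generator targets recoverable to machine precision rather than only in
expectation.

**Sea level.** Relative sea level rises quadratically from 0 cm in
2000; the quadratic coefficient is solved so the 2040–2055 window mean
equals the scenario value exactly (38.5 cm positive, 73.5 cm negative).

**Cyclones.** Landfalls follow a homogeneous Poisson process with
per-year rate `decadal_rate / 10` times a run multiplier. Landfall
position is uniform alongshore; wind speed is uniform within band —
strong [140, 250) km/h at 0.4/decade, weak [80, 140) km/h at
4.2/decade.

**Society.** Population follows a logistic path to the world's 2050
value; the economic index grows geometrically from 1.0 in 2015 (flat
before, since the contrast windows start in 2000); embankment
(polder) coverage and maintenance follow the socio-economic variant.

**Seeding.** Every stochastic stream takes a seed derived from the
master seed by SHA-256 over a path of string labels
(`derive_seed(master, "cyclones", run_id, ...)`), truncated to
< 2^31. Base runs and their OAT perturbations share cyclone and
weather streams (common random numbers), so OAT differences are due to
the perturbed driver alone.

## 2. Experiment design (`deltasim.scenario.enumerate_runs`)

62 runs: 36 base runs — 2 worlds × 3 cyclone sequences × 3
socio-economic variants × 2 SLR levels — plus 26 OAT runs (13 per
world) that perturb one driver away from the world's *parent* run
(its natural variant and SLR level, cyclone sequence 0). OAT axes
cover climate (no change / drier monsoon), SLR level, cyclone
frequency (±50%), population, economy, polder investment, farming
technology and social protection.

## 3. Flood (`deltasim.flood`)

A reduced-form annual rule per union cell. Coastal water level = SLR +
tide amplitude (1.0 m) + cyclone surge (3.5 m strong / 1.5 m weak,
Gaussian alongshore footprint, e-folding decay inland). A poldered
cell floods only when water level exceeds its crest (degraded by poor
maintenance); unpoldered cells flood by elevation. Fluvial/pluvial
flooding scales with discharge × precipitation excess over 1800 mm,
suppressed 80% inside drained polders. Floodwater salinity decays
e-fold with distance from the coast from 25 dS/m to a 0.5 dS/m fresh
floor. Outputs are per-cell inundated fraction, mean depth and
salinity; the rule is monotone in sea level and (negatively) in
embankment crest by construction.

**Emulator.** A PLS + CCA surrogate maps forcing summaries to flood
summaries: inputs and outputs are standardised, PLS extracts
`n_components` latent directions, CCA aligns them with the outputs,
and a linear map reconstructs the outputs. `n_components = 0` is the
training-mean predictor; the upper bound is `min(p, n−1, rank(X))`
(CCA self-caps at the output dimension). Optional columns are clipped
to [0, 1] (fractions). Five-fold CV on the toy flood model reaches
R² ≈ 0.9–0.97 depending on the output set.

## 4. Soil water and salt (`deltasim.soil`)

A single-bucket daily model per cell: store `W` (mm) and salt load `S`
(dS/m·mm), so EC = S/W. Defaults: porosity 0.45, field capacity 0.30,
wilting point 0.10 (all volumetric), root-zone depth up to 1.0 m,
drainage coefficient 0.1/day, capillary rise 0.2 mm/day at 8 dS/m,
leaching efficiency 0.9, flood infiltration fraction 0.1.

Daily order of operations: rain and irrigation enter at their EC;
flood infiltration is capped by remaining pore space; capillary rise
occurs only below field capacity; actual ET is demand-limited by water
above wilting point (keeping EC bounded during dry-downs);
percolation above field capacity leaches salt at `efficiency × S ×
perc/W`; saturation overflow drains at the current concentration. The
step returns a diagnostics dict whose water and salt balances close to
1e-9 of throughput; this is asserted over hundreds of random steps in
the tests.

## 5. Crops (`deltasim.crops`)

Reference ET via Hargreaves–Samani from daily min/max temperature and
top-of-atmosphere radiation. Season yield multiplies four stress
factors: water (FAO-33 with stage-weighted ky), salinity
(Maas–Hoffman threshold–slope on season-mean root-zone EC), heat (a
trapezoid between Tmin/Topt_lo/Topt_hi/Tmax), and a flood-spell rule
(total loss when depth and duration exceed crop-specific kill
thresholds). Default crops: aman rice (4 t/ha potential, monsoon),
boro rice (5 t/ha, dry-season irrigated, salinity-exposed), and
brackish aquaculture as a conversion option. Crop parameter sets
round-trip to CSV for user-supplied alternatives. Farming-technology
drivers act as multipliers on potential yield and salt tolerance.

## 6. Households (`deltasim.households`)

36 archetypes = land class (landless 56%, smallholder 34%, large 10%)
× livelihood × polder status, each an aggregate of ~thousands of
similar households with monthly state (savings, assets, debt,
arrears). Monthly income = labour + farm share + enterprise, scaled by
the economic index and a calibrated `income_scale`. Needs are food
(1300) + non-food (900) per member per month at baseline prices.

When income misses needs + fixed costs + debt service, a coping
optimiser searches combinations of ≤3 actions at ≤5 discrete levels —
draw savings, sell assets (≤20% per month), borrow (≤3 months of
needs), cut expenditure (≤50%), send an extra labourer (≤2) — and
picks the lexicographic minimum of (extra labourers, number of
actions, unmet need, total amount mobilised, canonical order). Safety
nets (postpone repayment, friends-and-family support ≤50% of needs)
trigger only when the primary search cannot close the gap; any
residual deficit is floored at zero consumption, flagged hungry.
The optimiser is verified equal to exhaustive enumeration over the
full action lattice in the tests.

A month is *poor* when achieved expenditure falls strictly below the
upper poverty line; annual poverty counts people in households poor
for more than a threshold of months. Regional indicators
(`deltasim.indicators`): population-weighted poverty rate, weighted
Gini via the mean-absolute-difference formula (closed forms 0, 0.5
and 0.25 verified), GDP per capita, and decadal means / %-changes
versus the 2005–2014 baseline decade.

## 7. Synthetic region and calibration (`deltasim.synthregion`)

`make_region` draws 64 unions (~26 km², ~21,000 people, 38 poldered)
with correlated elevation and coast distance; `make_climatology`
provides the monsoonal daily climate normals; `make_archetypes` splits
each cell's population into the 36 archetypes with land-class
marginals held exactly (landless = 0.56) and livelihood fractions
within documented tolerances.

`calibrate_baseline` bisects a uniform `income_scale` on (0.2, 10) so
that steady-state baseline poverty hits 27% ± 2%. "Steady state"
means three warm-up years with carried household wealth before the
scored year: scoring year one with fresh savings and assets
under-counts structural poverty by a factor of ~2. The calibrated
scale is 2.190625 (6 bisection iterations, ~4 s).

## 8. Coupled simulation and analysis

`run_simulation` chains the modules for one run: annual flood state →
daily soil loop (root depth 0.5 m in rice seasons, 0.3 m otherwise;
irrigation EC rises with SLR intrusion) → seasonal crop yields →
monthly household accounting with coping → annual indicator row,
including per-group poverty for six household groups. A 62-run
ensemble at 64 unions takes ~4–5 s per run, ≈5 minutes total on one
CPU (budgeted < 10 minutes).

**Sensitivity** (`sensitivity_table`): for each driver, indicator and
world, the max–min range of the decadal % change (2041–2050 vs
2005–2014) across the runs that vary that driver, normalised by the
largest range within the (indicator, world) block; categories low
(≤ 25), moderate, high (≥ 50 on the 0–100 normalised scale).

**Attribution** (`attribution_table`): per household group and world,
the mean |Δchange(OAT) − Δchange(parent)| per driver; the climatic
share is the {climate, SLR, cyclones} total over all drivers, clipped
to [0, 1], and NaN when a group's changes are identically zero (e.g.
groups never in poverty) — reported honestly rather than imputed.

## 9. Generator realism limits

The region, climatology and households are *synthetic*: they are
statistically plausible for a low-lying deltaic coast but are not
fitted to any survey, DEM or reanalysis. Flood physics is a
reduced-form annual rule, not hydrodynamic; the soil column is a
single bucket without explicit groundwater; household archetypes are
aggregates, so within-archetype inequality is invisible to the Gini;
and cyclone damage acts only through surge flooding and crop loss, not
housing stock or mortality. Headline magnitudes therefore differ from
any particular published study; the design aims for correct *signs,
orderings and attributions*, which is what the test suite asserts.
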