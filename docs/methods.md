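# Methods

## Model structure

The village is a square grid of 0.24-ha patches (50×50 at the default
600-ha area; any area for which `village_area / patch_area` is a perfect
square is accepted). Each patch is crop or woodland and carries a standing
biomass stock, a residue stock (crop patches, post-harvest), an
enhancement flag, and a fence state (meaningful on *boundary* crop
patches — those rook-adjacent to woodland or to the map edge). The model
advances in 8-hour steps, 3 per day, 365 days per year, for the length of
the rainfall series (60 years).

Each model year is scheduled as:

1. **Annual, at the year's start** — the rainfall draw is applied; the
   drought-subsidy decision is made on realized annual rainfall below
   `low_rainfall_trigger` (largest cows first, exactly
   `round(subsidy_fraction × herd)` of them); brush fences decay with
   probability `fence_decay_prob` and are repaired from the nearest
   woodland patch able to supply `fence_cost ×` segment length — if none
   can, the fence stays broken (the denudation feedback); ploughing is
   allocated (area = min(crop area, cows × `plough_rate` × window), the
   smallest sufficient team of the heaviest resident adults works and pays
   `e_work` per step during the window; unploughed fields produce nothing).
2. **Wet season (days 1–180)** — crop growth
   `crop_growth_rate × rain × patch_area` (× `crop_boost` on enhanced
   patches) and woodland growth
   `g_wood × patch_area × (rain / reference_rainfall) × (1 − B₀/K)`
   (× `wood_boost`; `B₀` the start-of-season stock, clipped at `K`) are
   deposited evenly across the 540 wet-season steps. Fenced growing fields
   exclude cows; broken-fenced boundary fields are raided with probability
   `fence_break_prob` per step whenever a cow stands on or beside them.
3. **Harvest (day 180)** — each crop patch's standing biomass splits into
   grain (`grain_fraction`, into the newest store vintage) and residue
   left on the field.
4. **Dry season (days 181–365)** — grazing on woodland browse and crop
   residue only; uneaten residue decays at the year's end.
5. **Annual, at the year's end** — the household draws
   `household_consumption` from the grain store oldest-first; vintages
   older than `storage_years` are discarded; transported cows return;
   adults calve with probability 1 − `P_nr` (transported adults at
   `transported_repro_factor` of that); the sustainability check runs and,
   on a breach, the run halts recording the failure year (a
   `run_to_completion` flag disables the halt for debugging).

**Sustainability.** A year passes iff herd ≥ `min_cows_thresh`, harvest
plus previously stored grain ≥ the seed minimum, and end-of-year woodland
biomass ≥ the woodland minimum. The seed and woodland minima default to
landscape-scaled values — `seed_per_ha` (15 kg/ha) × crop area, and
`min_wood_frac` (5%) of total woodland carrying capacity — and can be
overridden with absolute `min_seed_thresh` / `min_wood_thresh` values.
The logic: a community that cannot buy cows, seed, or trees needs at
least that much of each on hand to continue.

## Cow energetics and demography

Maintenance, maximum intake, and the supplemental-feed ration scale
allometrically with `(m / m_mature)^0.75` for all animals (prescribing it
only for juveniles would create a discontinuity at maturation). Grazing
per visit is `min(intake_max × s, h × patch stock, satiety)` where
`h = forage_access_frac` is a linear functional response — sparse forage
is hard to gather — and satiety is the energy the animal can still use
(maintenance + work + the anabolic room up to `m_max`). Raids through
broken fences are capped by `intake_max × s` only (a break-in is
concentrated feeding) and count against that step's grazing cap.

Net step energy converts to mass by `Δm = η_a E / η_cow` (gain) or
`Δm = E / (η_c η_cow)` (loss); since `η_a η_c < 1` a gain-then-loss round
trip strictly shrinks the animal — the thermodynamic ratchet that makes
variable rainfall costly. Death occurs below `m_min` (adults) or
`juvenile_min_frac × m_birth` (juveniles); the juvenile threshold exists
because a single absolute threshold cannot serve both a 35-kg calf and a
450-kg adult. A juvenile becomes an adult the first time its mass reaches
`m_mature` (one-way). There is no sex structure, no background mortality,
and no buying or selling of animals; the cow-number dynamics are purely
births, growth, starvation, and subsidies — a deliberate simplification
that is known to understate how real farmers manage herd size.

Movement is a random walk to a rook-adjacent patch per step, refusing to
leave forage for a bare patch and excluded from fenced growing fields;
`moves_per_day` ∈ {0..3} replaces the first steps of each day with a
farmer-directed jump to the best forage patch within `search_radius`
(Chebyshev) — implemented with a two-pass monotonic-deque sliding maximum,
ties to the smallest row then column.

## Rainfall

`synthesize_historical` stands in for a 60-year governmental rainfall
record: gamma-distributed annual totals (mean 550 mm, CV 0.35 — a
semi-arid, strongly right-skewed regime) with a two-state Markov chain
whose drought state halves the gamma mean, persists with probability
`drought_run_prob` (0.5) and is entered with a quarter of that, so
multi-year droughts occur as they do in the region's records. It emulates
annual totals only — no within-year distribution, floods, or erosive
events — so passing tests say nothing about intra-seasonal extremes.

Scenarios: `constant` (the historical mean each year), `historical`
(verbatim, cycled if the run is longer than the record), `random`
(nonparametric bootstrap), `statistical` (gamma fitted by method of
moments — the family is configurable in principle but not load-bearing,
since the system responds to the amplitude of variation rather than the
generating mechanism), and the `-extreme` variants which rescale
deviations, `x' = mean + 1.5 (x − mean)`, truncated at zero, so the
*generating* SD is `sd_multiplier` (1.5) × the historical SD.

## Landscape generation and metrics

Crop placement uses seeded region growing: `n_seeds = max(1, round(n_crop
× (1 − clumpiness)))` seeds placed uniformly, then uniformly-chosen
frontier cells converted until the quota is exact. Clumpiness 0 is
independent random placement; clumpiness 1 grows one 4-connected blob;
expected Moran's I increases monotonically between. The sweep records the
*realized* configuration of every run rather than aiming at a nominal
autocorrelation target.

Metrics use rook adjacency with binary weights and no torus wrap (the
village has real edges): Moran's I and Geary's C of the binary crop
indicator (both verified against brute-force double-sum oracles to 1e-12;
a chess-board gives I = −1 exactly), total crop perimeter in km (boundary
edges count — they need fencing too — with a flag to exclude them), and
mean 4-connected crop cluster size in ha.

## Sweep and sensitivity analysis

`build_sweep` crosses scenarios × intervention levels × replicates with an
equal number of runs per cell; each run draws its crop proportion
uniformly from 1–99%, samples a clumpiness level, and (by default)
perturbs each underlying parameter by ±5% uniform (±10% for `g_wood` and
the plan-level `crop_boost`), recording the realized δ vector. Seeds
derive from `(master_seed, run_id)` through numpy's SeedSequence — three
independent integers per run (design, rainfall, simulation) — so results
are identical for any worker count and execution order; a crashed run
becomes a `status='error'` row without stopping the sweep.

The sensitivity model is a binomial GLM with logit link: treatment-coded
factors for the rainfall scenario (reference `constant`) and each
intervention (reference off), centered+scaled (`standardize`) linear terms
for the perturbation deltas, and unpenalized cubic B-spline bases
(`bs`, 6 df) for crop proportion and Moran's I. Generous-knot unpenalized
splines stand in for penalized smooths because only the smooth *shapes*
are interpreted. Estimates are reported on the logit scale and as
`100/(1+exp(−(intercept+estimate)))` percent; p-values are
Benjamini–Hochberg-adjusted (via statsmodels, oracle-checked). Perfect
separation and single-outcome tables raise a diagnostic error rather than
returning an unidentified fit. The binned graphical analysis divides a
continuous variable's observed range into equal bins per stratum and
reports within-bin sustainable proportions, flagging (not dropping) empty
bins. Behavioral validation against field data uses percent difference in
mean and sample SD (n−1), with a configurable selector for the
"historically managed" subset of runs (historical scenario, completed
runs, grain storage, daily moves, brush fences, no subsidies).

## Numerical and reproducibility choices

- All stochastic inputs are pre-drawn from one numpy Generator per run in
  a fixed order; the step kernel is written once in plain Python over
  arrays and compiled with numba when available, so the jitted and pure
  paths agree bit for bit (tested). Per-year energy, woodland, crop, and
  herd-mass ledgers are double-entry-checked to 1e-9 relative error every
  simulated year; a failure raises, never passes silently.
- Grazing conflicts resolve in slot order (deterministic); subsidy and
  plough-team selection is largest-mass-first with ties to the lower slot
  index; raid events pick the lowest-index adjacent cow.
- Growth is deposited in equal per-step increments across the wet season
  (any within-year allocation preserving annual totals is compatible with
  the model's annual contracts); the logistic factor for woodland is
  evaluated at start-of-season stock so that an empty patch at reference
  rainfall gains exactly `g_wood × patch_area`.
- Degenerate inputs: single-class grids make the autocorrelation
  statistics undefined (error, not NaN); a zero-cow village never
  harvests; `cv → 0` rainfall synthesis degenerates to the mean.

## Parameter defaults and calibration

Defaults are literature-plausible placeholders for a south-central
Zimbabwean communal area and are all configurable; the analyses the
package exists for (scenario contrasts, intervention orderings,
perturbation sensitivities) depend on relative rather than absolute
values. Key values: `g_wood` 2500 kg·ha⁻¹·yr⁻¹ at 550 mm reference
rainfall and `woodland_carrying_capacity` 1200 kg per 0.24-ha patch
(5 t/ha accessible browse+grass); `crop_growth_rate` 4 kg·ha⁻¹·mm⁻¹ with
`grain_fraction` 0.5; energy densities 9 / 12 / 14 MJ·kg⁻¹ for browse,
crop matter, and cow tissue; η_c 0.8, η_a 0.55; `e_maint` 10 MJ per step
at the 250-kg reference mass (≈ 0.5 MJ·kg⁻⁰·⁷⁵·day⁻¹); masses 35 / 180 /
250 / 450 kg for birth / viability / maturity / maximum; `P_nr` 0.45;
`intake_max` 4 kg per step; `forage_access_frac` 0.006; `fence_cost`
300 kg·km⁻¹ with 50%/yr brush decay; `plough_rate` 0.12 ha per cow-step
(≈ 0.36 ha/day); spin-up at 80% woodland capacity and 0.3 cows per
woodland hectare.

The free parameters without literature anchors (`forage_access_frac`,
the viability masses, stocking) were calibrated qualitatively, the way
the underlying model itself was built: the target patterns were cow
populations that persist under the historical regime but crash in
droughts, fences that cannot be rebuilt when the woodland is denuded, and
a base case that survives under constant rainfall while variable-rainfall
scenarios frequently fail. They were frozen once those patterns held and
are not tuned to any quantitative output.

## Problem sizes

The package's own analyses run at desk scale: tests and the shipped
examples use a 96-ha (20×20) village with area-scaled household
consumption — the full 600-ha default exhibits the same regime — and
sweeps of tens to hundreds of runs (the `agropast sweep` preset is 6
scenarios × 16 intervention combinations × 10 replicates = 960 runs).
Full-scale designs of ~500k runs are out of scope; desk-scale sweeps
reproduce the sign and rank structure of the sensitivity results, not
their magnitudes.

## Known limitations

- No livestock market, sex structure, or adaptive farmer strategies; cow
  numbers are therefore expected to validate worse against field data
  than harvest does.
- Annual rainfall totals only; no within-year phenology beyond the fixed
  wet season.
- One pooled woodland biomass stock (no woody/herbaceous split after
  pooling, no species); one pooled crop.
- The feed-subsidy cost model is `feed mass × feed_price` in abstract
  currency units; only relative spend is meaningful. Transported cows are
  energetically dormant while away (no off-village accounting).
- The sustainability thresholds are deliberately minimal; stricter
  thresholds change the shape of the crop-proportion response (a higher
  harvest floor would make the low-crop end unsustainable too).
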