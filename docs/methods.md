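# Methods

## Scope and data model

The package analyses gridded year-of-disturbance maps: a 2-D integer grid
(0 = undisturbed, otherwise the calendar year of a stand-replacing canopy
opening; one disturbance per pixel), optionally with two co-registered
spectral bands (pre-disturbance index and disturbance magnitude; NaN =
unobserved).  All coordinates are planar meters with the origin at the
upper-left raster corner and y increasing with the row index; no geographic
projection is used anywhere.  Polygons (analysis units) live in the same
frame.  Everything on disk is plain text: ESRI ASCII grids, GeoJSON, CSV.

## Patch delineation

Within each year, patches are connected components under queen contiguity
(shared edge or corner).  Patches of *consecutive* years sharing an edge
(4-adjacency; corners deliberately excluded) are then merged, because
satellite time series analysed at the peak of the vegetation period can
split one event — e.g. a fire burning across two seasons — into two annual
patches.  Details that the merge rule must fix deterministically:

* the adjacency graph is built from **pixel** years, so the operation is
  idempotent (re-running it on its own output changes nothing; with
  whole-patch years a merged patch's majority year can shift next to a
  ±2-year neighbor and spuriously reconnect);
* chains spanning more than two consecutive years merge transitively
  (connected components of the graph);
* the merged year is the pixel-majority year, ties resolved to the earlier
  year (favors first detection);
* no minimum mapping unit: single-pixel patches are kept;
* patch ids are assigned in (year, row, col of first pixel) order, so
  results are bit-reproducible.

## Predictors

Twelve features per patch, in four groups:

| group   | features | notes |
|---------|----------|-------|
| size    | `n_pixels`, `area_m2` | |
| shape   | `perimeter_m`, `shape_index`, `core_fraction` | perimeter counts pixel edges against out-of-patch or out-of-raster cells (inner holes included); `shape_index = P/(4√A) ≥ 1`, equality for a full square; core pixels have all 4 neighbors in-patch |
| spectral| `pre_mean`, `pre_sd`, `mag_mean`, `mag_sd` | NaN pixels excluded; a patch with no valid pixels gets the global mean and a missingness flag (flag kept as metadata, not a model feature) |
| context | `ctx_count`, `ctx_area_m2`, `ctx_nn_dist_m` | other patches with centroid within R = 2000 m and |Δyear| ≤ T = 1; no neighbor ⇒ (0, 0, R) |

R and T are configurable; the defaults are package choices, set at the
scale at which storm/beetle clusters express in the synthetic landscapes.

Reference points link to the patch containing their pixel if the patch year
is within ±1 year of the point year (the maps' stated temporal inaccuracy).
Multiple points per patch collapse to one label; conflicting agents resolve
by point-count majority, ties by the fixed priority wind > fire >
bark_beetle.  Points on undisturbed pixels are dropped and counted, never
fatal.  The training table is balanced: all unplanned-labeled patches plus
an equal-size uniform background sample of unlabeled patches treated as
planned (the background therefore contains a small fraction of unlabeled
unplanned patches — deliberate, it mirrors how such reference databases are
built when planned openings are not explicitly labeled).

## Attribution model and its evaluation

A random forest (500 trees, bootstrap per tree, √p candidate features per
split, seeded; configuration, not doctrine) maps feature vectors to
`p(unplanned)`.  Because disturbance data are strongly spatially
autocorrelated, ordinary cross-validation overstates skill; evaluation uses
spatial block CV: patch centroids are binned into a pointy-top hexagonal
tessellation of cell area 0.5 km² (circumradius r from A = (3√3/2)r², i.e.
r ≈ 438.7 m), every occupied hexagon is assigned uniformly at random
(seeded) to one of k = 10 folds, and each fold is predicted by a model that
never saw its hexagons.  AUC is computed from the pooled out-of-fold
probabilities by the rank (Mann–Whitney) statistic with midranks for ties —
identical to the trapezoidal ROC integral, which the test suite asserts to
1e-9.

The binary cutoff maximizes the F1-score of the unplanned class over the
grid {0.01, …, 0.99} on the pooled out-of-fold predictions (smallest cutoff
among ties).  0.39 ships as the documented production default for use
without training data.

## Regime-change analysis

Patch areas are allocated to analysis units by pixel-center containment
(patches straddling a boundary split in proportion to pixel counts) and
summed per unit, year and cause, with explicit zeros.  The late 20th
century (1986–2000) is contrasted with the early 21st (2001–2020).  The
year 2000 belongs to the early period so that a December-1999 storm
recorded in 2000 stays with its period; the split year is a parameter for
sensitivity analysis.  A period contrast is used instead of a linear trend
because annual series are dominated by single large events.

Differences in annual areas are tested with the two-sample Van der Waerden
normal-scores test: pooled values are ranked (midranks for ties), scores
are a_i = Φ⁻¹(R_i/(N+1)), the statistic is the score sum T of the second
sample, and

* asymptotic mode: Z = (T − n₂ā)/√(n₁n₂/(N(N−1)) · Σ(a_i−ā)²), two-sided
  normal p-value.  Null calibration is verified by simulation (rejection
  rate 0.0459 at α = 0.05, n₁ = 15, n₂ = 20, 10 000 replicates).
* permutation mode: p is the share of group reassignments with
  |T − E[T]| ≥ observed, enumerated exhaustively when C(N, n₂) ≤ 10⁵.
* all pooled values identical ⇒ p = 1 with a warning.

Tests are two-sided; per-unit p-values are mapped without multiple-testing
correction (a deliberate faithful-reproduction choice — unit-level
significance maps are conventionally shown uncorrected).

Each unit is classed by the signs of its two percent changes into four
linked-change quadrants; a unit with an exactly-zero change in either cause
goes to a fifth `no_change` bucket, and a unit with zero period-1 area in a
cause is excluded from percent-change maps (its areas still count in
totals).  Quadrant shares are reported over units and over forest area
(weighted by unit `forest_area_km2`); in the significant-only variant the
denominator stays the full included set, so the quadrant rows and the
`not_significant` row sum to 100%.

## Salvage-logging validation

Management responds to most wind/beetle/fire damage with salvage logging,
so national fractions of fellings from salvage provide an independent check
on map-derived unplanned shares.  Shares are aggregated per country and
year (units → countries), zero-disturbance country-years excluded, and
compared by Pearson correlation: pooled over all matched country-years, and
within each year across countries (years with ≥ 3 countries), summarized by
the unweighted mean.  Area-based shares are compared to volume-based
fractions without conversion, so r = 1 is not expected even with perfect
attribution.

## Synthetic-data generator

The generator produces the joint structure the analysis assumes, on a
planar grid (default 500×500 pixels at 30 m, 1986–2020, 16 square analysis
units, countries = 4 consecutive units):

* **planned**: compact blob patches, lognormal sizes (median 9 px, log-sd
  0.8, clipped to 1–60 px — harvest size distributions are right-skewed),
  placed uniformly subject to a green-up adjacency constraint (no new
  harvest queen-adjacent to a same- or previous-year harvest, as in
  European forest-planning practice).  The annual rate ramps linearly so
  that the period-2/period-1 mean ratio equals `planned_trend` (default
  1.24).
* **wind**: irregular patches, log-uniform 100–600 px, scattered
  (σ = 1500 m) around 1–3 storm centers; concentrated in pulse years
  (defaults 1990, 2000 — the strongest, a Lothar-like event —, 2005, 2007,
  2018 with relative intensities 1, 3, 1, 1.5, 2 and pulse weight
  1 + 8·intensity).
* **bark beetle**: mid-size patches (10–150 px) seeded with probability
  ∝ exp(−d/δ), d = distance to previous-year wind, δ = 1500 m — the
  wind-beetle amplification without asserting a mechanism.
* **fire**: large patches (50–800 px) confined to a subregion (default the
  lower-right quadrant-and-a-bit).
* **spectral bands**: pixel value = patch effect + pixel noise.  Patch
  effects are N(μ_class, sd_class) with sd 0.25 for planned (clearcut
  magnitudes are narrowly distributed) and 0.5 for unplanned (agent
  severities vary); pixel noise sd 0.5.  The class mean difference equals
  `spectral_separation` (default 2.0) times the average marginal class sd
  for the magnitude band — i.e. a Cohen's d between the class pixel
  distributions — and half that for the pre-disturbance band.
* **budgets**: annual pixel budgets per cause are fixed by largest-remainder
  rounding so the realized unplanned share (default 0.178) and both period
  ratios (+24%/+30%) are hit essentially exactly by construction; events
  are grown until the year's budget is consumed (the last event is
  truncated).  Events never overlap; an unplaceable event raises an error
  naming the agent and year.
* **reference points**: total = round(1.36 × number of unplanned events)
  (the points-per-patch ratio of the reference database being emulated),
  split across agents proportional to 6986 : 727 : 1543
  (wind : beetle : fire).  Each sampled event gets at least one interior
  point; surplus points land in random events, so several points can share
  a patch.  With this mix many beetle events stay unlabeled and contaminate
  the background sample — intentionally realistic.
* **salvage table**: country-year salvage fraction = true unplanned share
  + N(0, `noise_sd`), truncated to [0, 1], default coverage 2004–2020.

`planned_rate` defaults to 0.0042/yr, chosen so that ≈ 20% of forest pixels
are disturbed over the 35 years — the magnitude of the European record the
study system mirrors.  Identical config + seed gives bit-identical outputs.

What the generator does **not** emulate: radiative-transfer or phenology
realism, Landsat time-series noise, topography, drought predisposition,
spatially varying forest cover, multi-year beetle outbreaks beyond the
one-year coupling, and real administrative geometries.  Passing recovery
tests therefore demonstrate the correctness and statistical behavior of the
pipeline under the assumed structure, not map accuracy on real data.

## Problem sizes used in tests

Module tests run on 150–200 px landscapes; the end-to-end recovery suite
and the acceptance script use the full default conditions (500×500 px, 35
years, ~3 600 patches, ~200 training rows) with the fixed seed set {0, 1, 2};
the null-calibration study uses 10 000 replicates.

## Known limitations

* **Desk-scale reference databases destabilize the cutoff.**  At default
  conditions the landscape yields ~130 labeled unplanned events — two
  orders of magnitude fewer than the continental database the design
  emulates.  A balanced table of ~200 rows leaves the hard tail of the
  ~3 500-patch planned population under-represented, so the F1-optimal
  cutoff varies widely across seeds and the classifier passes 2–5% of
  planned patches — preferentially storm-adjacent ones — into the unplanned
  class.  Oracle experiments included in the development diagnostics show
  the feature space itself is sufficient (a forest trained on the full
  labeled population recovers the generating +24%/+30% almost exactly, as
  does perfect patch-majority labeling), so this is a sample-size effect of
  the reference design, not of the features or the delineation.
* **Consequence for change estimates.**  False-positive area grows with
  storm activity and planned density, i.e. disproportionately in the second
  period; the acceptance suite documents that the estimated unplanned
  change then overshoots the generating +30% (and per-unit quadrant
  assignments degrade) even when AUC ≥ 0.98 and area-weighted accuracy
  ≥ 92%.  High headline skill metrics do not guarantee unbiased
  regime-change estimates — an instructive property of the design that the
  test suite leaves visible rather than papering over.
* Patch-count context (`ctx_count`) carries no class signal at desk extent
  (dispersed planned patches dominate every neighborhood count); the
  area-weighted context does.
* The Van der Waerden asymptotic p is slightly conservative at very small n;
  permutation mode is exact and preferred below n ≈ 10 per group.
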