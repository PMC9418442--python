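# Methods

This note documents the models and procedures `beelife` implements, the
parameters that matter, the numerical conventions, and what the synthetic
colony does and does not emulate.

## Coordinate frame and comb maps

All positions live in a single 2-D hive plane in centimetres, origin at the
top-left, y downward, with the nest exit at the lower-right corner
`(width, height)`.  The front and back comb sides share this plane:
side-blind pooling is adequate for the occupancy, dispersion and distance
statistics computed here, and side information is used only to invalidate
speed pairs that span a side switch.  Exit distance is Euclidean in this
plane; a walking-path metric around the comb edge could be substituted in
`core_model.exit_distance` if the physical hive demanded it.

Comb content is a raster of labels (honey, pollen, brood_young,
brood_capped, empty, wood, gallery, dancefloor) on a square grid, default
2 cm, one raster per measurement date.  Grid cells are half-open
`[x0, x0+g) × [y0, y0+g)`, which makes boundary labelling deterministic.
Young and capped brood merge to a single "brood" category everywhere
downstream.  The dance floor is defined once for the whole observation
period and is required to be identical across all maps in a series.

Content on a day between measurements is a linear interpolation in time:
with bracketing maps A (earlier) and B (later), a query date receives
weights `w_A = (t_B − t) / (t_B − t_A)` and `w_B = 1 − w_A`, so the nearer
measurement weighs more.  Per-bee substrate usage is computed against each
bracketing map separately and combined with the same weights
(`f_i = w_A S_iA + w_B S_iB`), as is the nest-level content fraction of
each substrate (fraction of comb cells, wood and gallery excluded).
Queries outside the measured range clamp to the nearest map with weight
(1, 0); a single-map series always returns (1, 0).

## The 12 behavioral metrics

Only detections with confidence strictly above 0.8 are used.  Detections
are first reduced to 1-hour records, keeping hours with at least 10
qualifying detections; time observed in an hour is
`n_detections / frame_rate`.

* **Substrate fractions** (honey, brood, dance floor): fraction of the
  hour's detections on each substrate, map-interpolated as above.
* **Exit distance**: median distance to the exit over the hour.
* **Median speed**: median of displacement/Δt over consecutive same-side
  detection pairs with Δt at most `max_speed_gap_s`.  The reference gate is
  1 s (the native rule at 3 Hz); at reduced frame rates the default becomes
  `max(1, 1.5/frame_rate)` so consecutive frames still qualify — the gate
  is a parameter, never a hard-coded constant.  Even-length medians use the
  mean-of-middle-two convention.
* **Circadian coefficient**: `C = Σ_h s_h r(h) / Σ_h s_h` over the day's
  hourly median speeds, with rhythm `r(h) = cos(2π(h − m)/24)`, hour-bin
  centres `h + 0.5`, and `m = 13.5` (local solar noon ≈ 13:30).  C is
  bounded in [−1, 1]; the extremes occur only when a bee is observed solely
  at the rhythm's peak or trough, and a constant speed profile over a full
  day gives exactly 0.  Hours without a valid speed contribute nothing to
  either sum.  A day with no speed data has no coefficient; such rows are
  removed by the day-matrix filters rather than imputed.
* **Outside trips and time outside.**  A barcode is often undetected even
  inside the hive, so departures are inferred from non-detection *plus*
  prior proximity to the exit.  Per 1-minute bin compute time observed and
  median exit distance; an exit occurs at bin t when observed time
  < `t_obs = 2 s` and the previous bin's median exit distance
  < `d_exit = 18.75 cm`; re-entry is the first later bin with observed time
  ≥ `t_obs`.  Trips do not span midnight: a trip still open at day end
  closes at midnight and its elapsed span counts as time outside, keeping
  per-day bookkeeping within 24 h.  Results are sensitive to `d_exit`;
  both thresholds are exposed parameters.
* **Dance-floor visits**: transitions from another substrate onto the
  dance floor across consecutive detections; a bee already on the dance
  floor at its first detection has not "entered".  Entries are credited to
  the hour of the entering detection and summed over kept hours.
* **Dispersion**: RMS distance from the day's detection centroid, pooled
  over kept hours (accumulated as running sums, so hourly records compose
  exactly).
* **Fraction of nest visited**: visited 2 cm cells divided by all nest
  cells, pooled over kept hours.

Per-day aggregation: time observed, trips and dance-floor visits are sums;
substrate fractions, exit distance and speed are averages weighted by time
observed; dispersion, nest fraction, circadian coefficient and the trip
quantities are whole-day computations as described.

## Day matrix, PCA, embedding, clustering

A behavioral day enters the matrix only if the bee was alive that day
(registry death date is the cutoff), had **more than 1,000 detections**
over the day, and the day is not the bee's introduction day.  Honey and
brood usage have the interpolated nest content fraction subtracted before
normalization, so a bee sitting on honey in a honey-rich nest is not
scored as honey-seeking; the dance floor needs no correction because its
area is fixed.  Columns are z-scored with the *population* standard
deviation, making total variance exactly the number of metrics (12).  A
metric with zero variance is left at zero with a warning rather than
dividing by zero.

PCA is computed by SVD of the z-scored matrix.  Components are orthonormal
and deterministically signed (largest-magnitude loading positive);
variance fractions are the normalized squared singular values.

The 2-D embedding is t-SNE (perplexity 30, 1000 iterations) initialized
from the first two PCA projections (rescaled to the conventional small
magnitude), so its global structure aligns with the leading components
while local structure reflects higher-order ones.  Fitting requires at
least 3× perplexity rows.  Out-of-sample points — needed to draw average
lifetime trajectories on the day embedding — are placed by inverse-distance
weighting over their 30 nearest training rows in PCA space; the placement
is a convex combination of those neighbours' coordinates, and an exact
duplicate of a training row maps onto that row's coordinates.

Ward clustering uses the standard Lance–Williams linkage
(`scipy.cluster.hierarchy`).  The within-cluster variance fraction of a
partition, and of any grouping {G} (per age, cohort, age × cohort, or any
row labelling), is the residual variance after subtracting conditional
group means, normalized by the squared matrix norm — computed identically
for cluster partitions and ad-hoc groupings so the two are directly
comparable, and available per metric (normalizing by that column's squared
norm) or over all metrics.  Explained variance is reported as
`100·(1 − W)` percent.  Refining a grouping can only decrease W.  The
default 5-cluster cut is a descriptive device: on data with continuous
variation (including these simulations) there is no "true" cluster count.

## Bee-life tensor and lifetime analysis

Bees qualify for the lifetime analysis with ≥ `Dmin = 10` rows in the day
matrix and (optionally) a birth date inside the observation period.
Life-day `t = 0` is the first full day after introduction; ages beyond
`Amax = 25` are truncated, giving a flattened width of `25 × 12 = 300`
columns.  Cells where a bee was dead or unobserved are filled with the
per-age mean over observed bees, `h[t, j]`; zero-filling would be wrong
because the age-conditional mean is far from zero even though each
day-matrix column averages to zero overall.  Filling preserves the
per-age column means exactly.  Bees alive at observation end are treated
the same as dead bees for filling (the mask drives everything).

Life-PCA runs on the column-centred flattened tensor.  Sign conventions
fix the two leading axes to interpretable directions: component 1 is
oriented so higher overall movement activity (mean loading on dispersion
and fraction of nest visited) is positive; component 2 so an earlier
transition to dance-floor use and time outside is positive.  Life
clustering is Ward on the same flattened tensor; per-cluster lifespan
distributions use registry death dates (true days lived), not tensor
occupancy, and are uncensored in the synthetic setting.  Per-cluster
average trajectories take the mean metric vector of *observed* bees at
each age and map it through the day embedding's transform; lifetime
summaries likewise average observed days only.

## The colony simulator

The simulator generates what the analysis consumes — detections, comb
maps, registry — with known per-bee parameters, so recovery can be tested
end to end.  Defaults mirror the study conditions: a 50-day observation
period; a cohort introduced and the comb re-measured every 5 days (the
field cadence is every 4–6 days); 3 Hz frames over a 49 × 74.2 cm hive
plane with the exit at the lower-right corner.

* **Archetypes.**  Activity ~ lognormal(0, 0.35) (median 1); transition
  age ~ Normal(12, 4) clipped to [3, 24] days; lifespan =
  `4 + 1.8 × transition_age + Normal(0, 4)` clipped to [6, 60] days, which
  plants the early-transition ⇒ short-life coupling; per-bee circadian
  amplitude κ ~ U(0.15, 0.5); trip rate ~ 3/day × lognormal(0, 0.25).
* **Movement.**  An Ornstein–Uhlenbeck walk (relaxation time 600 s,
  stationary SD 7 cm × activity) toward a phase-dependent anchor: brood
  centre before half the transition age, a nest-interior point until the
  transition age, then the dance floor.  Innovation scale is multiplied by
  `1 + κ·cos(2π(h − 13.5)/24)`, planting a positive circadian sign.
  Positions reflect at the walls.
* **Trips.**  Transitioned bees draw Poisson(trip rate) trips per day,
  starting uniformly between 08:00 and 18:00, lognormal durations (median
  35 min, clipped 10–120 min, non-overlapping).  For the 2 min before a
  departure the bee is pinned within ~5 cm of the exit (so the
  distance gate in trip detection is honestly satisfiable), then emits no
  detections until re-entry.
* **Detection.**  Each frame a present bee is detected with probability
  0.85, and 10% of detections draw a confidence below the 0.8 threshold
  (the real system's dropout and confidence distributions are not
  published; these are free parameters, not estimates).  Comb sides follow
  a slow telegraph process.  Ground truth records per-day occupancy from
  the full pre-dropout trajectory, the trip log, and the archetype table.
  Output is bit-identical for identical (config, seed), independent of
  whether days are streamed or simulated in one call.

What the simulator does *not* emulate: waggle-dance kinematics, social
interactions, crowding-dependent detection failure, weather- or
forage-driven day effects, queen and drone behavior, and realistic
path microstructure.  Passing recovery tests therefore demonstrates that
the pipeline's machinery is correct and sensitive to planted individual
differences of realistic magnitude — not that real colonies obey this
generative model.

## Problem sizes and determinism

Analysis-scale runs use a 20-second simulation step (`frame_rate = 0.05`)
with per-metric formulas taking the frame rate as a parameter; this keeps
a 450-bee, 50-day colony (≈ 9,000 bee-days, ≈ 30 M simulated frames)
to about a minute of compute while every per-day count threshold (10
detections/hour, 1,000/day) still operates in its intended regime.  The
planted-factor recovery study uses that configuration: ~340 bees survive
the 10-day filter, and Spearman correlations between planted factors and
the life-PCA projections exceed 0.9 in magnitude, comfortably above the
0.6 acceptance bar.  Day-by-day streaming bounds memory by one day of
detections.  All stochastic stages (simulation, t-SNE) are seeded;
repeated runs are bit-identical.

## Known limitations

* Euclidean exit distance ignores any extra walking path imposed by a real
  exit tunnel.
* Trip detection at very low frame rates produces occasional false exits
  for bees loitering near the exit (a minute with no detections by
  chance); this is inherent to the non-detection heuristic and shrinks as
  frame rate or detection probability rises.
* The dance-floor region must be supplied as part of the comb maps; the
  package does not infer it from dance observations.
* Comb maps are raster-only; polygon sources must be rasterized upstream.
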