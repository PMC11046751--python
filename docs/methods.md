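# Methods

This note documents the models, the synthetic study design, the numerical
choices, and the known limits of what the test suite demonstrates.

## The synthetic study and what it does (not) emulate

The generator builds a planar-meter world (an arbitrary local projection; at
a few tens of kilometres across, planar error is negligible, so no geodesy
appears anywhere). Timestamps are UTC-naive; the monitoring year is anchored
at 13 February, the earliest capture date in the emulated design.

**Within-range movement** is a discrete Ornstein–Uhlenbeck (OU) process
around the active range center: per coordinate,
`x_{k+1} = c + a (x_k - c) + ε_k`, `a = exp(-Δt/τ)`,
`ε_k ~ N(0, s²(1-a²))`, with stationary SD `s = range_sd` and timescale
`τ = ou_timescale`. OU was chosen because it yields a stationary home range
and an exact transition density against which the simulator is tested
(Kolmogorov–Smirnov on standardized increments). Tracks start exactly at the
center, so net squared displacement plateaus at `2·range_sd²` for residents.

**Defaults** (per species; meters, hours):

| parameter | deer | moose | wolf | why |
|---|---|---|---|---|
| range_sd | 600 | 1000 | 2000 | home ranges of a few km² for ungulates, tens to ~100 km² territories for wolves |
| ou_timescale | 6 h | 8 h | 2 h | ungulates revisit patches over several hours; wolves traverse their territory daily, so positions decorrelate fast |
| transit_speed | 350 m/h | 300 m/h | — | multi-day corridor transits (~17 km in ~2 days) |
| fix_interval | 4 h | 4 h | 4 h | the collar schedule the cleaning rules assume |
| dropout_prob | 0.02 | 0.02 | 0.02 | occasional missed fixes; exercises the 9-h max-lag skip |
| gps_error_sd | 15 m | 15 m | 15 m | typical collar accuracy |

**Migration timing.** Spring departures are synchronous
(N(day 56, 2 d) ≈ 10 April), fall departures asynchronous
(N(day 255, 12 d) ≈ late October), in study days since 13 February.
Migratory deer share one corridor polyline between a clustered winter
complex and dispersed summer ranges (median winter–summer displacement
≈ 17 km); migratory moose displace 3–8 km with no shared corridor, which is
why the analysis finds a deer corridor but no moose corridor. Nomads occupy
4–5 ranges in sequence, ~85 days apart, with consecutive steps of 7–11
range-SD and all pairs ≥ 6 range-SD apart — "distinct home ranges" are
generated to be genuinely distinct at the clustering scale.

**Wolves** are territorial residents. Seasonal within-territory
redistribution is modeled as a season-dependent offset of the OU center
toward the nearest corridor waypoint (default 2000 m in fall, 500 m in
summer, none in winter/spring). This encodes the prey-switching scenario
the overlap analysis is designed to detect. Note an important consequence:
the offset is a literal mean shift, so the white-noise range-shift test —
correctly — flags such wolves at collar sample sizes. Real predators can
redistribute intensity with a much smaller mean displacement; the
"stationary territorial" regime (no offsets) is the right generator setting
for demonstrating the no-shift behavior, and is what the corresponding test
uses.

**Not emulated:** habitat or land cover, step selection, predator–prey
encounters or kills, collar-error states beyond i.i.d. GPS noise and
Bernoulli dropouts. Mortality either truncates a track or pins it at the
death site with small jitter. Passing tests therefore show the *estimators
and pipeline* behave correctly under the stated movement model — not that
the model captures every feature of field data (e.g., real tracks have
autocorrelated gaps, habitat-driven anisotropy, and partial migrants).

## Cleaning rules

Defaults: 4-h target grid (snap tolerance 2 h, nearest fix per slot, no fix
used twice); speed cap 10.8 km/h with the later fix of an offending pair
removed (the earlier one is corroborated by prior history), iterated to a
fixpoint; spike censoring requires *both* first passage time ≤ 1 h (radius
300 m) and a turning angle in the 179–181° band, mapped to [179°, 180°] in
the relative-angle convention (180° = exact reversal). The FPT radius and
unit are not uniquely determined by the field protocol this mirrors; both
are exposed in `QCConfig`. Mortality censoring removes a terminal run that
spans ≥ 48 h with every fix within 50 m of the run centroid — a *net*
confinement criterion, because GPS jitter at a carcass accumulates unbounded
path length; interior rests are kept.

## Classification choices

Segmentation assigns fixes online to running-mean centers
(assignment radius = min_separation/2), then merges substantial centers
(≥ 18 fixes) within `min_separation` by weighted **centroid linkage** —
single linkage was rejected because transit and satellite micro-centers
chain genuinely distinct ranges together. `min_separation` scales with the
species' range size (4 × range_sd: 2.5 km deer, 4 km moose, 8 km wolves).
A home range requires ≥ 30 days of dwell, mirroring the stopover cutoff;
runs shorter than 30 d between two homes are stopovers of the migration
event. Strategy = 1 cluster resident, 2–3 migratory, ≥ 4 nomadic, monitoring
span < 60 d unknown. Migratory moose whose displacement is below the moose
clustering scale (< ~4 km) are classified resident; this is the same scale
ambiguity a visual classifier faces and is left as a documented limit.

Departure day is the last day in the source segment; arrival the first day
in the target. When an animal bounces repeatedly, the event with the longest
flanking stay per season-year is kept. Timing quantiles are empirical with
linear interpolation (fixed so the season worked example is deterministic).
Seasons: spring/fall = [25% departure, 75% arrival], both endpoints
inclusive at day granularity; summer/winter the complements, winter wrapping
the year boundary; the windows are validated to partition both common and
leap years exactly.

## BBMM numerics

The bridge density per coordinate at time fraction α has variance
`T α(1-α) σ²_m + ((1-α)² + α²) δ²`; δ defaults to 20 m. The motion variance
is maximized by bounded scalar search on [1e-8, 1e8] m²/h over the
leave-one-out likelihood of odd fixes given even neighbors. This standard
estimator attributes the left-out fix's own GPS variance to the bridge, so
it carries a known upward bias of order `δ²/(T α(1-α))` relative to σ²_m
(≈ +10% under the recovery test's conditions) — accepted as the field's
convention. Variance is estimated per individual per season, on the season's
own fixes.

Time integration uses Gauss–Legendre quadrature (default 12 nodes per step):
near the pinned endpoints the density collapses to the GPS error scale and
midpoint rules converge slowly, while GL nodes cluster at the endpoints and
reach ~1e-5 cell accuracy. Spatial deposition uses exact separable 1-D
Gaussian cell integrals (normal CDF differences) on a ±6σ window. For
quadrature nodes whose bandwidth spans ≥ 4 cells on lag groups of ≥ 16
steps, an equivalent evaluation deposits bridge means bilinearly into a
histogram and convolves with the Gaussian kernel (FFT for very wide
kernels); the two paths agree to ~1e-6 per cell and the fast path makes
wolf-scale rasters (bridge SD ~ 2 km on a 50-m grid) tractable. Rasters are
normalized to unit mass (enforced to 1e-6).

**Contours.** Cells are ranked by mass; the kept set is the smallest prefix
reaching the level. Tied cells at the cutoff density are admitted only as
needed, in deterministic row-major order — so a uniform 10×10 block at level
0.95 yields exactly 95 cells (0.2375 km²). Contour regions carry both the
cell mask (exact, fast set algebra on a shared grid) and lazily-built
shapely polygons (for analytic geometries and GeoJSON export). One shared
50-m analysis grid, origin snapped to the lattice, covers all individuals so
merging needs no resampling.

## Population distributions and corridor

Merging is a strict three-level mean: individuals within a season-year,
then season-years across years — years weigh equally however many animals
each contributed (verified against hand-computed toy cases). An individual
enters a season-year only with ≥ 3 usable fixes there (a bridge needs a
pair; the variance estimator a triplet). The corridor merges the migratory
population's spring and fall season-year distributions within each year and
then across years, and is treated as non-seasonal. The areal similarity
used to justify merging spring and fall corridors defaults to
intersection / smaller area (bounded, symmetric, robust to nesting);
union- and mean-denominator variants are selectable.

## Range-shift analysis

The white-noise variant is implemented deliberately (not an OU-correlated
one): positions are independent isotropic normals about a mean path that
ramps linearly from μ1 to μ2 over `[t1, t1+dt]`. For fixed `(t1, dt)` the
centers solve a 2-column least squares and σ profiles out in closed form,
so the optimization is 2-dimensional: L-BFGS-B with 5 restarts from jittered
candidates (fixed seed). The LRT uses χ² with df = 4 (second center, t1,
dt). Profile CIs walk outward from the MLE in 6-h steps and refine the
95% crossing (χ²₁ cutoff) by bisection.

Candidates come from k-means (k = 3, 5 starts, seeded) run either on the
whole track or, when season windows are supplied, on each contiguous
three-season window with candidates pooled; boundaries between maximal
assignment runs are scored by the shorter flanking run and de-duplicated
within a day. One model is fit per animal at the best-supported candidate:
measured on stationary white-noise tracks this keeps the type-I error
consistent with α = 0.05, whereas taking the best likelihood over several
candidates is noticeably optimistic (a selection effect, documented rather
than corrected). Against autocorrelated OU tracks the white-noise test is
inherently somewhat anticonservative; the generator's short wolf timescale
keeps this mild, and the no-shift cohort test tolerates one false positive
in six accordingly.

## Overlap statistics

Proportional overlap divides by the *predator* region's area. Wolf-seasons
are split by (season, start-year of the season window); each record needs
≥ 50 locations, and wolves with < 5% of all fixes inside the corridor
boundary are excluded before any record is built (boundary fixes count as
inside; regions are closed). Logit capping at 0.025/0.975 precedes OLS.
Five separate per-prey OLS models (moose, corridor, composite/migratory/
resident deer) regress logit overlap on season + sex + pack, reference
levels winter / F / FL; a rank-deficient design is rejected with the aliased
term named. OLS itself is statsmodels; the package's tests check it against
a hand-solved normal-equations oracle.

Mann–Whitney uses midranks; `W` is the U statistic oriented to the first
group (`W_reversed = nA·nB − W` is also reported since the orientation
convention differs between software). When `nA·nB ≤ 400` the two-sided
p-value (`2·min(P≤, P≥)`, capped at 1) comes from the exact null
distribution computed by dynamic programming over doubled midranks —
scipy's exact method does not handle ties; larger samples use the normal
approximation with tie and continuity corrections.

## Problem sizes used by the packaged experiments

The demo study runs 30 deer (20 migratory / 10 resident), 10 moose
(2 migratory / 4 resident / 4 nomadic, roughly the mixed strategies moose
show), and 6 wolves over 2 years. The directional experiment uses a one-year
world (8 migratory + 3 resident deer, 3 moose, 6 wolves) replicated over 20
seeds. Calibration experiments use 200 stationary replicates (type-I),
50 shifted replicates (power/coverage), 50 Brownian replicates of 500 fixes
(variance recovery), a 35-animal population (classification), and 200
migration events (timing recovery). The timing-recovery experiment sets a
synchronous spread in both seasons (sd 2 d) so that quantile sampling noise
(~0.1·sd at n = 200 per season) is small against its one-day check; with
the asynchronous fall spread the check would measure sampling noise, not
estimator error.

## Known limitations

- The visual classification the segmentation replaces has no ground truth;
  thresholds (separation, dwell, substantial-cluster size) are exposed in
  `ClusterParams` and scale with range size, but pathological movement
  (e.g., sub-separation migrations) degrades gracefully rather than failing.
- The white-noise range-shift likelihood is optimistic under strong position
  autocorrelation and pessimistic about gradual drifts it cannot represent.
- Occurrence distributions assume one motion variance per individual-season;
  behavior-switching (dynamic BBMM) and autocorrelated kernel estimators are
  out of scope.
- Corridor-use and corridor contours depend on how much transit falls inside
  the migration season windows; with very few migrants or strongly
  asynchronous timing the 95% region can clip thin corridor stretches.
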