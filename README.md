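# migoverlap

Seasonal predator–prey spatial overlap from GPS telemetry, built for
wolf–ungulate systems in which migratory prey (white-tailed deer) shift
between winter and summer ranges through a shared corridor while a
territorial predator (gray wolf) holds a year-round territory. The package
asks the questions a movement ecologist asks of such a system: who is
migratory, when do migrations happen, where is the corridor, do predators
shift their ranges to follow prey, and how does predator–prey overlap change
with season?

Because collar data from real predator–prey studies is rarely public, the
package is driven end to end by a synthetic track generator with a
ground-truth ledger, so every stage of the analysis can be scored against
the process that generated its input.

## What it computes

1. **Track QC** — resampling to a 4-h fix grid; censoring of post-mortality
   fixes (terminal runs confined within 50 m for ≥ 48 h), implausible speeds
   (> 10.8 km/h between consecutive fixes), and out-and-back spikes (first
   passage time ≤ 1 h *and* turning angle in the 179–181° reversal band).
2. **Movement classification** — home-range segments from spatial
   clustering with a 30-day dwell rule; strategies *resident* (1 range),
   *migratory* (2–3 ranges), *nomadic* (≥ 4 ranges), or *unknown*; stopovers
   (< 30 d) belong to the migration event. Migration timing quantiles define
   the analysis seasons: spring and fall windows run from the 25% departure
   date to the 75% arrival date, summer and winter are the complements.
3. **Brownian bridge movement model (BBMM)** — for a step pinned at
   relocations `z0, z1` a time fraction `α` along the step, the position is

       N( (1-α) z0 + α z1,  [ T α(1-α) σ²_m + ((1-α)² + α²) δ² ] I )

   with `T` the lag, `σ²_m` the motion variance (m²/h) and `δ` the GPS error
   SD. Integrating over the step duration and summing duration-weighted
   steps (lags > 9 h skipped) gives the occurrence distribution on a 50-m
   grid. `σ²_m` is estimated by leave-one-out likelihood of alternate fixes.
4. **Population distributions and corridor** — individual → season-year →
   across-year mean hierarchy for five populations (wolf, moose, composite /
   migratory / resident deer) × four seasons, plus one non-seasonal
   migration corridor from the migratory deer spring and fall distributions:
   21 distributions in all, with 95% probability contours.
5. **Mechanistic range-shift analysis** — a white-noise range-shift model
   (mean path moving linearly from one center to another over `[t1, t1+dt]`)
   fit by maximum likelihood from a 3-cluster candidate scan, tested against
   the single-center null by a likelihood-ratio test (χ², df = 4) with
   profile-likelihood CIs for shift timing and duration.
6. **Overlap statistics** — per wolf-season (≥ 50 locations; wolves with
   < 5% of fixes in the corridor excluded), proportional overlap =
   area(wolf 95% region ∩ prey 95% region) / area(wolf region);
   logit-transformed with 0.025/0.975 caps and modeled by OLS against
   season + sex + pack (winter/F/FL reference levels; packs NE/NW/SW by
   corridor position, FL for year-round ranges > 561 km²); seasonal
   prey-population contrasts by Mann-Whitney tests with an exact tie-aware
   tail for small samples.

## Worked example

```python
from migoverlap import pipeline

res = pipeline.run(pipeline.demo_config(seed=0))
print(len(res.distributions), res.corridor is not None)
print(res.timing.round(1))
print(res.models["deer-migratory"].table.round(2))
```

prints (seed 0; the demo world has 30 deer, 10 moose, 6 wolves over 2 years):

```
20 True
        start_05  start_25  mean_start  mean_finish  finish_75  finish_95
spring      52.8      54.7        56.3         58.2       59.5       62.2
fall       237.6     246.3       257.1        259.0      266.7      277.0
               coef    se     p
Intercept     -2.90  0.22  0.00
season:fall    1.68  0.23  0.00
season:summer  0.02  0.23  0.92
sex:M         -0.03  0.19  0.89
pack:NW       -0.86  0.23  0.00
pack:SW        0.16  0.23  0.48
```

The timing table is in study days (days since 13 February): spring
departures cluster tightly near day 56 (synchronous April migration) while
fall spans a month (asynchronous October–November return). The resulting
spring season window is only a few days long, so wolf spring-seasons fall
below the 50-location floor and no spring term appears in the model. In the
overlap model for migratory deer, the positive, significant fall
coefficient (+1.68 logits vs. winter) is the headline behavior: wolf
within-territory distributions concentrate on migratory deer during fall
migration.

A shell interface wraps the same stages:

```bash
migoverlap pipeline demo --out demo_run --seed 0
migoverlap simulate --seed 1 --out sim && migoverlap qc --in sim --out clean
```

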