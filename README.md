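# cpforage — sex-specific central-place foraging from GPS tracks

`cpforage` analyses high-frequency GPS tracks of colony-breeding
central-place foragers — the motivating system is breeding lesser kestrels
(*Falco naumanni*) carrying 1-s to 10-min GPS dataloggers — and asks how
the two sexes divide foraging effort across the breeding season.  It
implements the full chain from raw fixes to sex × breeding-period
inference, plus a calibrated synthetic-track generator so the whole chain
can be exercised and validated without access to the original tracking
deposit.

**Pipeline.** A *foraging trip* is a run of fixes that leaves the 50-m
colony buffer, exceeds 300 m from the colony, and contains a *foraging
event* (clumped fixes with highly variable instantaneous speed).  For each
complete trip the package computes duration (h), accumulated distance
(km) and maximum distance from the colony (km); for each *complete
tracking day* (sunrise-to-sunset coverage) it computes daily distance,
number of trips, and colony attendance (% of daylight inside the buffer,
interval-weighted).  *Perching bouts* — sit-and-wait hunting — are runs of
consecutive fixes displaced less than a cadence-specific threshold (1 m at
1-s sampling, 5/15/25/50 m at 1/3/5/10-min), with bouts under 30 s
discarded as possible hovering flight.  Days and trips are labelled with
the breeding-phenology period (establishment, courtship = the 21 days
before laying, incubation, nestling).

**Statistics.** Movement variables are modelled with GLMMs
(gaussian/identity, poisson/log, binomial/logit; log and
arcsine-square-root response transforms) with crossed random intercepts
for individual, year and colony; seasonal trends use penalized regression
splines whose flexibility is chosen by REML.  Model comparison uses AIC
and Akaike weights $w_i = e^{-\Delta_i/2} / \sum_j e^{-\Delta_j/2}$;
predictors are pruned by backward-stepwise likelihood-ratio tests, and
post-hoc sex-within-period / period-within-sex Wald contrasts are
Holm-corrected with a compact letter display.  Habitat-use homogeneity
between sexes is a Pearson chi-squared test on a 2 × 9 count table.

**Synthetic cohort.** `published_summary_preset()` builds sex × period
movement strategies (males: many short trips close to the colony;
females: fewer, longer, farther trips with more perch-hunting; no contrast
before pair formation) normalized in closed form so the pooled means equal
the published summary statistics: 1.16 h trip duration, 6.67 trips/day,
97.82 km daily distance, 19.41 % attendance, 10.98 km trip distance,
3.68 km maximum range, 21.79 min perching per perching trip.  Every
simulated day carries a ground-truth sidecar, making trip segmentation,
metric computation and perch detection directly testable.

## Worked example

```bash
python analysis/01_simulate_tracks.py
python analysis/02_segment_and_measure.py
```

prints (seed 42):

```
2053 complete foraging trips, 300 complete days
variable              measured  published    diff
trip_duration_h           1.15       1.16   -0.8%
trip_distance_km         10.96      10.98   -0.2%
max_distance_km           3.68       3.68   +0.0%
trips_per_day             6.84       6.67   +2.6%
daily_distance_km        98.71      97.82   +0.9%
attendance_pct           19.52      19.41   +0.6%
perch_time_min           21.55      21.79   -1.1%
```

i.e. the segmentation + metrics pipeline, run on tracks it has never seen,
recovers the pooled movement summaries the generator was calibrated to —
each within a few percent (the residual is Monte-Carlo noise of a
300-day cohort plus small scheduling biases documented in
`docs/methods.md`).  `analysis/03_fit_movement_models.py` then fits the
mixed-model set and prints which terms survive backward elimination (the
sex × period interaction, by construction of the generator), with
Holm-corrected letter displays; `04_body_mass.py` reproduces the
AIC-selection of the body-mass model (the smooth-plus-sex model takes
essentially all Akaike weight and recovers the planted −18.28 g male
offset within two standard errors); `05_habitat_use.py` runs the habitat
chi-squared test.

## Acceptance script

```bash
python scripts/acceptance.py --seed 42 --out results/acceptance.json
```

recomputes everything from scratch: it simulates the 30-individual ×
10-day cohort at 1-min cadence with the given seed, runs segmentation,
movement metrics and perch detection, fits the body-mass smooth to a
synthetic parameter-recovery dataset, and writes the pooled trip duration,
daily distance, trips/day, attendance, trip distance, maximum range, mean
perching time and the recovered sex coefficient as JSON (`value` plus the
problem size `n` for each quantity).

## Layout

```
src/cpforage/        library: track_model, phenology, trip_segmentation,
                     movement_metrics, perch_hunting, glmm, stats_layer,
                     synthetic_data, pipeline
analysis/            numbered narrative drivers writing results/
scripts/acceptance.py
tests/               pytest suite incl. tests/test_acceptance.py
docs/methods.md      model and generator documentation
```
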