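# Methods

This note documents the models, rules and numerical choices implemented in
`cpforage`, what the synthetic-data generator does and does not emulate,
and the design decisions taken where the underlying field protocol leaves
the operational definition open.

## Track model and geodesy

Fixes are UTC-timestamped WGS84 positions with altitude (m) and
instantaneous speed (m/s) at one of five cadences (1 s, 1, 3, 5, 10 min).
All distances are great-circle (haversine, R = 6371 km): trips span at
most tens of kilometres, where the ellipsoidal correction is below 0.3 %,
so no projection machinery is used.  Duplicate timestamps keep the first
fix with a warning; malformed CSV rows are skipped and counted.  The
sampling interval is inferred from the modal inter-fix gap, snapped to the
legal cadence set, unless declared.

Sunrise and sunset use the Spencer/NOAA Fourier-series solar position with
the official zenith of 90.833°.  Against a Meeus-algorithm ephemeris the
error is under 2 min near the solstice and up to ~2.5 min near the
equinoxes — negligible relative to the 15-min tolerance used for
day-completeness, but the tests encode the honest bounds.  Polar day or
night raises an error (out of scope for a mid-latitude breeding season).

## Trip segmentation

* Colony attendance: a fix is at the colony iff its distance to an anchor
  site (colony, or optional roosts) is ≤ the 50-m buffer radius
  (boundary inside).
* A candidate excursion is the run of fixes between leaving and
  re-entering an anchor buffer; its departure is the last fix inside
  before exit and its arrival the first fix inside after return, which
  bounds trip duration consistently across cadences.  Excursions missing
  either endpoint are flagged incomplete and excluded from statistics.
* A candidate becomes a foraging trip iff its maximum colony distance
  exceeds 300 m (strictly) **and** it contains a foraging event.
* Foraging events are greedy maximal windows in which every fix lies
  within 100 m of the window centroid, with ≥ 3 fixes and a sample speed
  CV ≥ 0.5.  The altitude criterion (median altitude ≤ 50 m above a
  ground reference) is optional and off by default, because no DEM is
  used; when wanted, the median altitude of colony-attendance fixes
  serves as the ground reference.  These thresholds are package choices
  that operationalize a qualitative description ("clumped locations at
  low altitude with highly variable speed"); they are exposed in
  `ForagingEventParams`.
* A day is complete iff the first fix is ≤ 15 min after sunrise, the last
  ≥ 15 min before sunset, and no internal gap exceeds 3 sampling
  intervals.

## Movement metrics

Trip level: duration = arrival − departure; distance = Σ consecutive-fix
great-circle steps over the trip slice (anchor fix to anchor fix);
maximum distance = max fix distance to the colony.  Daily level: daily
distance sums all consecutive steps of the day; trips are counted on
their departure date; attendance accrues per inter-fix interval with full
credit when both endpoints are inside the buffer and half credit when
exactly one is (unbiased for symmetric crossings), normalized by the
sunrise-to-sunset day length.  Under subsampling the measured path length
can only shrink (triangle inequality) — the reason GPS sampling frequency
enters every model as a correction factor.

## Perch-hunting detection

A perching bout is a maximal run of consecutive steps strictly below the
cadence threshold (1 / 5 / 15 / 25 / 50 m at 1 s / 1 / 3 / 5 / 10 min);
bout duration is the span from the first to the last fix of the run, and
bouts under 30 s are discarded as possible hovering (hovers almost never
exceed 30 s; at cadences ≥ 1 min a single sub-threshold step already
spans ≥ 60 s, so the filter only bites at 1-s data).  Runs are broken at
colony-buffer entries: near-stationary fixes at the colony are
attendance, not hunting.  Whether the original protocol excluded
within-buffer bouts is not stated; this package excludes them.

## Phenology

Periods partition [arrival, fledging] with start-inclusive/end-exclusive
boundaries: establishment (arrival → laying − 21 d), courtship (exactly
the 21 days before laying), incubation (laying → hatching), nestling
(hatching → fledging, with fledging day itself still nestling).  Eldest
chick age is whole days since hatching (hatch day = 0).  A trip spanning
a boundary takes the period of its departure.

## Mixed-model engine

`glmm.py` fits y ~ family(g⁻¹(Xβ + Σ Z_g b_g)) with independent gaussian
random-effect blocks.  Gaussian responses use the exact marginal
likelihood with β and σ² profiled out (ML for likelihood-ratio
comparisons, REML for reported coefficients — the standard split);
poisson/log and binomial/logit use the Laplace approximation with joint
penalized IRLS, the approach of lme4's default `glmer` fit, because no
installed Python package provides maximum-likelihood GLMMs for these
families.  The outer optimization over log standard deviations is
Nelder-Mead (derivative-free, deterministic, smooth at the σ → 0
boundary).  Random factors with fewer than two observed levels are
dropped with a warning.  SE(β) comes from the profiled GLS information
(gaussian) or the top-left block of the inverse joint penalized Hessian
(Laplace).  AIC counts fixed coefficients plus variance parameters (plus
the residual variance for gaussian).  Cross-checks: statsmodels MixedLM
(gaussian, exact agreement), a Gauss-Hermite quadrature oracle (poisson,
agreement to Laplace-approximation error), and R mgcv via Rscript
(smooths).

Penalized smooths use a k = 10 cubic B-spline basis with equally spaced
knots and a second-difference penalty, reparameterized so the penalty
range space becomes an iid random-effect block and the null space
(constant absorbed by the intercept, linear trend as a fixed effect)
stays unpenalized; REML on the block variance then selects the effective
degrees of freedom, and a pure-noise response shrinks to edf ≈ 1.

Backward-stepwise elimination drops the least significant droppable term
with LRT p ≥ 0.05, respecting marginality (main effects protected while
their interaction stands) and never dropping declared correction factors.
Post-hoc inference builds 16 Wald contrasts (sex within each of 4
periods; 6 period pairs within each sex), Holm-corrected as one family by
default (configurable to per-family correction, since the original family
definition is ambiguous), with a compact letter display computed from the
maximal cliques of the non-significance graph.  Percentages are divided
by 100 before the arcsine-square-root transform; log-transformed
responses drop non-positive values with a logged count.

A note on AIC under the null: for a nested 1-df comparison AIC prefers
the smaller model iff 2·ΔlogLik < 2, i.e. with asymptotic probability
P(χ²₁ < 2) ≈ 0.84 — not higher; the tests assert a majority preference
accordingly.

## Synthetic-data generator

### What it emulates

Each individual-day is a schedule over a sunrise-to-sunset tick grid:
colony residency bouts (fixes jittered inside a 20-m disc), K ~ Poisson
foraging trips, and "loafing" excursions that absorb the remaining
daylight.  A trip is an outbound commute at 10 m/s to a foraging patch, a
clumped foraging phase (radius ≈ 85 m, speed CV well above 0.5 via a
hover/strike speed mix), an optional contiguous perching run
(sub-threshold jitter), and a straight return.  Trip duration, maximum
range and perch time are moment-matched lognormals (within-group CVs
0.35 / 0.5 / 0.7) with a gaussian copula (ρ = 0.5) tying range and perch
time to duration — long trips go far and perch more.  Attendance is
planted directly per day as a clipped gaussian fraction of daylight.
At 1-s cadence the foraging phase switches to an explicit hover/flight
alternation: hovers are sub-threshold but always shorter than 30 s, so
only planted perches survive the filter — mirroring why the 30-s rule
exists.

Sex × period structure follows the reported patterns for this system — no
contrast in establishment; males many/short/near, females few/long/far
with more perch-hunting; both sexes busiest in the nestling period — and
the relative pattern is normalized in closed form so the implied pooled
(trip-weighted or day-weighted) means equal the published pooled values
under the default day plan (2 establishment, 2 courtship, 3 incubation,
3 nestling days per individual).

### Calibration corrections (part of the stated construction)

Two realized-vs-planted gaps are corrected at preset-build time, using
only the generator's own arithmetic — never pipeline output:

1. The clump radius is solved so that commute legs plus per-tick clump
   wandering reproduce the pooled trip distance at the calibration
   cadence (the expected hop between uniform points in a disc,
   E ≈ 0.9054 r, refined by the exact pair-distance density).
2. A deterministic *schedule pilot* replays the day-scheduling arithmetic
   (trip draws, infeasible-day resampling, busy-day attendance squeeze,
   perch-window clipping) and inflates the planted trips/day, duration,
   attendance and perch-time parameters until the pilot's realized means
   equal the calibrated targets.

With these corrections a 1 500-day cohort reproduces every pooled target
within ~1 %, and the standard 300-day cohort within ~3 % (Monte-Carlo
noise dominates).

### What it does not emulate

Real GPS error (positions are exact up to planted jitter), altitude as a
usable foraging cue (the altitude criterion is off by default),
weather/thermal soaring, roost sites, nest failure, device outages
(every simulated day is complete by construction), and realistic pooled
*standard deviations*: within-group spreads are kept moderate so day
schedules fit inside daylight with negligible resampling, which makes the
pooled SDs smaller than the published ones (whose spread mixes strong
between-group structure).  Pooled *means* are the calibrated quantities.
At cadences other than 1 min the distance-related summaries deviate from
the printed values (coarser sampling shortens measured paths — the
real-data motivation for the sampling-frequency correction factor), and
at 10-min cadence the minimum trip length of 7 ticks inflates short
trips.  A green pipeline test therefore establishes correct recovery of
*planted structure at 1-min cadence*, not fidelity to every property of
the field data.

### Body mass and habitat

Body mass = 140 g female baseline − 18.28 g male offset + a shared smooth
seasonal curve (amplitude 10 g: rise to incubation, decline through the
nestling period) + individual intercepts (SD 7 g) + residual (SD 5 g),
~9 measurements per bird across March-July (weekly captures).  A shared
curve keeps the smooth-plus-sex recovery experiment well specified;
per-sex curves are deliberately not the default.  Habitat counts are per-
sex multinomials over the nine published habitat classes (renormalized
printed percentages), n = 161 locations per sex.

## Reproducibility

Every individual-day draws from its own RNG stream seeded by
(master seed, individual index, date ordinal), so single days are
reproducible in isolation and cohorts are byte-identical across runs.
The schedule pilot uses fixed internal seeds, making
`published_summary_preset()` deterministic.

## Known limitations

* The Laplace approximation can bias variance components for binomial
  responses with very small cluster sizes; cluster sizes in this design
  (≥ 8 observations per individual) keep the bias well below the
  reported SEs.
* The stepwise procedure inherits the usual caveats of sequential
  testing; it is implemented because it is the procedure being
  replicated, not as a recommendation.
* `solar_times` is accurate to ~2.5 min; applications needing
  second-level ephemerides should substitute a dedicated library.
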