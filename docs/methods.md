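# Methods

## Sleep scoring

Activity is per-minute beam-break counts from a 32-channel activity
monitor under a 12:12 light:dark cycle (zeitgeber minute 0 at lights-on;
ZT 0–719 is day, 720–1439 night). A **sleep bout** is a maximal run of
consecutive zero-count minutes of length ≥ `min_sleep_minutes`
(default 5, the standard fly-sleep rule); an **activity bout** is a
maximal run of positive-count minutes, with no minimum length — the
symmetric definition minus the threshold. Minutes in zero runs shorter
than the threshold are awake-but-inactive and belong to neither bout
kind, so per period: sleep minutes + awake minutes = 720.

Runs crossing a day/night boundary are split at the boundary and each
segment keeps the parent run's state *without re-applying the threshold*:
the animal was asleep throughout, and this convention keeps total sleep
additive across periods. (How the original Matlab scorer treated boundary
runs is not documented anywhere we could find; splitting is our choice
and is asserted in tests, not inferred.)

An **animal-period pair** — one animal, one 12-h day or night — carries
total sleep *T*, bout count *x* and mean bout length *y* = *T*/*x*
(undefined when *x* = 0). This identity is exact by construction and is
asserted on every summary; it is also the structural reason the
regression below measures total-sleep regulation.

Cohort statistics use **mean of means**: per-pair mean bout lengths are
averaged unweighted across pairs (pairs with zero bouts excluded from the
bout-length mean only), never pooled across bouts. SDs are sample SDs;
the SD of a single observation is reported as 0 with a logged warning.

**Health exclusion.** The default rule excludes an animal wholesale when
it shows no activity in the final 12 h of recording — the usual signature
of death, whose apparent "sleep" would otherwise contaminate every
statistic. The rule is pluggable (`health_filter(traces, rule=...)`);
the published analyses this emulates used an unpublished criterion.

## The power-law model

For each condition the pairs (*x*, *y*) with *x* ≥ 1 are fitted to
*y* = *a·x*^*b* by least squares, minimizing Σ wᵢ(yᵢ − a·xᵢ^b)². The
ordinary fit has wᵢ = 1; the weighted variant uses wᵢ = 1/yᵢ² (constant
relative error). Because *T* = *x·y* exactly, a fit with *b* = −1
reduces to *x·y* = *a*: the scale parameter estimates the condition's
typical total sleep, and R² = 1 − SSres/SStot (SStot about the mean of
*y*) measures how tightly total sleep is held there. For *b* > −1 the
scale underestimates total sleep, for *b* < −1 it overestimates.

Numerical contract:

- **Initialization** from the ordinary linear regression of ln *y* on
  ln *x*; with that start, Levenberg–Marquardt (analytic Jacobian,
  ftol/xtol/gtol 1e-10, ≤ 1500 objective evaluations) converges
  deterministically on well-posed inputs. Non-convergence is flagged on
  the result, which is still returned.
- **Covariance** s²·(JᵀWJ)⁻¹ with s² = SSres(w)/(n − 2); 95% parameter
  CIs are estimate ± t₀.₉₇₅,ₙ₋₂ · SE.
- **Confidence band** by the delta method:
  ŷ(x) ± t₀.₉₇₅,ₙ₋₂ · √(gᵀCg), g = (x^b, a·x^b·ln x). This is a band
  for the fitted curve, not a prediction band for new observations.
- **Dependency** = cov(a,b)²/(var(a)·var(b)) ∈ [0, 1]; values near 1
  mean the two parameters are nearly redundant for the data at hand.
  (Reference analyses of real fly data report 0.822–0.984; the simulated
  cohorts here, whose bout counts concentrate at small x, give lower
  values — the statistic is data-dependent and is not calibrated for.)
- **R² of weighted fits** is reported from *unweighted* sums of squares
  by default so weighted and unweighted fits are comparable
  (`weighted_r2=True` switches to weighted sums).
- **Degenerate inputs**: < 3 points or < 2 distinct x values are errors
  (the exponent is unidentifiable); all-equal *y* makes R² undefined
  (NaN). Fixing the exponent (`fix_b=-1`) uses the closed form
  a = Σw·x^b·y / Σw·x^(2b) with n − 1 degrees of freedom.

Eligibility: pairs with *x* = 0 have no defined *y* and are excluded from
regression input, but remain in total-sleep cohort statistics.

Confidence-interval coverage is validated under multiplicative noise
y = a₀x^(b₀)(1 + ε) with the variance-matched 1/y² weighted fit; the
unweighted fit's homoscedastic covariance formula is *not* calibrated
under multiplicative noise, which is precisely why the weighted variant
exists.

## Hypothesis tests

- **D'Agostino & Pearson omnibus K2**: K2 = Z(√b₁)² + Z(b₂)², using the
  Johnson-SU skewness transform and Anscombe–Glynn kurtosis transform
  with the constants of D'Agostino, Belanger & D'Agostino (1990),
  referred to χ²(2). Requires n ≥ 20. Exposed both for raw samples and
  for the pooled y-residuals of a fit (`residual_normality`) — least
  squares assumes Gaussian residuals, and the report labels which usage
  produced each row.
- **Welch's t test**: two-tailed, two-sample, unequal variances,
  Welch–Satterthwaite degrees of freedom. Used for genotype comparisons
  of total sleep, mean bout length and bout count, per period and per
  24 h (day + night sums per animal-day). No multiple-testing correction
  is applied (deliberately, to match standard practice in this
  literature); the report footer says so.

## The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes;
its defaults are the study conditions, not tuning knobs.

**Regulated mode** (the key modeling commitment): per pair, draw bout
count *x* from the calibrated count distribution, draw total sleep *T*
from Normal(mean, SD) truncated to [5x, 720 − (x − 1)], round to whole
minutes, and set *y* = *T*/*x*. The identity *y* = *T*/*x* holds exactly
in real scored data, so all scatter about the power law derives from
variation in *T* — which is exactly the interpretation of R² as
total-sleep regulation. Consequences worth knowing:

- the truncation bounds guarantee every summary is realizable as a trace
  (each bout ≥ 5 min, one waking minute between bouts; bout counts are
  capped at 120, the largest feasible value);
- truncation biases realized means slightly toward the feasible interval
  (control night ≈ −3.5 min from the upper bound; conditions with large
  counts and wide SDs, such as the *insomniac* presets, gain ≈ +10–20 min
  from the lower bound 5x). These shifts are small against the SDs
  involved and are left uncorrected;
- rounding *T* to whole minutes (needed for minute-level traces) adds
  ±0.5 min noise, negligible against every condition's SD.

**Unregulated mode** (severely fragmented mutants): *x* as above; *y*
drawn log-normally (median = mean total sleep / mean count, log-SD 1.0)
*independently* of *x*; *T* = clip(round(x·y)) to the feasible interval,
with *y* recomputed as *T*/*x* where clipping bites. Because *y* carries
no information about *x*, the fitted R² collapses toward 0. Note that
total sleep *x·y* is then positively correlated with bout count — a
structural consequence of independence, not a calibration target.

**Count distribution**: shifted negative binomial 1 + NB(r, p),
moment-matched analytically to the target mean/SD (healthy bout counts
are over-dispersed — SD 4.2 on mean 4.9 — which a Poisson cannot
express). Infeasibly small SDs fall back to a shifted Poisson with a
logged warning; SD ≈ 0 collapses to a point mass.

**Trace realization**: bout lengths are a uniform composition of *T*
into *x* parts ≥ 5; waking gaps a uniform composition of the awake
minutes into *x* + 1 parts with interior parts ≥ 1. The two compositions
are independent, so arrangements are uniform over the feasible set.
Awake minutes get positive-truncated Poisson(activity_rate, default 2)
counts. Re-scoring a realized trace reproduces its summary exactly
(asserted as a round-trip property).

**Deprivation/rebound scenarios**: baseline day/night conditions for
days 1–4 / nights 1–3; night 4 sleep drawn Normal(deprivation mean, SD)
truncated ≥ 0 — deprivation is modeled only through its outcome, not the
mechanical protocol that produces it; day 5 regulated around the rebound
mean with a tighter relative SD than baseline day (496 ± 50.2 min for
control, vs 396.4 ± 82.9 baseline), which reproduces the empirical
finding that rebound sleep is *more* tightly regulated than ordinary
daytime sleep.

**Presets.** Control and *insomniac* presets use the published cohort
moments (31 animals × 4 periods; control night 672.6 ± 29.9, day
396.4 ± 82.9; counts 4.9 ± 4.2 night, 12.6 ± 4.6 day; *insomniac* night
394.7 ± 148.7, counts 16.8 ± 7.5 night, 23.1 ± 8.1 day). *Insomniac*
daytime totals were never published directly; the preset derives them
from the 24-h (770.1 ± 210.0) and night moments assuming independent day
and night totals (mean 375.4, SD 148.3). *iso31* and *fumin* presets use
the published totals of the first comparison experiment; their bout-count
moments were not published, so *iso31* borrows control-like counts and
*fumin* uses plausibly fragmented ones (day 18 ± 7, night 12 ± 7).
*fumin* runs in unregulated mode. Each preset carries a fixed seed so
default runs are reproducible; one seeded generator drives all of a
cohort's randomness.

## What the simulations do and do not show

The generator reproduces the *moment structure* (total-sleep and
bout-count means/SDs, the exact T = x·y identity, over-dispersed counts)
and the regulated/unregulated dichotomy. It does not model circadian
waveform within a period (bouts are placed uniformly), inter-day
correlation within an animal (pairs are independent), arousal dynamics,
or the joint constraint between the count distribution and mean bout
length — matching count mean/SD and total sleep does not guarantee
matching a published mean bout length (e.g. 216.1 min for control
night), and the generator does not calibrate it. Passing tests therefore
demonstrate the analysis machinery and its sensitivity to regulation,
not biological realism of minute-level behavior. Real-data residuals are
heavier-tailed than the generator's truncated normals; the K2 test's
role in the pipeline is exactly to surface that.

## Problem sizes

Default analyses run 124 pairs per condition (31 animals × 4 periods,
the published cohort size) and 7–9 animals for rebound scenarios.
Property suites use 500 parameter-recovery replicates for CI coverage,
100 seeded replicates for K2 type-I calibration, 1000 for Welch null
calibration, 50 seeds × 4 grid points for the R²-vs-spread monotonicity
check, and random traces up to 2880 minutes for scoring-oracle
agreement. The whole suite runs in well under a minute on one CPU.
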