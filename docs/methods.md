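# Methods

## Scope and data model

`actiprofile` computes a comprehensive physical activity / inactivity
profile from minute-epoch accelerometer output: per-minute activity counts
(counts/min) and steps (steps/min), 1,440 minutes per participant-day.
Minutes are indexed 0–1439 and every interval in the package is half-open
`[start, end)`. Minutes absent from an input file are filled with zero
counts and steps (the convention of the public-release monitor files, where
unrecorded time appears as zero activity) and each fill is logged.

The pipeline has three stages:

1. **Day stage** — wear detection, intensity classification, volume and
   rate indicators, censored steps, sedentary breaks, MVPA bout minutes,
   day validity.
2. **Participant stage** — unweighted day averages, step-defined activity
   level, public-health-guideline achievement, BMI category.
3. **Cohort stage** — ordered exclusion cascade, survey-weighted means with
   linearized SEs per indicator × sex × BMI category, and weighted trend
   tests across BMI categories.

## Wear detection

A minute is non-wear iff it lies in a maximal run of consecutive
zero-count minutes of length ≥ `wear.min_zero_run` (default 60 min). Runs
are detected day-wise and never span day boundaries, because monitor files
are day-blocked and all aggregation is per-day. A day is *valid* when worn
time ≥ `wear.min_wear_minutes` (default 600 min = 10 h, inclusive).

The strict-zero rule is the default: any minute with counts ≥ 1 breaks a
run. An optional allowance (`max_interruption`, `interruption_ceiling`,
off by default) merges zero runs separated by ≤ 2 min of counts below a
ceiling, for sensitivity analyses against more tolerant macro variants.
With the allowance active a non-wear run may contain its interrupting
minutes, so the all-zero run property holds only for the default.

## Intensity classification and day indicators

Count bands are half-open with inclusive lower bounds, matching the
integer cut points used for the national monitor data:

| class     | counts/min    |
|-----------|---------------|
| sedentary | [0, 100)      |
| low       | [100, 500)    |
| light     | [500, 2020)   |
| moderate  | [2020, 6000)  |
| vigorous  | [6000, ∞)     |

Non-wear takes precedence: a zero minute inside a qualifying zero run is
never sedentary time; a zero minute outside such runs is sedentary. The
six classes (non-wear + five intensities) always decompose the 1,440-minute
day exactly.

Volume indicators are daily sums (activity counts/day, steps/day).
**Censored steps** drop steps from minutes with counts < `censor_below`
(default 500, the low/light boundary, configurable independently); count
totals are never censored. Rate indicators divide daily volumes by worn
minutes; a zero-wear day yields NaN rates — an explicit undefined marker
distinct from zero.

A **break in sedentary time** is an adjacent pair of *worn* minutes whose
counts rise from below the sedentary bound (< 100) to at or above it.
Requiring both minutes to be worn reflects that a sit-to-stand transition
is only observable during wear; a pair touching non-wear is not counted.

## MVPA bouts and the guideline

A modified 10-minute bout opens at a worn minute with counts ≥ 2,020
(inclusive, consistent with the moderate band's lower bound), continues
through above-threshold minutes and below-threshold interruptions of at
most 2 consecutive minutes, and closes when a below-threshold run exceeds
the allowance, a non-wear minute occurs, or the day ends. With the default
parameters this closure is identical to the "terminated by 3 minutes below
threshold" rule; the implementation closes a candidate at the first
below-threshold run longer than `max_interruption_run`, which is the
earliest closing event permitted by the parameter invariant
(`max_interruption_run < termination_run`). Trailing below-threshold
minutes are trimmed so a bout starts and ends on above-threshold minutes.
A candidate is emitted iff it contains ≥ 10 above-threshold minutes; only
above-threshold minutes are credited toward bout minutes, because the
guideline phrase counts minutes *of at least moderate intensity*.

Guideline achievement — ≥ 30 bout minutes on ≥ 5 of 7 days — is evaluated
deterministically on the observed valid days. Participants with fewer than
5 valid days can therefore never qualify; this biases prevalence low for
short-wear participants relative to model-based imputation approaches, and
is a deliberate, documented simplification.

## Participant aggregation

Indicators are averaged with unweighted arithmetic means over **valid
days** by default (`aggregate.averaging = valid_days`); averaging over all
worn days (any wear > 0) is available because the inclusion language of
surveillance reports is ambiguous between the two. Rates are averaged as
per-day rates. Step-defined activity levels classify mean censored
steps/day into six half-open bands: basal [0, 2500), limited
[2500, 5000), low active [5000, 7500), somewhat active [7500, 10000),
active [10000, 12500), highly active [12500, ∞). BMI categories are
underweight [0, 18.5), normal [18.5, 25), overweight [25, 30), obese
[30, ∞) kg/m²; the half-open convention resolves the boundary ambiguity
sometimes printed as "≤ 18.5".

## Cohort estimation

The exclusion cascade assigns each eligible participant to the first
failing rule, in order: unreliable device data → uncalibrated device →
self-reported pregnancy → BMI > 100 kg/m² → no valid day of wear. Bucket
counts always conserve the eligible total.

Weighted means use the ratio estimator Σwx/Σw with a standard
stratified-cluster Taylor linearization (with-replacement PSU
approximation): with score zᵢ = wᵢ(xᵢ − x̄)/Σw and PSU totals z_hc,
Var = Σ_h n_h/(n_h−1) Σ_c (z_hc − z̄_h)². With no design variables the
sample is one stratum with each unit its own PSU, reducing to the familiar
weighted-ratio SE (and to s/√n under equal weights). A stratum with a
single PSU either raises an error or is collapsed into a synthetic stratum
(`summary.single_psu`, default `collapse` in the cohort tables). 95% CIs
use the normal multiplier 1.96 by default (design-df t multipliers can be
substituted via `summary.ci_multiplier`). Exact replication of
masked-design variance estimation for the national survey is out of scope.

Trend tests fit survey-weighted least squares of an indicator on the
ordinal BMI-category code (0 = normal, 1 = overweight, 2 = obese), with a
sandwich covariance — PSU-clustered when design variables are present,
heteroskedasticity-robust (HC1) otherwise — and a two-sided p-value for
the slope. An optional wear-time covariate supports the
wear-adjusted sensitivity analysis. The test is the simplest
design-consistent choice for an ordered-category trend and is recorded in
the summary metadata. Underweight participants are profiled but excluded
from cohort tables and trends by default (small-sample convention),
controlled by `summary.include_underweight`.

## Synthetic cohorts and ground truth

The generator draws, for each scheduled wear minute, an intensity class
from a mixture, counts uniformly within the class band (vigorous capped at
15,000 counts/min by default — only band membership matters downstream, so
the marginal shape within a band is free), and steps from a Poisson with a
class-specific mean, forced to zero whenever counts are zero. Scheduled
non-wear minutes are exact zeros. Defaults encode the population
conditions the pipeline is meant to reproduce:

- one 715-minute wear block per day ([480, 1195), ≈ 11.9 h, every day
  valid), 7 days per participant;
- wear-time intensity shares 56.8 / 23.7 / 16.7 / 2.6 / 0.2 % (sedentary
  → vigorous);
- BMI-category prevalences 69 : 1016 : 1195 : 1242 (underweight : normal :
  overweight : obese) with uniform BMI within category;
- per-category activity scaling (normal 1.10, overweight 1.05, obese 0.88)
  applied to the moderate/vigorous mixture mass and to step means,
  following the observed censored-steps gradient about the overall mean;
- class step means (1, 16, 41, 80, 105 steps/min) chosen once so that
  censored ≈ 6.5 k and uncensored ≈ 9.5–10 k steps/day emerge — the class
  step rates themselves are not published quantities;
- 3.2 % of participants are "bouters" who receive one injected qualifying
  bout per day (16 + 2 + 16 minutes: 32 above-threshold minutes with one
  2-minute interruption), so guideline prevalence is ≈ 3.2 % by
  construction;
- lognormal survey weights, 15 strata × 2 PSUs.

Ground truth for every day and participant indicator is computed from the
construction (sampled labels, schedule, injection patterns), not by
running the pipeline. Two guards make the truth exact rather than
approximate:

1. **Zero-run guard** — wear minutes adjacent to a block edge are forced
   non-zero and interior zero runs are capped below 60 min, so the wear
   schedule *is* the wear truth (with the default sedentary-zero
   probability of 0.3 a spontaneous 60-zero wear run is essentially
   impossible anyway; the guard makes it structurally impossible).
2. **Bout guard** — background moderate/vigorous minutes are demoted to
   light whenever they would accumulate 10 above-threshold minutes without
   an intervening closure, and a termination-length buffer below threshold
   is cleared around each injected bout, so the injected patterns are
   exactly the bouts present in the data.

What the generator does **not** emulate: within-day autocorrelation
(classes are i.i.d. given the schedule, so sedentary-break counts are
higher than in real behaviour, ≈ 175/day rather than ≈ 90), circadian
structure, device noise, partially-worn transition minutes, and
participant-level correlation between wear time and activity. Passing
end-to-end tests therefore demonstrates algorithmic correctness of the
pipeline on data with the assumed structure, not behavioural realism of
the cohort.

## Test and script problem sizes

The verification suite checks scanner equivalence against naive
brute-force oracles on 10,000 structured random days (boundary-heavy count
palette), conservation identities on ~2,400 days, exact ground-truth
recovery on a 50 × 7-day cohort, statistical calibration at n = 1,000
(weighted-mean recovery within 3 SEs of the generator-implied expectation)
and 2,000 null replicates of n = 300 for the trend test's type-I error.
`scripts/acceptance.py` regenerates the default cohort (n = 1,000, 7
days), runs the full pipeline and reports the weighted estimates, plus an
oracle-equivalence mismatch count over 2,000 fresh random days.

## Known limitations

- Guideline prevalence is biased low for participants with < 7 (especially
  < 5) valid days; no model-based imputation is attempted.
- SEs use the with-replacement PSU approximation; no finite-population
  correction, no age standardization, no replicate-weight methods.
- The trend test treats BMI category as an equally-spaced ordinal score.
- The wear-detection interruption allowance is a sensitivity tool, not a
  validated reimplementation of any specific macro's tolerant mode.
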