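# Methods

This note documents the models, rules, and numerical choices behind
`gravitrack`, and what the synthetic cohort does and does not emulate.

## Gestational calendar

All dates are located on a gestational timeline anchored at day 0 (the
start of gestational week 1, i.e. the last-menstrual-period reference).
Gestational week `w` covers gestational days `7(w-1) … 7w-1`, the
obstetric "completed weeks" convention. Under this convention the
pregnancy monitoring window of weeks 13–42 (half-open at week 42) spans
exactly `7 × (42 − 13) = 203` days, and the postpartum window is the 28
days strictly after delivery; the delivery day itself belongs to
pregnancy. The second trimester is weeks 13–27 and the third trimester
runs from week 28 to delivery (the completed-weeks 27/28 split; sources
differ on 26/27 vs 27/28, and this package fixes the former convention
once rather than exposing it as an option).

Coverage denominators are deliberately *fixed* at 203 and 28 days for
every participant, independent of the actual delivery date: a
participant delivering at week 38 can therefore never reach 100%
pregnancy coverage. This mirrors reporting practice for cohorts with a
single nominal follow-up length.

## Preprocessing

**Heart-rate homogenization.** Wrist devices emit heart-rate samples at
irregular rates. Samples are binned onto a 15-minute grid anchored at
local midnight (so daily aggregation never splits a bin): bins
containing samples get the arithmetic mean (`averaged`); runs of empty
bins flanked by averaged bins no farther apart than `max_gap` (default
60 min = 4 bins) are filled by linear interpolation *between the bin
aggregates*, never between raw samples (`interpolated`); everything else
is `missing`. Longer gaps are treated as off-wrist evidence rather than
interpolated.

**Wear detection.** A minute counts as worn iff its covering bin was
directly averaged from samples (optical heart-rate contact), or the
minute itself recorded a positive step count. Interpolated bins are not
wear evidence — interpolation spans exactly the intervals where the
device produced nothing.

**Sleep cross-check.** Device-scored sleep periods are validated
automatically against wear and movement (the upstream device scoring is
trusted; re-scoring sleep from raw signals is out of scope): a period
containing any not-worn minute is removed (`off-wrist`); a period whose
fraction of positive-step minutes exceeds `movement_fraction_threshold`
(default 0.10) is removed (`movement-mismatch`); leading/trailing runs
of stepping minutes are trimmed off, with the device's awake minutes
rescaled proportionally to the retained duration (the device's per-period
awake attribution is not recoverable after trimming, so proportional
rescaling is this package's choice). The operation is idempotent on its
own accepted output, and every non-accepted period carries an audit
reason.

## Validity rules

- A day's **awake wear** is its worn minutes outside retained sleep
  periods. "10 hours while awake" is read against the device's own sleep
  periods, not clock time.
- An **activity day** is valid at ≥ 600 awake-wear minutes. In the
  delivery week (which is truncated — a delivery at 40+1 leaves a 2-day
  week) any day with positive awake wear is admitted. The exception
  applies only to days up to and including delivery: postpartum days that
  happen to share the gestational week are ordinary postpartum days, or
  the postpartum coverage would be mechanically inflated.
- An **activity week** needs ≥ 4 valid days; the delivery week needs ≥ 1
  (a 4-day rule is unsatisfiable in a 2-day week).
- A **sleep week** needs ≥ 4 retained sleep periods on distinct nights.
  Nights run noon-to-noon: a period starting after midnight belongs to
  the night it interrupted. Whether the 4 periods must fall on distinct
  nights is ambiguous in the underlying protocol; this package counts
  distinct onset nights.
- Days that enter analysis must pass both their day rule and their week
  rule.

## Metrics

- **Daily steps**: sum of minute counts; absent minutes contribute 0.
- **Nightly sleep**: durations of retained periods attributed to the
  onset night, minus device awake minutes (which are reported
  separately). A night without a retained period is *missing*, not zero.
- **Resting heart rate**: the minimum 30-minute (2-bin) rolling average
  of consecutive non-missing bins within the calendar day; missing if no
  two consecutive bins exist. Weekly resting HR is the mean of daily
  values. Device vendors do not publish their resting-HR computation;
  the minimum sustained average is a standard operationalization.
- **MVPA (intensity minutes)**: a minute qualifies as moderate when the
  homogenized heart rate reaches `resting + 0.40 × (max_hr − resting)`
  with `max_hr = 220 − age` (heart-rate reserve), or — only when no
  heart-rate value covers the minute — when cadence reaches 100
  steps/min; vigorous uses fraction 0.60 and 130 steps/min. Only minutes
  inside maximal runs of ≥ 10 consecutive qualifying minutes earn
  intensity minutes, and *every* minute of a qualifying run counts (not
  run − 9). The HRR fractions and cadence cut-points are standard
  exercise-physiology conventions, all exposed in config; heart-rate
  reserve logic is approximate in pregnancy, where resting HR rises and
  maximal HR falls.
- **Guideline compliance**: a week is compliant at ≥ 150 moderate or
  ≥ 75 vigorous minutes; a config switch additionally counts vigorous
  minutes double toward the 150 (off by default — device behaviour here
  is unverifiable). Reported percentages round half away from zero.
- **Aggregation**: weekly values average valid days within valid weeks;
  period values average *all* accepted days of the period directly, so a
  period mean equals the mean over the concatenated valid days with no
  week-weighting. A participant-period with zero valid days is absent
  from that period's n (the shrinking-n pattern of longitudinal tables).

## Longitudinal statistics

Period and weekly comparisons use a linear mixed model with one
within-participant time factor and a **compound-symmetry** covariance:
all observations of a participant share variance σ² and pairwise
correlation ρ, i.e. `V_i = σ²[(1−ρ)I + ρJ]`. The fit is restricted
maximum likelihood with σ² profiled out in closed form and a bounded
1-D search over ρ on `(−1/(m−1), 1)` (so negative within-participant
correlation is representable — a random-intercept parameterization is
not equivalent, as it forces ρ ≥ 0). Participants with missing levels
contribute their observed cells through the likelihood; no imputation.

Cell means, all pairwise contrasts (adjacent pairs first) and an overall
Wald F test are reported with t/F reference distributions on
between-within degrees of freedom `N − s − (k − 1)`, which reduces to
`(s−1)(k−1)` for balanced complete data and makes the two-level
complete-pair contrast identical to the paired t test. No multiplicity
adjustment is applied to pairwise contrasts. All tests are two-sided at
α = .05. Degenerate zero-variance data short-circuit to exact means with
zero-width intervals.

MVPA (non-normal) is compared across periods with the Friedman test,
tie-corrected, on complete cases; for ≤ 8 blocks an exact permutation
p-value is computed by dynamic programming over within-block rank
permutations, and the χ² approximation is expected to land between the
strict and non-strict exact tail probabilities. Activity–sleep
association uses Spearman rank correlation (tie-adjusted, two-sided).

The weekly model treats gestational week as a categorical factor with
compound symmetry over the declared week set — the same structure as
the period model, applied to a finer level set.

## Synthetic cohort generator

The generator emulates the study conditions of a 20-woman nulliparous
cohort monitored continuously from gestational week 13 to one month
postpartum, and is first-class tested code, not a fixture:

- age ~ N(26, 5²) years; delivery at N(39.4, 2.6²) gestational weeks
  (draws clipped to 29–43 weeks only when constructing calendar dates);
- daily steps: flat participant-level mean near 6838/day to week 31,
  linear decline from week 32 to a floor equal to the postpartum mean
  3705/day at week 36; day totals are lognormal around the trajectory
  (right-skewed, non-negative; within-person CV 0.25, between-person SD
  1200 — day-level variance components are not published anywhere, so
  these two are explicitly uncalibrated defaults);
- minute allocation: a background comb of walking minutes (cadence well
  below the moderate threshold) between 08:00 and 21:00, plus scheduled
  exercise bouts of 15/30 minutes aligned to 15-minute bins at cadence
  ~110 steps/min with heart rate at 50% of heart-rate reserve, so the
  bout detector's heart-rate branch sees unambiguous bins. Weekly bout
  volume is lognormal with cohort median 46 min/week, scaled by 0.6 in
  the third trimester and 0.35 postpartum;
- sleep: one period per night with onset ~23:00 ± 30 min; sleep minutes
  N(477/457/393, 45²) by period plus a participant offset; awake minutes
  built from a Poisson number of awakenings with ~7-minute exponential
  durations calibrated to means 21/32/67. The final night of the window
  spills past the monitoring end and goes unrecorded;
- resting heart rate: linear 60 → 70 bpm from week 13 to week 32,
  plateau to delivery, linear return to baseline across the postpartum
  month; samples carry a daytime circadian bump (absent during sleep,
  where noise is folded positive so the nightly minimum tracks the
  trajectory);
- heart-rate sampling: 3-hour blocks alternating dense (~70–130 s
  spacing) and sparse (~10–15 min) regimes so homogenization exercises
  both averaging and interpolation. Night blocks (21:00–09:00) keep a
  ≤ 7-minute gap: with the averaged-bins-only wear rule, sparser night
  sampling would disqualify sleep wholesale as off-wrist;
- missingness: per-day whole-day sync gaps (45% of the segment rate) and
  long 7–13 h non-wear intervals (55%), with expected day-invalidation
  rates 0.28 in pregnancy and 0.48 postpartum, plus benign 1–2 h
  non-wear on 15% of days. Non-wear intervals contain no heart-rate
  samples and zero steps. The defaults land median valid-day coverage
  near 70% of 203 pregnancy days and near 50% of 28 postpartum days;
- reproducibility: one global seed with per-participant derived
  substreams (`[seed, participant, concern]`), so cohorts are
  bit-identical under a seed and each participant is independent of
  cohort size.

**What the generator does not emulate**: raw accelerometer or
photoplethysmogram waveforms, device battery behaviour, pregnancy
complications, naps (exactly one sleep period per night), informative
(outcome-dependent) missingness, seasonal or weekday structure, and
drift or bias in the device's own step/sleep scoring. Passing end-to-end
tests therefore demonstrates that the pipeline recovers the structure
this generator encodes, not that the device's proprietary scoring is
reproduced.

## Problem sizes and numerical choices

The default test and acceptance runs use the 20-participant cohort
(~230 monitored days each, ~90k heart-rate samples per participant);
the law-of-large-numbers pass-through check uses 200 participants, and
mixed-model recovery uses 200 simulated cohorts of 20 — sizes chosen so
the whole suite completes in a few minutes on one core. The REML search
over ρ uses `xatol = 1e-12` so the two-level contrast p-value matches
the paired t test to 1e-8. Friedman exact enumeration is capped at 8
blocks / 3×10⁶ permutations. Report percentages round half away from
zero; timestamps are naive local time (time zones and daylight-saving
are out of scope).
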