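# Methods

This note documents the statistical model behind `exacertrend`, the
conventions chosen where the published analysis left details open, and
what the synthetic-data checks do and do not establish.

## Outcome definition and phenotyping

The unit of analysis is the binary patient-week: in each ISO-8601 week a
patient either has an exacerbation episode or is episode-free. A week
holds an episode when at least one of three triggers falls in it:

* (a) an asthma-related A&E attendance code;
* (b) a hospital-admission code with an asthma diagnosis code recorded for
  the same patient on the same calendar day;
* (c) an oral corticosteroid (OCS) prescription with a respiratory-review
  event within the review window.

Multiple triggers in one week collapse to a single episode; triggers in
different weeks count separately — no merge rule is applied across
consecutive weeks. Each episode week carries a care-setting label:
`hospital` if any trigger is (a) or (b), otherwise `primary`. Hospital
takes precedence because the label describes where the episode was
resolved.

Conventions chosen here:

* **Review window direction.** "Within two weeks" is directionless in the
  source definition; the default is symmetric (±14 calendar days), because
  discharge or review correspondence can precede or follow the
  prescription. `review_window_mode` exposes `after`, `before` and `both`.
* **A&E code dating.** Attendance codes such as "A&E attendance since last
  visit" are counted in the week they are *recorded*; the true attendance
  date is not recoverable from primary-care records.
* **Week grid.** Only ISO weeks fully contained in the follow-up interval
  are analysed; records in partial boundary weeks are ignored (with debug
  logging). For the default follow-up (2016-01-02 to 2021-10-03) the grid
  is exactly 300 weeks, 2016-W01 .. 2021-W39.

The cohort is any patient with ≥1 asthma diagnosis code in the
identification window (2010–2015), restricted to patients with ≥1 episode
during follow-up ("exacerbators"); an empty analysis cohort is an error.

## Rates and quarterly aggregation

The weekly rate is episodes divided by the active-patient denominator,
scaled by 365.25/7 × 100 to episodes per 100 patient-years. The
weeks-per-year constant is not stated in the source analysis; 365.25/7
(≈52.1786) reproduces the published rate magnitudes to within rounding.

* **Denominator convention.** A patient counts in a week if their activity
  interval overlaps any day of it (`overlap`, default); a strict
  full-week-coverage alternative (`strict`) is provided for sensitivity.
  A week with zero denominator raises an error rather than producing a
  silent NaN.
* **Quarter calendar.** Follow-up is divided into consecutive 13-ISO-week
  blocks per year; an ISO year with 53 weeks (2020 in the study span)
  contributes one 14-week final quarter absorbing week 53, and a trailing
  block shorter than 13 weeks is dropped with a warning. The published
  summary instead prints the 14-week block against 2018 and a 52-week
  2020 — labels that cannot be realised on the ISO calendar (ISO 2018 has
  52 weeks, ISO 2020 has 53). `build_quarters` therefore defaults to the
  ISO-consistent calendar and accepts an explicit quarter map for analyses
  that must match an externally fixed layout.
* **Quarterly summary.** The quarter's rate is the *unweighted mean of the
  weekly rates* (not pooled episodes over pooled patient-weeks — the two
  differ under attrition), with a two-tailed t-interval
  mean ± t₀.₉₇₅,ₙ₋₁·s/√n. Reported tables round to 1 dp; internal
  computation keeps full precision.

## Control series and Welch comparison

For quarter position q ∈ {1..4} the control value is the mean of the
corresponding quarterly rates over the control years (default 2016–2019);
a missing control quarter is an error. Each target quarter is compared to
its position-matched control:

* difference in means, `diff = mean(target weekly rates) − mean(pooled
  control weekly rates)`, negative for reductions;
* Welch two-sample 95% CI with Satterthwaite degrees of freedom (via
  `scipy.stats.ttest_ind(equal_var=False)`; the closed-form Satterthwaite
  formula is used as an independent oracle in the tests);
* percentage change = 100·diff / control mean.

The Welch **sample construction** is not stated in the source analysis.
The default uses the target quarter's 13 weekly rates against the pooled
weekly rates of the matching position across control years (52 values for
four 13-week quarters): pooling maximises degrees of freedom and is the
reading that yields CIs on the scale of the published ones. A
`welch_samples="quarterly"` alternative (4 control points) is provided.
If both samples have zero variance the CI degenerates to the point
difference with a warning. Changes beyond ±25% are flagged "substantial" —
a descriptive label, not an inferential gate; no multiple-testing
adjustment is applied (none was in the original analysis).

## Stratification and sensitivity cohorts

Only year of birth is assumed available: ages use a July-1 birthday and
completed years at 2016-01-01, mapped to bands 0-5 / 6-17 / 18-54 / 55+.
Region derives from the GP practice postcode area through an editable
lookup shipped as data. Missing sex/birth-year/region excludes a patient
only from that stratification. Stratification is a pure filter: running
the pipeline on a stratum equals filtering patients first (tested).
Sensitivity cohorts: *stayers* (activity interval overlaps the final
quarter) and *young* (age ≤34 at baseline under the same birthday rule,
so all are <40 at study end, excluding most asthma–COPD overlap).

## Synthetic cohort model

For active patient i in week w the latent episode indicator is
Bernoulli with

    p_iw = 1 − exp(−λ0 · s(w) · g_i · I(w)),
    s(w) = 1 + A·cos(2π (w − w_peak) / 52.1786)

* λ0 — baseline hazard (episodes per patient-week) for a reference
  patient at the seasonal midpoint; default 0.01224, calibrated so the
  cohort-mean pre-pandemic rate is ~66 per 100 patient-years under the
  default strata mix (the published 2016–2019 quarterly rates average
  66.2).
* A = 0.25, peak at ISO week 1 — reproduces the published winter peak
  (~85–89) versus summer trough (~49–54). The period is fixed at
  365.25/7 weeks on a continuous week index so the phase does not drift
  over six simulated years.
* g_i — product of sex, age-band and region effects (defaults: F 1.1 /
  M 0.9; 0-5 1.3, 6-17 0.9, 18-54 0.95, 55+ 1.1; regions 1.0); the mix
  and missingness rates (1.4% sex, 0.1% birth year) follow the published
  cohort. A configuration error names the stratum if the peak weekly
  hazard reaches one expected episode per week.
* I(w) — 1 before the intervention date, then per-quarter multipliers
  indexed from the quarter containing the cutover; defaults
  (0.92, 0.60, 0.53, 0.44, 0.37, 0.42, 0.47) from 2020-03-23 mirror the
  published quarterly reductions (the leading 0.92 covers the one
  pre-existing week of 2020-Q1 after the cutover).
* Attrition is geometric with per-week hazard μ = ln(100362/58776)/299 ≈
  0.00179, matching the published decline from 100,362 to 58,776 patients
  over 299 weeks. Dropout is non-informative: the original sensitivity
  analysis found no systematic difference between stayers and leavers, so
  informative censoring is out of scope.
* Episodes materialise as hospital records with probability 0.118
  (A&E-attendance 70% / admission-plus-asthma-code 30%; the published
  analysis reports the A&E code as most common but no split) or as an OCS
  prescription with a review lagged Uniform{0..14} days. Reviews falling
  after a patient's deregistration are not written (the prescription then
  stays non-qualifying). Registry activity intervals cover follow-up
  only; the cohort-defining asthma codes are historical records dated in
  the 2010–2015 identification window.
* Coding noise: non-qualifying OCS at 0.002 per patient-week, and a
  year-end-week recording dip δ = 0.5 (an episode's records are written
  with probability δ in the last ISO week of each year). No magnitude is
  published for the dip; 0.5 is a flagged guess. A noise OCS landing
  within the review window of a genuine review can create an extra
  ascertained episode — deliberate, realistic miscoding.

At most one latent episode per patient-week, matching the binary outcome
definition exactly (a weekly Bernoulli, not a Poisson count).

**What the generator does not emulate:** correlation between covariates
and dropout, within-patient episode clustering beyond the weekly hazard,
practice-level coding heterogeneity, and the true mixture of Read-code
usage. Passing tests therefore establish that the *estimators* behave
correctly under the assumed data-generating process, not that the process
captures every feature of real primary-care data.

## Calibration studies and problem sizes

* **Oracle equivalence.** On ≤20-patient cohorts over the full 6-year
  follow-up (50 seeds), the vectorised weekly classifier must match a
  day-level brute-force re-derivation of rules (a)–(c) exactly, including
  fixtures with review lags beyond the window (rejection branch) and
  noise prescriptions.
* **Parameter recovery.** 100 cohorts of 20,000 patients with ρ = 0.6
  injected from the first Monday of 2020-Q2. Truth per run is computed
  from the latent expected rates (so it reflects seasonal alignment and
  attrition rather than assuming 100(ρ−1) = −40%); the truth percentage
  change must fall in the Welch 95% CI in ≥90% of runs per quarter, and
  the pooled estimate within 3 points of truth. Truth weekly tables feed
  the estimators directly here; record-level fidelity is covered by the
  oracle study.
* **Interval coverage.** 200 simulated quarters at 2,000 patients with
  A = 0: coverage of the quarterly t-interval must sit in 93–97%. The
  flat-hazard regime is used because the t-interval's nominal level
  applies to exchangeable weekly rates; a within-quarter seasonal trend
  inflates the sample SD and makes the interval conservative by
  construction.
* **Degenerate limits.** A = 0 shows no quarter-position effect (one-way
  ANOVA on pre-period weekly rates); ρ = 0 yields exactly zero
  post-cutover episodes.

Problem sizes (20,000-patient recovery runs, 2,000-patient coverage runs,
300-patient unit fixtures) were chosen so each study resolves its target
tolerance comfortably while the whole suite stays quick to run.

## Known limitations

* The published summary tables are internally inconsistent for quarter
  position 1: the mean of the printed 2016–2019 Q1 rates is 81.0, while
  the printed Q1 differences imply a control near 79.8–79.9 (likely a
  consequence of the non-ISO quarter labelling noted above). The
  consistency checks therefore reproduce Q2 exactly and Q3/Q4 to ≤0.5 per
  100 patient-years, but the Q1 rows disagree by ~1.1–1.2 and the
  corresponding checks fail by design rather than being loosened.
* No formal interrupted-time-series model (segmented regression, ARIMA)
  is fitted; the method is a descriptive control-period contrast, as in
  the original analysis.
* Ethnicity/deprivation stratification and linkage to secondary-care data
  are out of scope (unavailable in the source data).
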