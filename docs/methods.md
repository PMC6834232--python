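# Methods

## Scope and design

The package models a paired screening study: every patient is measured in
one night by a reference device (respiratory polygraphy, whose scored
event list yields the diagnosis) and a candidate screen (a 1 Hz mobile
pulse oximeter, whose only readout is the ODI). The analysis surface is
split into five layers — signal I/O, dip detection/ODI, event-list
scoring, paired agreement statistics, and orchestration — plus a
synthetic-data generator that stands in for patient recordings, which were
never publicly deposited for this design.

## Dip detection and ODI

A dip is a **maximal run of consecutive valid samples with value ≤
baseline − min_drop whose span is ≥ min_duration** (defaults 3 points and
10 s; both bounds inclusive). Maximality makes dips non-overlapping by
construction. Decisions where the printed definition is silent:

* **Termination.** A dip ends as soon as saturation returns above
  `baseline − min_drop`; there is no hysteresis or recovery-to-baseline
  requirement. This is the simplest rule consistent with the definition;
  the thresholds are exposed as parameters for sensitivity analyses.
* **Units.** The "≥3% decrease" is absolute percentage points, the
  standard oximetry convention, not a relative fraction of baseline.
* **Dropouts.** Invalid samples break a run — a dip is never assumed to
  continue through missing data. `bridge_gap_s` (default 0) can bridge
  short dropouts explicitly.
* **Denominator.** ODI divides by total recording span by default;
  `use_valid_time=True` switches to valid (non-dropout) time. The choice
  matters only for artifact-heavy recordings.
* `pct_time_below_90` uses strict `< 90` over valid samples.

Two baseline conventions mirror the two devices: `fixed` (a pre-sleep spot
value) and `eleventh_minute` (mean of valid samples in [600 s, 660 s)).
The eleventh-minute method raises on recordings shorter than 11 minutes or
with an all-invalid window — no silent fallback, because a wrong baseline
silently shifts every dip threshold.

## Diagnosis rules

AHI = scored events / hours of sleep, with sleep time supplied by the
caller (sleep staging is out of scope). Sleep apnea ⟺ AHI ≥ 15/h; CSA ⟺
additionally ≥ 50% of events central (the boundary belongs to CSA), OSA
otherwise. The three labels partition every input. Events carry a binary
central/obstructive mechanism; "mixed" labels in external data are
rejected at read time rather than silently bucketed. Reported percentages
round half-up to integers.

## Agreement statistics

* **2×2 tables.** Screen positive ⟺ ODI ≥ 15 (boundary positive);
  cells: a = ref+/screen+, b = ref−/screen+, c = ref+/screen−, d =
  ref−/screen−.
* **McNemar.** Default is the exact binomial test, two-sided via doubling
  the smaller tail of Binomial(b+c, ½) and capping at 1 — appropriate at
  the small discordance counts this design produces (b+c = 11 in the
  reference cohort). Continuity-corrected and uncorrected chi-square
  variants are available; all three depend only on (b, c), and b = c = 0
  returns p = 1 (no information). Both default variants round to the
  reference cohort's p = .55.
* **Metrics.** Sensitivity a/(a+c), specificity d/(b+d), PPV a/(a+b),
  NPV d/(c+d); a zero denominator yields `None` (undefined), never 0.
* **Sample size.** The conditional normal-approximation formula in the
  README, parameterised by ψ = p01/p10 and p_disc = p01+p10. ψ = 1 is
  rejected (no effect, unbounded n). The formula models the *uncorrected
  asymptotic* statistic: Monte-Carlo simulation (`simulate_mcnemar_power`)
  confirms ≥ 80% power at the returned n for that test, while the exact
  binomial variant — being conservative — lands a few points below nominal
  at the same n (≈ 77% at n = 26 with the default parameters; it reaches
  80% near n = 28). Plan with the asymptotic test in mind or add a margin
  if the exact test will be used.
* **Bland–Altman.** bias = mean(x−y), limits = bias ± 1.96·SD (sample SD,
  n−1). Plot-data export uses the *first measurement* as abscissa against
  the difference — the short-term–reproducibility variant — rather than
  the conventional pairwise mean.
* **Quantiles.** Linear interpolation between order statistics (the
  default of mainstream statistical software).

## Synthetic nights and cohorts

The generator emulates the statistical structure the analysis assumes, not
cardiorespiratory physiology (no loop-gain/chemoreflex model, no
pulse-rate channel, no wake/sleep staging; recording span = sleep span).

* **Event placement.** Central phenotype: one periodic train at the
  Cheyne-Stokes cycle length (default 60 s, ±10% jitter), event count
  drawn Poisson at the configured rate. Obstructive/none: exponential
  inter-arrival with a guard gap so events never merge.
* **Event shape.** Piecewise linear: 10–14 s descent to
  `baseline − depth`, a plateau at the nadir for the event's duration,
  10–14 s recovery. Everything is aligned to whole seconds so an 8 Hz
  night and its 1 Hz decimation contain the same below-threshold runs;
  with noise off, the detected dip count equals the planted event count
  exactly — the anchor the property tests assert.
* **Defaults per phenotype** (chosen as typical for a heart-failure
  screening population): central — 30 events/h, depth 5 pts, plateau 22 s,
  cycle 60 s; obstructive — 25/h, depth 7 pts, 30 s; none — 4/h, depth
  4 pts, 15 s (AHI safely below 15 in expectation). Baseline saturation
  varies 93–97% across cohort patients; nights default to 7 h.
* **Mechanism labels** are applied deterministically (85% central for the
  central phenotype via ceiling, 15% via floor otherwise) so the ≥50% /
  <50% diagnostic rule holds on *every* draw, not only in expectation.
  Events start after the 12th minute, keeping the eleventh-minute baseline
  window clean.
* **Device layer.** Additive Gaussian noise (default σ 0.5 points for the
  app, 0.2 for the polygraph), rounded to the integer percent an oximeter
  reports and clipped to [50, 100]; dropout segments (app only by
  default) arrive at a configurable rate with exponential lengths (mean
  30 s). Depths that would push SpO2 below 50 are clipped and flagged.
  The event plan depends only on (profile, seed), never on sampling rate
  or noise settings, so both devices see one shared night; equal seeds
  reproduce traces bit-for-bit.

**What passing tests do and do not show.** Quantization makes the
shallowest (3-point) events fragile under noise: their plateau sits
exactly at the detection threshold, so device noise splits their runs and
the noisy screen under-counts by roughly 10–25% while essentially never
over-counting — a realistic behavior the suite asserts. Real recordings
add motion artifacts, perfusion loss, oximeter firmware averaging and
sleep/wake ambiguity that the generator does not model; synthetic results
validate the pipeline's correctness, not the clinical operating
characteristics of any particular device.

## Reference-cohort fixture

The packaged per-patient table (`data/study_cohort_synthetic.csv`, SHA-256
verified at load time) is a *reconstruction*: the published study reports
only four marginal 2×2 tables and per-diagnosis counts, not per-patient
data. The fixture is an assignment of 24 patients (8 CSA, 6 OSA, 10 none;
22 with first-night screen data) whose above/below-15 calls reproduce all
four published tables simultaneously, cell for cell — the test suite
asserts this consistency. The numeric ODI values in the file are synthetic
stand-ins; only their side of the 15/h threshold is meaningful. One
published inconsistency is noted here rather than modeled: the prose
quotes a polygraph-screen specificity of 53%, while the corresponding
table implies 9/15 = 60%; the package reports the table-derived value.
Likewise the abstract's "3 (13%)" for the primary-endpoint cell rounds the
table's 14% differently.

## Problem sizes

Default simulations are sized for interactive use: cohorts of 22 patients
at 4–7 h nights, 1000-trace detector/oracle comparisons, 10,000-replicate
power simulations, and exhaustive McNemar enumeration to 20 discordant
pairs. All complete in well under a minute each on one CPU.

## Known limitations

* No apnea-vs-hypopnea discrimination or AASM scoring of raw airflow /
  effort channels: the pipeline consumes already-annotated events.
* No hypopnea detection from oximetry alone, and no emulation of oximeter
  firmware averaging times.
* The AHI denominator is whatever sleep duration the caller supplies; the
  generator equates recording and sleep span, so app-vs-polygraph
  total-sleep-time discrepancies seen with real devices are not modeled.
* Confidence intervals for sensitivity/specificity and ROC analysis over
  thresholds are out of scope.
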