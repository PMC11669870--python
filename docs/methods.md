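# Methods

This note documents the models, estimators and numerical conventions the
package implements, the assumptions behind the synthetic cohorts used to
validate them, and the known limitations of both.

## Data model and conventions

Minute-resolution streams (heart rate in bpm, steps per minute) are stored
as sparse series: a missing minute means *device not worn* and is never
zero-filled for heart rate. Steps behave differently — a worn minute with
no movement records zero — so in the event study missing step minutes on
worn days count as zero steps, while a fully unworn window excludes the
event. All timestamps are naive local clock time, floored to the minute on
ingestion (device exports bucket by minute; whether vendors floor or round
is unknowable, so the convention is fixed and documented here — estimates
near the actuation minute inherit a ±1-min ambiguity either way).
Daylight-saving irregularities are treated as ordinary missing/duplicate
minutes. Medication status (LABA user or not) is a set of inclusive,
non-overlapping date intervals; a reported switch takes effect on its
interval's start date, and dates outside every interval have unknown
status and are excluded from the group comparison.

## Cohort comparison

Patients wearing the device for fewer than 10,080 total minutes (one week
of minutes) are removed before analysis; the threshold is configurable
(25,200 — one week of *hours* expressed in an alternative reading — is
also offered) and every removal is recorded with its reason. The estimator
is patient-first: per person-time segment, the unweighted mean heart rate
per clock hour (hour h covers [h:00, h+1:00)); per group and hour, the
unweighted mean over segment profiles; overall difference, the unweighted
mean of the 24 hourly differences. This deliberately weights each
patient-segment equally rather than each minute, trading efficiency for
robustness to wildly unequal wear time.

Two 95% intervals are reported because the right one depends on the
question. The pooled-minute Welch interval treats minutes as independent;
with millions of minutes it collapses onto the pooled difference and
mostly demonstrates that statistical and clinical significance diverge at
this data volume. The patient-level bootstrap (resampling segments within
group, 200 replicates by default, percentile interval) propagates
between-patient variability and is the honest uncertainty statement; it is
skipped with a warning when a group has fewer than two segments.

## Self-controlled event study

For an actuation at clock minute m on date d, control days are the nearest
≤50 earlier and ≤50 later calendar days with at least one worn heart-rate
minute and zero SABA actuations. The caps are per side and are not topped
up when one side is short. The control reference at relative minute t is
the mean over control days of the heart rate at clock minute m + t,
following the clock into the adjacent calendar date past midnight; a
reference minute backed by fewer than `min_control_days` (default 10)
control-day values is undefined. The activity screen totals steps over
[−60, +60] around the actuation and excludes the event when this total
strictly exceeds the control-day mean + 2 sample SDs (ddof = 1) of the
same clock window; equality keeps the event. Events with no step wear in
the window, or fewer than two step-covered control days (SD undefined),
are excluded for lack of wear. Every actuation is an event; an optional
refractory rule (off by default) can drop actuations within N minutes of a
previously analysed one. Event accounting partitions exactly into
included / excluded-by-steps / no-controls / no-wear.

The difference curve is computed **paired**: at each relative minute, both
the event mean and the control mean are taken over the same set of
surviving events — those with a worn event-day minute *and* a defined
control reference there. The unpaired alternative (each side averaged over
whichever events define it) is biased on real-shaped data: night non-wear
removes circadian-trough observations from the event side only, which in
simulation shifted the whole curve by ≈ +0.25 bpm. Pairing makes the
circadian term cancel within each event and restored a null curve of
≈ −0.03 bpm under a zero-effect generator.

Crossing landmarks are computed on the unsmoothed curve: first pre-event
minute with Δ ≥ threshold (default 5 bpm, the sustained change usually
taken as clinically relevant), value at t = 0, argmax and max, and the
return time defined as one minute past the last post-event exceedance.
Smoothing — `statsmodels` LOWESS, tricube weights, local-linear, no
robustness iterations, span 0.15 of defined minutes — is for display only
and never interpolates undefined minutes into existence. For
maintenance-inhaler actuations (LABA pooled with ICS/LABA) no
reliever-free control-day concept exists, so the event-aligned curve is
reported raw, without control subtraction, and inherits the circadian
confound; it is rendered but not landmark-summarised.

## Synthetic cohort generator

The generator produces the statistical structure the estimators assume,
with defaults chosen once to mimic the study-like regime:

* **Circadian rhythm**: single-harmonic cosinor, mesor 70 bpm, amplitude
  5 bpm, acrophase 15:00. One harmonic gives a broad daytime plateau and
  is analytically checkable.
* **Minute noise**: i.i.d. Gaussian, SD 6 bpm (an AR structure is
  deliberately not modelled; independence keeps closed-form tolerances).
  Values are clipped to [35, 220] bpm, wide enough never to bind under the
  defaults.
* **LABA offset**: +0.8 bpm while a patient is a LABA user — either
  constant or as a 24-slot hour-of-day profile
  (`morning_peak_offset_profile` builds a Gaussian bump, e.g. 3 bpm at
  10 AM). 70% of patients are users by default.
* **Drug-effect kernel**: zero before −onset, linear to (0, 9 bpm), linear
  to (+9 min, 10 bpm), then exponential decay with rate solved so the
  kernel equals the 5 bpm threshold exactly at +138 min
  (λ = ln(2)/129 ≈ 0.005373 min⁻¹). The default is built from
  *crossing* landmarks: the ramp start (−38.25 min) is derived so the
  rising limb passes through (−17 min, 5 bpm) — the threshold crossing is
  the observable, not the ramp start. The pre-actuation ramp lumps
  dyspnea/arousal and pharmacology into one curve because minute-level
  sensor data cannot separate them. No acute maintenance (LABA) kernel is
  injected by default; its magnitude is a free scenario parameter.
* **Reliever use**: two day types. *Lone-event days* carry one spontaneous
  actuation at a minute drawn from a waking-hours intensity with an 8 AM
  bump. *Exercise days* carry a burst of coupled actuations (1 + Poisson,
  mean 2 — the standard two-puff dose — spread over ≤60 min) taken around
  a single step bout spanning ~30 min before the first to ~90 min after
  the last actuation. Day-type probabilities are solved from the overall
  rate (default 0.36/day) and the coupled share (default 0.5), so the
  fraction of actuations with an overlapping bout equals the configured
  coupling probability. Clustering reliever use on exercise days is both
  the realistic pattern and what keeps lone-event windows free of
  neighbouring-kernel contamination; with i.i.d. Poisson events at ~1/day,
  overlapping kernels add a ~2 bpm pedestal to the difference curve and no
  estimator can recover the injected landmarks.
* **Maintenance schedule**: doses at 08:00 and 21:00 ± 30 min, per-dose
  adherence 0.84; ICS for non-LABA users, ICS/LABA for users.
* **Background activity**: 3 bouts/day in 08:00–22:00, lognormal duration
  (median 15 min), Poisson steps at 40–100/min, heart-rate gain 0.2 bpm
  per unit of the trailing 10-min mean step rate — enough to create the
  confounding the step filter must remove.
* **Wear**: hourly blocks kept with probability 1 by day and
  `night_retention` (default 0.690, the closed-form solution for an 18.7%
  night share) between 00:00 and 06:00, plus a charging gap (60–180 min,
  daytime) on ~30% of days. Hourly night blocks rather than whole-night
  Bernoulli keep gaps contiguous while roughly halving the Monte-Carlo
  noise of the realized night share.

Determinism: per-patient generators are spawned from one `SeedSequence`;
equal seeds give bit-identical cohorts.

**What the generator does not emulate** — and hence what passing recovery
tests do not show about real data: between-patient heterogeneity in mesor,
amplitude or drug response; autocorrelated heart-rate noise; non-step
exercise (cycling, weightlifting) invisible to the activity filter;
maintenance-and-reliever therapy (LABA taken as needed); device
measurement bias; informative non-wear beyond the night/charging pattern.

## Recovery experiments and their tolerances

`inhalerhr.studies` packages the validation experiments the acceptance
script and test suite run: offset recovery (40 patients × 60 days, 50
replicates; constant 0.8 bpm and 10 AM-peaked 3 bpm profiles), reliever
landmark recovery (20 patients × 120 days, rate 1.05/day ≈ 2,520
actuations, coupling 0.5, filter on; 10-replicate medians), a zero-effect
null calibration (100 small cohorts; the difference curve must reach 5 bpm
at <1% of defined minutes), an exact minute-for-minute comparison against
a nested-loop brute-force oracle on a small cohort, and the night-share
calibration (20 × 60; binomial tolerance).

A known property of the landmark experiment: the recovered **return time**
runs ~10–20 min above the injected 138-min anchor. Three mechanisms add
up, measured by switching generator components off: (i) the anchor itself
sits exactly at threshold, so the first sub-threshold minute is 139 even
without noise; (ii) the last exceedance of an unsmoothed curve is an
extreme-value statistic — with ≈1,200 surviving events the per-minute
noise is ≈0.25 bpm against a local slope of ≈0.026 bpm/min, giving a
median stretch of ≈+5–10 min (a zero-coupling cohort yields a median
return of ≈143); and (iii) ≈2% of exercise-coupled events pass the
mean + 2 SD screen (their windows look ordinary when the patient's control
days are themselves active), contributing ≈+0.2 bpm near t ≈ 150 and
another ≈+5–10 min. The other four landmarks (pre-crossing, value at
t = 0, peak lag, peak amplitude) are recovered within ±2 bpm / ±5 min.
The value-at-t0 estimate carries a small (−0.2 to −0.4 bpm) downward
selection effect because the filter preferentially keeps low-activity
event windows.

## Numerical choices and degenerate inputs

Ties in the peak search resolve to the earliest minute. Hours or minutes
with no data are NaN (undefined), never zero, and propagate as "absent"
through summaries. A curve undefined at t = 0 is an error for the crossing
summary; absence of any pre- or post-event exceedance reports the
corresponding landmark as absent rather than failing. CSV round-trips are
exact (floats are written at full precision and re-parsed with
round-trip parsing). The sample (n−1) SD is used for step totals;
equality with the mean + 2 SD bound includes the event. Empty cohorts,
event-free patients and single-interval timelines are all legal inputs;
an analysis with zero surviving events raises an error naming the dominant
exclusion reason.
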