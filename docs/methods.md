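# Methods

This note documents the models, parameter choices and numerical
conventions behind `ppgaf`, and what its synthetic studies can and cannot
say about real screening data.

## Rhythm models

All generators produce an `RRSeries`: inter-beat intervals in
milliseconds, clipped to the physiological band 200–3000 ms, with the beat
times as their cumulative sum from t = 0.  Intervals are drawn one beat at
a time until the next beat would fall at or beyond the requested duration
(default 60 s, the length of one app measurement).

**Sinus rhythm.**  `RR(t) = μ + ε + d·sin(2π f t)` with Gaussian
beat-to-beat noise `ε ~ N(0, σ²)` and a sinusoidal respiratory modulation.
Defaults: μ = 800 ms, σ = 30 ms, f = 0.25 Hz, d = 20 ms — a resting adult
with ordinary heart-rate variability and respiratory sinus arrhythmia at
15 breaths/min.

**Atrial fibrillation.**  Intervals i.i.d. as
`refractory + Exponential(μ − refractory)`, truncated to the physiological
band; defaults μ = 750 ms, refractory 350 ms.  This captures the two
statistical properties an RR-variability detector keys on — high
dispersion (CV ≈ 0.5 at defaults) and no serial correlation — without
claiming to model atrioventricular-node physiology.  A fitted point
process would add realism (e.g. weak short-range correlation) that none of
the downstream statistics exploit.

**Atrial flutter.**  Fixed N:1 conduction of an atrial cycle in
180–300 ms: a perfectly regular ventricular response at
`cycle × ratio` ms.  Zero interval variance is the point — it is what
makes flutter invisible to variability-based classifiers.

**Ectopy.**  A premature beat splits a normal interval pair
`(RR₁, RR₂)` into `(prematurity·RR₁, pause)`.  Ventricular ectopics carry
a fully compensatory pause (the pair still sums to RR₁+RR₂: the sinus node
is not reset); atrial ectopics reset the node, so the pause is an ordinary
RR₂ and the pair shortens.  Default prematurity 0.6.  Cohort ectopy counts
per measurement are Poisson with the configured per-minute rate.  The
classifier's false-positive dose-response in ectopy rate is steep: at
defaults, ≥ 2 ectopics/min lifts normalized RMSSD near the 0.10 decision
threshold, and ≥ 4/min trips it almost surely.  Real screening cohorts
should be modelled with low average rates (most subjects ectopy-free), not
a uniform high rate.

## Waveform rendering

Morphology is template-based; only beat *timing* is faithful, because
every downstream decision is made on RR intervals.

* **ECG** (default 250 Hz): per-beat Gaussian mixture for P-QRS-T with the
  R peak exactly at the beat time, QRS span ≈ 90 ms, plus white noise
  (σ = 0.02 of the R amplitude).
* **PPG** (default 30 Hz, phone-camera grade): a smooth gamma-shaped pulse
  (fast systolic upstroke, slow diastolic decay, C∞ at its peak so
  sub-sample interpolation is well-behaved), peak exactly at the beat
  time; baseline wander at 0.15 Hz (10% of pulse amplitude) plus white
  noise.  Pulse width is 50% of the mean RR, **capped at 0.42 s**:
  systolic ejection time in real pulses is roughly rate-independent, so at
  slow rates an uncapped width would produce unphysiologically flat pulse
  tops whose timing no detector could resolve.
* **Artifacts**: a window is overwritten by broadband high-amplitude noise
  (motion), a constant (sensor dropout/flatline), or hard clipping
  (saturation).  The cohort simulator corrupts 60–95% of a recording when
  it corrupts at all, emulating the all-or-nothing quality failures of
  fingertip measurements.

## Beat detection

The ECG detector is the Pan-Tompkins chain: 5–15 Hz band-pass,
differentiation, squaring, 150 ms moving-window integration, dual adaptive
thresholds with running signal/noise peak estimates, a 200 ms refractory
period, 360 ms T-wave slope discrimination, and search-back at 1.66× the
running 8-beat RR average.  Deviations from the 1985 integer-coefficient
design, chosen for arbitrary sampling rates: filters are specified by
response (order-2 Butterworth, applied zero-phase), thresholds are seeded
from the first 2 s of the integrated signal, and the R fiducial is the
band-passed maximum within ±100 ms of the integrated peak, refined by
parabolic interpolation.

The PPG detector (no published counterpart exists for the emulated
pipeline; this is a conventional stand-in) band-passes 0.5–8 Hz, picks
peaks with a 300 ms minimum distance and a relative height floor (30% of
the 75th-percentile peak height, making detection invariant to global
amplitude scaling), then refines the systolic peak on the lightly smoothed
raw signal using the vertex of a 5-point least-squares parabola — at 30 Hz
one sample is 33 ms, so sub-sample refinement is what makes ±20 ms timing
possible at all.

Detector scoring (`match_beats`) pairs detected to true beats greedily
within a tolerance and excludes beats within 0.25 s of the record edges,
the usual convention in QRS benchmarking: a beat whose waveform is
truncated by the boundary carries no recoverable timing.

## Quality filtering

The fielded system used a recurrent neural network whose architecture and
weights were never published; this package substitutes a transparent
rule-based filter with the same contract.  A recording is sufficient iff
detected beats ≥ 30, beat coverage (fraction of the record spanned by
plausible 0.25–2.5 s inter-beat gaps) ≥ 0.7, out-of-band/in-band spectral
power ≤ 0.5 (Welch PSD; bands 0.5–5 vs ≥ 8 Hz for PPG, 1–20 vs ≥ 40 Hz for
ECG), and mean beat-template correlation ≥ 0.4.  Thresholds were
calibrated once on the clean fixture grid and its corrupted variants.
Known limitation: saturation that preserves pulse-flank periodicity can
evade the filter on PPG; motion and flatline artifacts — the modes the
cohort simulator uses — are caught reliably.

## Rhythm classification

Features per measurement (≥ 30 intervals required): normalized RMSSD
(RMSSD/mean RR), Shannon entropy of the RR histogram over 16 equal-width
bins spanning [min RR, max RR] (0·ln 0 := 0; a constant series has zero
entropy), turning-point ratio, mean heart rate.  The call is AF iff
`rmssd_norm > 0.10` **and** `entropy > 0.55·ln 16`.  The AND-rule and
thresholds follow the established RMSSD+entropy family of RR-based AF
detectors; the proprietary algorithm it stands in for disclosed only that
it analyses RR-interval variability, so this is a functional surrogate,
not a reconstruction, and one rule serves both modalities.  No ectopy
filtering is applied by default — deliberately, so the surrogate
reproduces the fielded system's ectopy false positives; an optional
premature-beat filter (drop each interval < 80% of the series median
together with its pause) can be switched on.

## Aggregation and diagnostics

Per subject, insufficient calls are recoded per scenario
(exclude / as-sinus / as-AF) *before* the majority vote; three calls
decide by strict majority, a discordant pair falls to the more severe call
(AF — the conservative resolution in screening; the ordering is
configurable), a single remaining call decides, and a subject with no
usable call is excluded (exclude scenario only).  The recode-then-vote
order is what makes the scenario tables satisfy the exact bookkeeping
identities (e.g. `tp_as_af = tp_exclude + insufficient gold-AF subjects`).

Confidence intervals for all raw proportions are exact Clopper-Pearson
(beta quantiles).  Predictive values at an external prevalence use Bayes'
rule; their approximate CIs propagate the binomial variances of
sensitivity and specificity through the logit (delta method) and are
flagged as approximate — they degenerate at perfect sensitivity or
specificity.  Display rounding follows the conventional mixed precision:
one decimal at participant level, two at measurement level.

## Reference counts and known discrepancies

`ppgaf.study` stores the published validation-study counts.  Two
inconsistencies in the source tables are preserved, not patched: the
single-lead-ECG participant row's negative-side counts do not add up (only
its sensitivity, 90/95, is reproduced), and the prevalence-adjusted PPV
recomputes to ≈ 63.9% against a printed 63% — the implementation reports
the recomputed value.

## Problem sizes and determinism

Monte-Carlo checks in the test suite use 1000 replicate one-minute strips
for distributional properties, a 1000-subject artifact-free cohort (RR
truth fast path, `simulate_cohort(render=False)`) for cohort-level
classifier operating characteristics, and smaller rendered cohorts
(12–60 subjects) for the full waveform pipeline — sizes chosen so the
whole suite runs in well under a minute of simulation time while keeping
binomial error on the 0.95 assertions a few percent or less.  Every
stochastic component takes an explicit integer seed (cohorts derive
per-subject streams from a `SeedSequence`), and identical configuration
yields byte-identical serialized outputs.

## What passing tests do and do not show

The simulator reproduces the *statistical structure* the pipeline relies
on — RR dispersion and serial correlation per rhythm, beat-timing
observability through the two sensor models, all-or-nothing quality
failures — and the documented clinical error modes (flutter false
negatives, ectopy false positives) emerge from the mechanisms, not from
labels.  It does not model optical skin interaction, electrode contact,
pulse-transit physiology, drug effects on AV conduction, pacemaker
rhythms, or the slow heart-rate drifts of real recordings.  Synthetic
accuracies are therefore internal-consistency results for the algorithms,
not forecasts of field performance; the published-count reproductions are
the package's only claims about real patients.
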