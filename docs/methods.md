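# Methods

## The MSDA metric

MSDA (moving standard deviation of acceleration) quantifies physical
activity as the standard deviation of the Euclidean norm of chest-worn
triaxial acceleration over a short sliding window:

    norm_i = sqrt(x_i² + y_i² + z_i²)
    MSDA_t = SD(norm_{t-w+1..t}),   w = 2 s · f_s  (50 samples at 25 Hz)

with x/y/z the vertical, lateral, and anterior/posterior axes in g.  Unlike
step counting, which thresholds discrete gait events, the MSDA is a
continuous measure of trunk oscillation, so it registers non-gait activity
(wheelchair propulsion, transfers, fidgeting) and does not exhibit a floor
at zero for non-ambulatory wearers.

Implementation choices where the definition is underdetermined:

- **Norm.** Euclidean norm; a squared variant (`norm_variant="squared"`)
  exists only for sensitivity analyses.
- **Gravity.** Not removed.  The SD is invariant to the constant component
  within a window, so high-pass filtering would only change behaviour during
  orientation changes, which are themselves activity.
- **Window.** Sliding, right-aligned, stride 1 sample, full windows only
  (the first w−1 positions and any window touching an invalid sample are
  missing).  Stride is configurable; `stride_samples = window` gives
  tumbling windows.
- **SD denominator.** Sample SD (n−1) by default, population SD available.
  At w = 50 the two differ by ~1%, well below between-subject variability.
- **Numerics.** The windowed SD uses cumulative sums of the globally
  mean-centred series; centring keeps the classic sum-of-squares
  cancellation benign at 48 h length (worst-case error ~1e-10 against a
  two-pass oracle on random series).  Negative variances from round-off are
  clamped to zero.

## Minute aggregation and ensemble averaging

Per minute of day (1440 half-open slots, 0-based), the MSDA value is the
mean of window SDs whose window end falls in the minute, and the step value
is the count of detected step events.  A slot is valid when at least 50%
(inclusive, configurable) of a full minute's samples are valid and at least
one window was emitted; partial minutes at recording edges are held to the
same standard.

Multi-day recordings (the measurement protocol records 48 h) are fused by
ensemble averaging: slot-wise means across days, per channel, over the days
with valid data in that slot.  Subjects whose fused profile has ≥ 5% empty
slots are excluded ("measurement error"); the rule is inclusive at the
boundary, so exactly 72/1440 empty slots excludes.  "Measurement error" is
operationalised as the fraction of ensemble slots with no contributing day —
the simplest post-ensemble reading; the 5% rule is applied jointly to both
channels because slot validity is shared.

Per-subject daily summaries: daily MSDA is the mean over contributing
slots; daily steps is the slot sum rescaled by 1440/#contributing slots so
that short gaps (bathing pauses) do not deflate the count.  A gap-free
profile reduces to the plain sum.  These are conventions — a slot sum and a
device register are equally defensible readings — and are documented as
such.

## Step detection

The wearable's pedometer firmware is undisclosed, so the package provides a
transparent stand-in operating on the orientation-free norm: moving-average
smoothing (0.2 s), an adaptive baseline (moving median, 2 s), local maxima
exceeding baseline + 0.1 g, a 0.25 s refractory period, and a bout filter
discarding runs of fewer than 4 peaks spaced ≤ 2 s apart (commercial
pedometers suppress isolated jolts similarly).  All parameters are exposed
so the detector can be deliberately degraded to emulate missed steps in
slow or irregular gait.  For long recordings the baseline median is
evaluated on a 4x-decimated grid — it varies on the scale of seconds, so
the approximation is far below the detection threshold.

Equivalence with any particular commercial step counter cannot be asserted;
the detector is validated against the simulator's ground truth (recall and
precision ≥ 95% at default amplitudes) and against the qualitative
behaviours that matter downstream: cadence-locked impulse trains are counted
near-exactly, bounded wheelchair-propulsion oscillation yields ≈ 0 events.

## Synthetic cohort

The simulator emulates 48-hour chest-worn recordings from a rehabilitation
ward, graded by the six FIM-mobility subgroups (FIM1-4, FIM5-WC, FIM5-walk,
FIM6-WC, FIM6-walk, FIM7; default sizes 94/23/15/19/18/28, 197 subjects).
Each recording is 1 g of gravity on the vertical axis plus Gaussian rest
noise, activity bouts scheduled in waking hours (07:00–21:00), and one
~30 min missing block per day (bathing analog).  Gait bouts superpose
raised-cosine heel-strike transients (width 0.12 s, amplitudes
0.45–0.55 g — chosen as a realistic trunk-level heel-strike transient that
the default detector resolves reliably) at a per-subject cadence plus
anterior/posterior sway; the scheduled step count of a bout is exactly
floor(duration × cadence).  Wheelchair-propulsion bouts superpose bounded
narrowband (0.8–1.2 Hz) amplitude-modulated oscillation on the horizontal
axes: it moves the MSDA through the norm but is bounded, so it cannot cross
the step-detection threshold the way heavy-tailed band-limited Gaussian
noise would.

Between-subject structure, chosen to reproduce the study's qualitative
findings rather than any individual's data:

- a lognormal **activity factor** (σ = 0.4) scales each subject's bout rate
  and (weakly, exponent 0.3) rest noise;
- an independent lognormal **gait propensity** (σ = 0.8) scales the share
  of bouts that are gait.  Decoupling gait from overall activity is what
  produces wheelchair users with mid-range MSDA and exactly zero steps —
  the floor-effect mechanism;
- a small **inactive probability** per subgroup lets a walking-capable
  subject record no gait in the window (their bouts become non-walking
  activity), so zero-step subjects also occur in the walking stratum;
- day-to-day intensity jitter (±10%) makes the two recorded days differ, so
  ensemble averaging is exercised nontrivially.

Subgroup intensity parameters (rest noise, bout rate, impulse and
oscillation amplitudes) are nondecreasing from FIM1-4 to FIM7.  Rest-noise
levels (0.0060–0.0105 g) and bout schedules were calibrated once, by coarse
search, so that median daily MSDA per subgroup lands in the 0.006–0.015
range with a strictly increasing ordering, and median daily steps fall near
70 / 250 / 1300 / 380 / 2800 / 4800 — walking subgroups out-stepping
wheelchair subgroups of equal or higher independence, while MSDA still
orders by independence.  Bout *durations* are mode-dependent (walking
sessions are longer than wheelchair-activity bouts) and are therefore not
part of the monotone intensity grading.

What the simulator does **not** model: biomechanically validated gait
waveforms, sensor bias or orientation drift, posture transitions, tremor,
or any heart-rate channel.  Passing tests on this cohort demonstrate that
the pipeline recovers planted structure (correlations, orderings, floor
effects) — not that the metric's absolute values match any particular
device.

## Validation battery

On the subject-summary table: Spearman rank correlations between daily MSDA
and daily steps (overall and per mobility stratum, each also with zero-step
subjects excluded); Fisher-Pearson skewness g1 = m3/m2^1.5 and Fisher
kurtosis g2 = m4/m2² with plain-n central moments (g2 is non-excess: the
normal reference is 3); Shapiro-Wilk normality (3 ≤ n ≤ 5000); Kruskal-Wallis
across the six subgroups with pairwise two-sided Mann-Whitney U tests,
Bonferroni-multiplied over all 15 pairs and capped at 1; and the floor
effect as the percentage of exactly-zero step counts (exact equality — step
counts are event counts, no epsilon).  Mann-Whitney was chosen as the
pairwise statistic for consistency with the rank-based omnibus test; Dunn's
test would be the main alternative.  All tests are two-sided at α = .05.
Constant inputs make the rank correlation undefined; it is reported as
missing with a warning rather than silently zero.

## Problem sizes

The qualitative-reproduction checks and the acceptance script pool 10
cohort replicates at 0.15× the default subgroup sizes (29 subjects per
replicate, 290 pooled) with 48 h at 25 Hz per subject — the package's
chosen balance between sampling error and simulation cost.  The type-I
error simulation uses 1000 replicates at the full study sizes.  Full-size
cohorts (197 subjects per seed) run with the same code path via
`default_profiles()`.

## Known limitations

- Absolute MSDA levels depend on calibration constants chosen here; only
  orderings, correlation structure, and floor-effect mechanics are
  meaningful comparisons.
- The step detector is a stand-in; its agreement with any commercial
  pedometer is untested by construction.
- The error-exclusion rule assumes the 5% threshold applies to the fused
  profile jointly for both channels; per-channel application would differ
  only when channels had separate validity, which this pipeline does not
  produce.
- Spearman correlations on small strata (< 3 subjects) are omitted with a
  warning rather than extrapolated.
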