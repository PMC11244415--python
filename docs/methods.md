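# Methods

## Signal model and detection

A tap is a short impact: on the axis normal to the tapping surface the
accelerometer sees a sharp transient, followed by quiet baseline until
the next tap. The analysis makes no assumption about the exact waveform
beyond "a dominant unimodal crest per tap"; detection is therefore
formulated in terms of **topographic prominence** — how far a local
maximum rises above the higher of the two lowest points separating it
from larger terrain — rather than absolute amplitude. Prominence is
robust to baseline offsets (gravity projection on the motion axis) and
to amplitude decay across the trial.

**Axis selection.** Per trace, the motion axis is the one with the
largest robust excursion, measured as the spread between the 99th and
1st percentiles (isolated glitch samples are ignored by construction).
Ties break in the fixed order z > y > x, z being the expected motion
axis for the standard dorsal-phalanx mounting. **Polarity** is
mount-dependent (the impact deceleration can register as a negative
spike), so the detector can flip the signal; in `auto` mode the side
with the larger 99th/1st-percentile deviation from the median wins.

**Detection parameters.** Defaults: `min_prominence` 0.5 g,
`min_separation` 0.08 s, smoothing off. 0.5 g is conservative against
broadband sensor noise at the ±8 g/120 Hz operating point while
accepting weak taps; 0.08 s is below the period of the fastest plausible
tapping (~12 taps/s) yet above within-pulse ringing. When two candidates
violate the separation, the higher-prominence one survives (the earlier
one on an exact tie). For noisy traces (SNR around 10) a centred
moving-average of halfwidth 2 samples is recommended; because smoothing
flattens the crest, detection is then two-stage: peaks are located on
the smoothed signal and snapped to the raw-signal argmax within
±halfwidth samples. A practical threshold rule for a known noise level:
place `min_prominence` midway between the smoothed pulse prominence and
the smoothed noise floor (~4 noise standard deviations).

## Single-finger metrics

**Inter-tap times.** ΔT_i = t_{i+1} − t_i, attributed to the time the
interval completes (t_{i+1}). Their sum telescopes exactly to the span
of the tap train — a conservation law the tests assert in exact float
arithmetic.

**Fatigue slope.** Ordinary least squares of ΔT on elapsed execution
time (not tap index: late intervals count by *when* they happen). The
slope has units s/s; +0.01 means each second of tapping lengthens the
inter-tap interval by 10 ms. R² = 1 − SS_res/SS_tot. When the
inter-times are exactly constant, SS_tot = 0 and the ratio is undefined;
the fit then reports slope 0, R² 1 and a `degenerate` flag instead of a
NaN so downstream aggregation stays total. Zero variance in the event
times raises a typed error instead.

**Windowed excursion.** "Excursion" is defined here as crest amplitude
minus the minimum signal value within ± half the local inter-tap
interval of the crest (interior taps use the smaller adjacent interval,
edge taps their single one). This choice is invariant to constant
offsets and captures the full crest-to-trough swing of a biphasic tap
pulse; the bare crest value is available via `use_raw_crest=True`. The
record is partitioned into consecutive 5 s windows (the last may be
shorter; non-overlapping, stride = window); each window's value is the
mean excursion of the taps inside it. Empty windows are omitted, not
zero-filled — zeros would bias the per-trial mean downward. All reported
standard deviations in the package are sample (n−1) estimates.

## Dual-finger metrics

**Pairing.** The per-event statistic SATime_i = |t2_i − t1_i| needs a
correspondence between the two tap trains, which is under-determined
once detections are missed or merged. Two modes:

- `index_aligned` (default): truncate both trains to the shorter length
  and pair i-th with i-th — the straightforward reading of the
  reference procedure, correct while detections are one-to-one;
- `nearest`: the assignment of min(n1, n2) pairs minimising the total
  |Δt| (solved exactly via `linear_sum_assignment`). This is the robust
  choice when offsets are large relative to the tap period or when
  detections drop events; a greedy closest-first heuristic is *not*
  equivalent (it can double the total cost on easy instances), which is
  why the optimal assignment is used.

**Classification.** A simultaneous trial passes iff mean SATime is
*strictly* under the 0.1 s threshold — an experimental bound derived
from what a healthy cohort achieves in the easiest (UniSIM) condition;
boundary cases fail, and the raw mean is always reported so users can
re-threshold. An alternating trial passes iff the mean SATime *exceeds*
the criterion: either the same fixed 0.1 s, or adaptively the
participant's simultaneous mean + std of the same manual condition
(UniALT↔UniSIM, BimALT↔BimSIM). Failure rates are reported unrounded.

## Cohort statistics

**Placement CV.** CV = 100·std/mean of the tap counts over repeated
runs of one sensor placement; scale-invariant, so it compares
placements fairly across participants of different speed.

**Sample Fatigue Percentage.** Per test and finger, the
per-participant slopes are summarised as a Gaussian N(μ, σ) (sample
mean, sample std). SFP = P(X > 0) = 1 − Φ(−μ/σ) estimates the fraction
of the population that fatigues. It is computed from the fitted
Gaussian, not the empirical exceedance fraction (available separately as
`empirical_fatigue_fraction`): the Gaussian version is smooth in the
inputs and comparable across cells of different size. Degenerate σ = 0
is a point mass: SFP is 0 or 1 by the sign of μ, and undefined at μ = 0
(typed error). Aggregation cells with fewer than two participants are
marked absent, never zero-filled.

**Rounding.** Full precision internally; presentation rounding
(`round_to_printed`) snaps binary floats at 1e-9 and rounds decimal
half-up, so a mean of 2-d.p. inputs that lands exactly on a .xx5
boundary rounds the way the printed tables do.

## Synthetic generator

The generator emulates what matters to the pipeline, not finger
biomechanics:

- event times: t_{i+1} = t_i + max(ε, T0 + m·t_i + jitter), with
  jitter ~ N(0, σ_j²) and floor ε = 2·pulse_width (a physical
  minimum-interval limit). The first tap falls at t = T0 and no tap is
  scheduled in the final pulse_width, so every pulse lies wholly inside
  the record. The drift m is the ground-truth fatigue slope (the fitted
  OLS slope converges to m/(1+m) ≈ m, within the ±0.002 recovery
  tolerance for |m| ≤ 0.02);
- waveform: per tap a biphasic raised-cosine pulse — crest +A then
  trough −A/2 over pulse_width — on the z axis, white Gaussian noise on
  all three axes. Any sharp unimodal crest would do for a
  prominence-based detector; this shape is a modelling convenience, not
  a claim about real tap waveforms;
- second finger: per-event offsets, either around a constant δ0
  (simultaneous mode) or around half the realized gap to the next
  first-finger tap (alternate mode — tied to the realized rather than
  the nominal interval so alternation stays physical under drift), both
  with N(0, σ_δ²) jitter. Note |SATime| of a zero-mean-offset
  simultaneous trial has expectation σ_δ·√(2/π) (folded normal), not 0;
  the recovery tests assert against that;
- a single seed fans out through `SeedSequence.spawn` into independent
  timing/offset/noise substreams, so each trace is reproducible alone.

Defaults describe the study conditions: 30 s trials at 120 Hz, ±8 g
full scale, base interval T0 = 0.3 s (its alternation half-period of
0.15 s sits in the 0.14–0.17 s range healthy adults produce in the
alternating conditions), pulse amplitude 2 g, pulse width 0.08 s,
timing jitter 10 ms, offset jitter 10 ms, noise 0.05 g. Experiments
that sweep the drift down to −0.02 s/s use a 0.8 s base interval so the
shrinking intervals stay clear of the ε floor for the whole 30 s.

What the generator does **not** model: waveform variability between
taps, pulse overlap at extreme rates, sensor drift/clipping, cross-axis
leakage of the tap transient, or correlated (non-white) noise. Passing
recovery tests therefore demonstrate the correctness of the measurement
chain on signals with known structure, not performance bounds on real
recordings.

## Problem sizes used in the recovery experiments

Slope recovery averages 200 seeded trials per drift value; SATime
recovery 200 trials per offset-jitter level; detection validation uses
100 trials at SNR 10 plus 50 randomized signals checked against a
definition-level prominence oracle; the SFP closed form is checked
against 10⁶-draw Monte-Carlo simulations on a (μ, σ) grid within 0.002.

## Known limitations

- Index-aligned pairing degrades silently if one detector drops events
  mid-trial; prefer `nearest` when tap counts disagree by more than one.
- The fixed 0.1 s alternation criterion misclassifies genuinely
  alternating tapping faster than ~5 taps/s (half-period under the
  threshold); the adaptive criterion avoids this.
- The 0.1 s simultaneity threshold and the excursion definition are
  analysis conventions; both are configurable, and all raw quantities
  (sa_times, window excursions) are exposed for re-analysis.
- Reader validation requires uniform sampling within 1%; recordings
  with dropped samples must be repaired upstream.
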