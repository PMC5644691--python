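# Methods

This note documents the models, parameter choices and numerical
conventions behind `pwfilter`, and what the synthetic validation does
and does not establish about real recordings.

## Signal model and preprocessing

All processing assumes paired single-channel ECG and PPG sampled
uniformly at a common rate (the package's reference configuration is
2 kHz; anything ≥ ~200 Hz works).  Internally everything is 0-based
sample indices and seconds; milliseconds appear only in reported PTT.

The PPG is conditioned with a 4th-order low-pass Butterworth filter,
cut-off 9 Hz.  Application is zero-phase (forward–backward,
`sosfiltfilt`) by default: landmark *times* feed PTT directly, and a
causal filter's group delay (~tens of ms at these orders) would bias
every PTT by a constant.  The cost is that the effective magnitude
response is |H|², so the gain at the cut-off is 0.5 rather than
1/√2 — irrelevant for timing landmarks.  The flag is switchable
(`FilterSpec.zero_phase`) for pipelines that must mimic causal
processing.  The ECG is not low-pass filtered here; its conditioning
(5–15 Hz band-pass) lives inside R-peak detection.

Derivatives are central finite differences scaled by the sampling
rate, one-sided at the array ends (`np.gradient` semantics); the
second derivative applies the operator twice.  No smoothed derivative
kernels are used: the 9 Hz low-pass has already removed the noise that
such kernels target, and a plain stencil keeps the foot definition
transparent.  Both landmark detection and criteria S5–S7 read the
*same* derivative arrays — one computation, guaranteed consistency.

## Beat delimitation

R-peaks come from a Pan–Tompkins-family detector (band-pass →
derivative → squaring → 150 ms moving-window integration → adaptive
signal/noise thresholds with a refractory period, default 250 ms),
with each detection refined to the raw-ECG maximum within ±25 ms.  The
detector is deliberately pluggable: any strictly increasing index
array can be supplied instead (CLI flag `--rpeaks`), because the
filter's subject is the PPG, not QRS detection.

Each candidate PW is clipped from `round(0.050·fs)` samples after its
R-peak to `round(0.8·meanRR)` samples after it, where `meanRR` is the
*recording-wide* mean R–R interval — deliberately not a per-beat or
sliding value.  For arrhythmic beats the clip can therefore extend
past the next R-peak; criteria S2/S3 then catch the overrun.  Rounding
is nearest-integer, ties half away from zero, for platform-stable
indices.  The last R-peak bounds no beat; such beats are "not
evaluated" and inflate neither the suitable nor the eliminated count.

## Landmarks

The peak is found with an excursion-based local-maximum detector: a
candidate maximum is confirmed once the signal falls more than
`delta = delta_frac × (segment range)` below it; the highest confirmed
maximum wins, the global argmax is the fallback, and all ties break to
the earliest sample.  `delta_frac` defaults to 0.1 — a detector of
this family needs *some* excursion threshold, 10% of the local range
is small enough to keep genuine systolic peaks and large enough to
reject ripple; it is exposed in the configuration.  Note one
consequence of these semantics: the start of the segment is itself
confirmable as a "maximum" when the segment opens on a falling slope,
which is exactly how badly truncated waves end up with a boundary
peak — the criteria stage must see that, so the landmark stage never
hides it.

The foot is the argmax of the second derivative within the clipped
segment.  The search is *not* widened beyond the clip: on distorted
waves the curvature maximum lands on the boundary or the wrong limb,
and the filter's job is to observe those failures, not prevent them.

Landmark indices are invariant to amplitude scaling and constant
offsets of the PPG (argmax-based definitions; the excursion threshold
scales with the range).

## The seven criteria

All inequalities are strict, exactly as the criteria are stated;
boundary equality fails.  Equality is measure-zero on real signals,
so strictness only matters for degenerate segments — a constant
segment is flagged and fails S4 and S6 by construction.  A beat
failing several criteria counts once as eliminated but under each
failed criterion in the tally, so per-criterion counts sum to ≥ the
eliminated count.

One structural observation, verified in the test suite: with
"highest confirmed local maximum" peak semantics, the detected peak
bounds every other segment sample that could become the foot, so a
strict S4 failure (peak below foot) cannot arise through the full
pipeline except in degenerate ties.  S4 still guards direct/imported
landmark paths and degenerate segments, and is fully exercised in
unit and oracle tests; pipeline-level amplitude-collapse artefacts
manifest instead as S1/S5/S7 failures with a boundary peak.

## PTT

`PTT(n) = t_foot(n) − t_Rpeak(n)` in milliseconds.  By clip
construction no PTT can be below 50 ms.  Window averages use
consecutive non-overlapping windows (60/30/5/1 beats are the
conventional sizes); masked averaging excludes unsuitable beats from
each window, empty windows yield NaN (never 0), and a trailing partial
window is emitted flagged rather than dropped, so no data silently
disappears.  The Gil-style range filter keeps PTT in [150, 400] ms
with inclusive boundaries ("below 150 or above 400" read literally as
strict exclusions).

## The synthetic generator

The generator emulates what the pipeline consumes, not cardiovascular
physiology: ECG realism stops at exact R-peak timing (a Mexican-hat
spike), and the PPG beat is a sum of two analytic bumps

    p(u) = (u/2b)² · exp(2 − u/b),  u > 0

a main systolic wave (b = 90 ms, so the peak sits 180 ms after the
onset) plus a dicrotic bump (relative amplitude 0.20, onset 280 ms
after the main onset, b = 80 ms).  The onset u = 0 is analytically
known and annotated as ground truth.  Defaults: 60 s at 2 kHz, 60 bpm
with 2 bpm beat-to-beat jitter, R-peak→onset delay 250 ms (a typical
finger-PPG transit time), additive white noise with σ = 0.005 of the
pulse amplitude on the PPG (rest-condition, medical-grade acquisition)
and 0.01 on the ECG.  The template keeps ≥ 99% of its spectral energy
below 9 Hz, so the low-pass is shape-preserving on clean beats, and
its post-systolic dip exceeds the 10%-range excursion threshold at
every supported heart rate (30–200 bpm config range; the validation
corpus draws 60–80 bpm), which is what guarantees that clean peaks are
always confirmed — the template parameters above were chosen to honour
that clean-beat contract at the fast end of the range.

**Foot-offset calibration.**  The detected foot is a curvature
landmark, not the physiological onset: after the 9 Hz filter rounds
the onset corner, the second-derivative maximum sits a constant
14.5 ms (at 2 kHz, default template) after the true onset.
`calibrated_foot_offset_ms()` measures this constant on a single
noiseless template pulse, and all recovery statements compare detected
PTT against `true_delay + offset`.  Conflating onset and foot would
make recovery tests unfalsifiable; separating them keeps "PTT within
±10 ms" a real claim about detector stability (observed spread on
clean 5-minute records: ≤ ~2 ms).

**Artefact classes.**  Four archetypes of distorted waves, each
parameterized (`ArtefactParams`) so that it *structurally* produces
its failure mode rather than probabilistically — positions scale with
the beat period, amplitudes with the pulse amplitude:

* **A — early/truncated rise** (onset shifted 100 ms before the
  R-peak): the rise completes before the clip window opens; the foot
  lands on the catacrotic limb after the peak.  Fails S1 (and S5/S7).
* **B — amplitude collapse**: the pulse is replaced by a smooth
  monotone decline whose only sharp concave-up feature is a knee at
  0.25 periods.  The foot lands on that knee, giving a nonactual PTT
  of ~190–250 ms — squarely inside the 150–400 ms range-filter band —
  while the falling segment start becomes the confirmed "peak".
  Fails S1/S5/S7.  The decline's unavoidable level-off is spread over
  0.3 periods so its curvature stays ~3× below the knee's, and the
  recovery to baseline fades over 8 beat periods so the residual drift
  slope (< ~1 amp/s) stays below the clean pulse decay slope and does
  not disturb neighbouring beats.
* **C — unrecognizable wave**: a large excursion (6× pulse amplitude)
  rising just before the clip window with a smooth exponential return
  (τ = 150 ms); both landmarks collapse onto the clip boundary.
  Fails S1 and S5/S6.  A pure broadband-noise replacement was
  deliberately not used: smooth filtered noise satisfies all seven
  criteria by chance a few percent of the time, which would make
  per-beat elimination guarantees impossible; the excursion-dropout
  form reproduces the same "landmarks at the segment extremes"
  signature deterministically.
* **D — time-warped wave**: a wide spurious bump (1.2× amplitude,
  σ = 100 ms) at 180 ms precedes a steep rise displaced to 0.55
  periods; the foot (on the late rise) follows the peak (the bump),
  and the nonactual PTT is biased high (> 400 ms).  Fails S1/S7.

Because every class fails at least one criterion by construction, the
validation corpus (6 × 60 s records, heart rate uniform in 60–80 bpm,
artefact beats drawn independently at 15% — the elimination rate of
the hardest recording in the published validation study) yields
sensitivity and specificity at or near 100%.  That is the intended
reading: the synthetic corpus checks the *mechanics* (landmark
placement, criterion logic, masking, bookkeeping) against exact ground
truth.  It does not reproduce the ambiguity of real artefacts — real
distorted waves are not drawn from four parametric archetypes, and
real reference labels come from human judgment with its own
variability (the published comparison against manual elimination
reports 96.3% / 99.3%).  Passing here shows the filter does exactly
what its definition says; it does not bound performance on data whose
distortions straddle the criteria boundaries.

## Numerical conventions and degenerate inputs

* Ties everywhere break to the earliest sample (argmax semantics,
  explicit in the excursion detector), making runs platform-stable.
* Sample-offset rounding: nearest integer, half away from zero.
* Constant segments: degenerate landmarks, S4/S6 fail by construction.
* Undefined metric denominators yield missing values, not exceptions.
* Reported percentages round to one decimal, half away from zero; full
  precision is kept internally.
* Empty averaging windows yield NaN; partial trailing windows are
  flagged, not dropped.
* Sizes used by default test/acceptance runs: 60 s records for the
  corpus (6 records), 120 s for averaging/range-filter comparisons,
  300 s for the clean null — large enough for stable rates (hundreds
  of beats) while keeping a full run in seconds.

## Known limitations

* The criteria judge *detected landmarks*, so a wave whose rise is
  genuinely absent but whose window still contains a well-formed
  curvature maximum on an upward slope can pass — the published study
  saw exactly this in its six false negatives ("no visually
  recognizable beginning").  No extra criteria were added to patch
  this; it is a property of the method.
* ECG quality is out of scope: R-peaks are assumed detectable, and the
  mean R–R interval uses all detected peaks.
* Single-channel PPG only; no repair/interpolation of eliminated
  beats; no physiological modulation (respiration, baroreflex) of the
  synthetic PTT.
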