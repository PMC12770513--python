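# Methods notes

This note documents the models and procedures implemented in `noctomap`,
the choices made where the method description left room, and what the
synthetic test bench does and does not establish.

## Movement detection

The per-segment detector operates on the signal vector magnitude (SVM) of
raw triaxial acceleration, in mg. Design choices:

* **Filter.** 4th-order Butterworth band-pass 0.1–10 Hz applied zero-phase
  (`sosfiltfilt`). Only the band is prescribed by the method; the zero-phase
  realization was chosen because event-locked cardiovascular analysis keys
  on movement onset, and causal filtering would delay onsets by a
  band-dependent group delay.
* **Envelopes.** Extrema are samples where the first derivative changes
  sign (plateaus count once, at their last sample). Extrema are grouped
  into consecutive windows of `group_window = 1.0 s` and only the global
  maximum (minimum) per window is retained; retained extrema are linearly
  interpolated, with constant extension beyond the first/last point, and
  the envelope difference is clipped at 0. The grouping scale is not
  prescribed; 1.0 s smooths intra-burst oscillation (movement content is
  roughly 2–10 Hz) without bridging distinct movements, which are ≥ 0.5 s
  apart by definition. Linear interpolation is monotone and overshoot-free,
  so the difference signal cannot ring above the data.
* **Thresholding.** Maximal intervals with envelope difference ≥ threshold;
  crossings of the same segment closer than 0.5 s (offset to next onset)
  merge *inside* the detector, so the cross-segment merger receives clean
  per-segment lists. Default thresholds: 20 mg (wrists), 15 mg (ankles and
  trunk), the values selected by mean-F1 optimization; no minimum burst
  duration is imposed. `optimize_threshold` re-runs that selection against
  annotation files, breaking ties toward the smaller (more sensitive)
  threshold.
* **Validation metric.** TP/FP/FN by at-least-partial interval overlap;
  F1 = TP/(TP + (FP+FN)/2). Note that with overlap matching a single very
  long detection spanning several annotations counts once; degenerate
  "mega-burst" detections at very low thresholds can therefore score
  deceptively well, which is why threshold selection should use candidate
  grids starting above the noise floor.

## Composite movements and taxonomy

Per-segment bursts connect when they overlap or are separated by < 0.5 s;
composites are the transitive closure (chains collapse), onset/offset are
the first/last crossing of any involved sensor, and magnitude is the sum
over contributing segments of that segment's maximum envelope difference
(a segment contributing several bursts counts its maximum once). Applying
the 0.5 s rule uniformly across segments — not only within a segment — was
chosen deliberately so that "distinct movement" has a single definition;
`merge_gap_s` is configurable, and setting it to 0 recovers strict-overlap
merging.

Classification is a total function on the 31 non-empty segment subsets:
singletons are segmental; the full set is global; subsets of
{both wrists, trunk} with ≥ 2 members are upper-body; likewise ankles/trunk
for lower-body; the remaining 17 subsets are cross-regional.

Postural changes are global movements whose trunk gravity vector (low-pass
< 0.5 Hz) rotates ≥ 30° between 3-s quiet windows placed 1 s before onset
and 1 s after offset; window and guard lengths are package choices (gravity
estimation needs movement-free data, and the method does not specify them).
Upright posture is flagged where the low-passed trunk longitudinal axis
reads below −0.66 g, per the L5 mounting convention (x axis longitudinal);
flagged intervals are excluded from all downstream analyses.

## Sleep scoring

The arm-angle heuristic re-implements the published open-source description
rather than calling that software: per-axis 5-s centred rolling medians,
`angle = atan(z/√(x²+y²))` in degrees, averaged per 5-s epoch anchored at
dSPT start. An epoch is inactive when its angle differs from the previous
epoch by ≤ 5°; maximal inactive runs ≥ 5 min are aS. The inactivity test
uses successive-epoch differences (not deviation from a bout mean), which
makes scoring invariant to any constant angle offset. The cited algorithm
family has variants (median window, angle metric); all constants are
exposed as arguments. Awakenings are maximal aW runs flanked by aS on both
sides, normalized per hour of aS; leading/trailing aW runs do not count.

## Cardiovascular responses

* HR = 60/RR bpm per R-R interval, timestamped at interval end; PWA =
  systolic peak − immediately preceding diastolic foot, timestamped at the
  peak. R-peak and PPG fiducial *detection* is out of scope (pluggable
  inputs; `naive_rpeak_detect` is unvalidated plumbing only).
* Artifact intervals < 10 s: beats replaced by a cubic spline fitted on
  clean beats; ≥ 10 s: marked discarded. Annotations come from CSV files or
  the synthetic injector (the original workflow used a manual GUI).
* Isolation: a movement enters the analysis iff no other movement
  intersects [onset−30 s, offset+30 s] and its −19…+40 s window contains no
  discarded artifact. Pulse-arrival delay between ECG and wrist PPG
  (~0.3 s) is ignored; PWA windows use the same onset clock as HR.
* Windows are interpolated linearly at 1 Hz (no smoothing), baseline is the
  mean over −19…−9 s, and rows are percent change from that baseline, which
  makes them exactly invariant to positive rescaling of the raw series.
* HR peak / PWA trough are the signed max/min over 0…40 s after onset
  (responses begin 1–2 s pre-onset; the pre-onset part shapes the curves
  but not the peak statistic — the search window is configurable, and a
  non-responder can have a negative "peak"). Grand averages are computed
  within subject first, then across subjects, so event-rich subjects do not
  dominate; per-second one-sample t-tests vs 0% use the subject means
  (N = subjects). No multiple-testing correction is applied; per-second
  p-values are reported raw.

## Statistics

Paired comparisons are routed by Shapiro–Wilk on the paired differences at
α = 0.05 (α is a package choice) to a paired t-test or Wilcoxon signed-rank
test; all-zero differences report p = 1. The three mixed models use a
single scalar random intercept per subject, fitted by maximum likelihood
via statsmodels `MixedLM` (REML optional), with a z-test on β1. With the
random-intercept variance pinned at zero the fit reduces exactly to OLS,
which serves as a limit-case check. Whether published correlation values
are marginal Pearson correlations or model-derived is ambiguous, so both
the pooled Pearson r (with p) and the mixed-model slope are emitted, plus
per-subject correlations and the count of individually significant
subjects.

## Synthetic nights

The generator emulates, with ground truth: five accelerometer traces as
unit-gravity orientation plus white sensor noise (default SD 5 mg/axis)
plus oscillatory bursts injected along the gravity axis; R-peaks from an
instantaneous-rate process (baseline 60 bpm, respiratory sinus arrhythmia
1.5%, slow drift 1%); PPG fiducials with template-modulated per-cycle
amplitude (3% beat noise); scripted wake bouts that reorient the
non-dominant wrist (visible to the arm-angle scorer, invisible to the SVM
detector since rotations preserve the norm); postural trunk rotations
(default 45°) during a configurable fraction (0.35) of global events; and
optional upright bouts.

Default study conditions per 8-h night: 150 movements (60 segmental, 15
upper-body, 20 lower-body, 15 cross-regional, 40 global), per-segment
amplitudes log-uniform on 25–400 mg, durations lognormal clipped to
1.5–12 s, a 2:1 second-to-first-half rate ratio, and 20 two-minute wake
bouts (≈ 2.5 awakenings/h, ≈ 90% efficiency). Events are placed on jittered
60-s slots, which guarantees the 30-s isolation criterion by construction;
configs that cannot satisfy it raise.

Two generator choices deserve note. Bursts are frequency-modulated 2–6 Hz
tones under a 0.5-s raised-cosine taper, injected along the gravity axis:
unlike normalized band-limited noise, a unit-amplitude tone has an exact
peak-to-peak, so the filtered-SVM envelope difference equals the configured
amplitude and detector magnitude accuracy is testable. HR/PWA response
templates are piecewise raised-cosine (rise from 2 s pre-onset, HR peak at
+3 s, PWA trough at +4 s, recovery by +40 s / +25 s, optional undershoot):
the zero slope at the extremum matters because beat-to-beat HR is an
interval average — a kinked (piecewise-linear) template would make the
injected peak unrecoverable to within ~slope×RR/2. Response amplitudes
(defaults: HR peak 25% and PWA trough −20% for global movements, graded
down for other categories) are coupled to within-category standardized
log-magnitude (coefficient 0.3) through a shared per-event autonomic gain
(SD 0.15), which induces the expected magnitude–response and HR–PWA
correlations while keeping each category's mean response at its configured
value.

What the generator does *not* emulate: realistic ECG/PPG waveform
morphology (fiducials are synthesized directly), sleep-stage structure,
movement-correlated artifacts, non-stationary noise, periodic limb
movement sequences, or inter-device clock drift beyond a constant offset.
Passing tests therefore demonstrate algorithmic correctness and
end-to-end internal consistency under controlled conditions — not clinical
performance on real recordings.

## Problem sizes and numerical choices

The validation cohort is 9 subjects × 8 h at 100 Hz (the generator's
default conditions); detection performance, response recovery and the
statistical checks in `tests/test_acceptance.py` and
`scripts/acceptance.py` all run at that size. Mixed-model recovery uses
200 replicates of 9 subjects × 50 observations. Envelope interpolation and
beat-to-grid interpolation are linear throughout; ties in threshold
optimization go to the smaller threshold; degenerate inputs (strictly
monotone series, empty segment sets, constant predictors, zero-variance
differences, single subjects) raise or return documented sentinel values
rather than guessing. Tap-burst synchronization detects onsets on a
rectified, 3-sample-averaged > 5 Hz high-passed SVM with a 500 mg
threshold; the rectified moving average is needed because an impulse rung
through a high-pass filter crosses zero between lobes. A single clean burst
per device is assumed (the full multi-tap protocol is out of scope).

## Known limitations

* Sleep scoring inherits the arm-angle heuristic's known tendency to
  overestimate sleep; aW specificity is limited.
* Overlap-based detection scoring is permissive toward long detections
  (see above).
* The mixed models use random intercepts only; random slopes, GEE and
  Bayesian variants are out of scope.
* The pipeline assumes all five accelerometers are present for full
  taxonomy; with missing segments, categories are computed over the
  available set and a warning is logged.
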