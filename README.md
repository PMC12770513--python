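# noctomap

Detection and characterization of body movements during nocturnal sleep and
wakefulness — and of their beat-to-beat heart-rate (HR) and pulse-wave-
amplitude (PWA) correlates — from a wearable multi-sensor array: triaxial
accelerometers on both wrists, both ankles and the lower back, a single-lead
ECG and a PPG sensor.

The package is aimed at sleep/autonomic physiology researchers who want a
scalable alternative to video-polysomnography for quantifying nocturnal
motor activity and its cardiovascular responses. Because no public recording
of this kind is available, `noctomap` ships a first-class synthetic-night
generator with full ground truth, so the entire pipeline is testable and
reproducible without any data download.

## Method

**Movement detection.** Per body segment, the signal vector magnitude of the
raw acceleration, `SVM = sqrt(ax² + ay² + az²)`, is band-pass filtered
(0.1–10 Hz, zero-phase). Local maxima/minima of the filtered SVM are grouped
into 1-s windows, the global extremum per window is retained, and linear
interpolation of the retained extrema yields smooth upper/lower envelopes.
Movements are maximal intervals where the envelope difference exceeds a
per-segment threshold (20 mg wrists, 15 mg ankles/trunk, selected by
maximizing the mean F1-score against manual annotations); intervals closer
than 0.5 s merge. Bursts overlapping across segments (same 0.5 s rule) form
*composite movements* with magnitude = Σ per-segment maximum envelope
difference, classified by segment set into segmental, upper-body, lower-body,
cross-regional and global movements; global movements with ≥ 30° trunk
gravity-vector rotation are postural changes, and intervals with trunk
vertical-axis acceleration below −0.66 g (upright posture) are excluded.

**Sleep scoring.** Each 5-s epoch of the diary-defined sleep period (dSPT) is
scored from the non-dominant wrist via the arm-angle heuristic
(`angle = atan(z/√(x²+y²))` of 5-s rolling medians): runs of ≥ 5 min without
epoch-to-epoch angle changes > 5° are actigraphy-defined sleep (aS), the
rest wakefulness (aW).

**Cardiovascular responses.** HR = 60/RR from R-peak times; PWA = PPG
systolic peak − diastolic foot per cardiac cycle. Artifact intervals < 10 s
are cubic-spline corrected, longer ones discarded. For each *isolated*
movement (no neighbour within 30 s, clean window), beat series are linearly
interpolated at 1 Hz over −19…+40 s around onset and expressed as percent
change from the −19…−9 s baseline. Curves are averaged within, then across
subjects; per-second one-sample t-tests assess deviation from 0%. Per event,
the HR peak (max increase after onset) and PWA trough (max decrease) enter
three random-intercept mixed models, `y_ij = β0 + β1 x_ij + u_j + ε_ij`
(HR peak ~ magnitude, PWA trough ~ magnitude, PWA trough ~ HR peak), with
z-tests on β1, alongside Shapiro–Wilk-routed paired t / Wilcoxon comparisons.

## Worked example

```python
import dataclasses
from noctomap import SimConfig, generate_night
from noctomap.pipeline import PipelineConfig, analyze_night

cfg = SimConfig(duration_h=2.0, seed=11,
                n_events={"segmental": 15, "upper_body": 4, "lower_body": 5,
                          "cross_regional": 4, "global": 10},
                n_wake_bouts=5)
night = generate_night(cfg)
res = analyze_night(night, PipelineConfig(), subject="demo")

m = res["sleep_metrics"]
print(f"sleep efficiency {m.efficiency_pct:.1f}%  "
      f"awakenings {m.awakenings_per_h_aS:.1f}/h of aS")
print(f"{len(res['composites'])} composite movements, "
      f"{len(res['isolated'])} isolated")
ev = res["events"]
g = ev[ev.category == "global"]
print(f"global movements: HR peak {g.hr_peak_pct.mean():+.1f}%  "
      f"PWA trough {g.pwa_trough_pct.mean():+.1f}%")
```

prints

```
sleep efficiency 91.7%  awakenings 2.7/h of aS
56 composite movements, 40 isolated
global movements: HR peak +29.8%  PWA trough -24.0%
```

i.e. this simulated sleeper spent 91.7% of the 2-h sleep period in
actigraphic sleep with 2.7 brief awakenings per hour; 56 movements were
detected and merged across segments, 40 of which were isolated enough for
event-locked analysis; global (whole-body) movements raised HR by ~30% of
the pre-movement baseline and dropped PWA (peripheral vasoconstriction) by
~24% (per-event peak statistics; the grand-average curve peaks lower because
averaging precedes the extremum).

The same pipeline is available from the shell:

```bash
noctomap simulate --out night/ --seed 3
noctomap detect night/ --out bursts.csv
noctomap run --out run/ --seed 7 --subjects 2   # full pipeline + report.md
```

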