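"""Synthetic full-night generator with ground truth for every pipeline stage.

One simulated night comprises:

* five triaxial accelerometer traces (both wrists, both ankles, trunk):
  unit-gravity orientation + white sensor noise + oscillatory movement
  bursts (frequency-modulated 2-6 Hz tone under a tapered window) injected
  along the gravity axis so the band-passed SVM envelope difference matches
  the configured burst amplitude;
* R-peak times drawn from an instantaneous-heart-rate process equal to a
  baseline plus event-locked response templates (plus respiratory sinus
  arrhythmia and slow drift);
* PPG systolic-peak / diastolic-foot fiducials whose per-cycle amplitude
  difference (the PWA) is a baseline modulated by event-locked templates;
* a sleep diary, scripted wake bouts that perturb the non-dominant wrist's
  orientation (visible to the arm-angle sleep scorer but invisible to the
  SVM detector, which only sees the norm), optional upright-posture bouts,
  and postural rotations of the trunk during a fraction of global events.

Everything is driven by a single seed; identical configs and seeds give
bit-identical outputs.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

from .cardio import BeatSeries
from .io_sync import DiaryRecord, Segment, TriaxialRecording, write_recording, write_diary
from .taxonomy import Category


class ConfigError(ValueError):
    """Simulation configuration is internally inconsistent."""


@dataclass
class ResponseTemplate:
    """Smooth event-locked response shape (unit peak).

    Raised-cosine segments: rise from 0 starting ``lead_s`` before movement
    onset to 1 at ``peak_latency_s`` after onset, then decay back to 0 by
    ``end_s`` — optionally through an undershoot of ``-undershoot_frac``
    at ``undershoot_latency_s``. Zero slope at the peak keeps the injected
    peak value recoverable from interval-averaged beat series.
    """

    lead_s: float = 2.0
    peak_latency_s: float = 3.0
    undershoot_frac: float = 0.0
    undershoot_latency_s: float = 10.0
    end_s: float = 40.0

    def __call__(self, tau: np.ndarray) -> np.ndarray:
        tau = np.asarray(tau, dtype=float)
        out = np.zeros_like(tau)
        rise = (tau >= -self.lead_s) & (tau < self.peak_latency_s)
        out[rise] = 0.5 * (1 - np.cos(
            np.pi * (tau[rise] + self.lead_s) / (self.lead_s + self.peak_latency_s)))
        if self.undershoot_frac > 0:
            u, tl = self.undershoot_frac, self.undershoot_latency_s
            fall = (tau >= self.peak_latency_s) & (tau < tl)
            out[fall] = -u + (1 + u) * 0.5 * (1 + np.cos(
                np.pi * (tau[fall] - self.peak_latency_s) / (tl - self.peak_latency_s)))
            rec = (tau >= tl) & (tau < self.end_s)
            out[rec] = -u * 0.5 * (1 + np.cos(
                np.pi * (self.end_s - tau[rec]) / (self.end_s - tl)))
        else:
            fall = (tau >= self.peak_latency_s) & (tau < self.end_s)
            out[fall] = 0.5 * (1 + np.cos(
                np.pi * (tau[fall] - self.peak_latency_s) / (self.end_s - self.peak_latency_s)))
        return out


#: mean HR-peak / PWA-trough response amplitudes (% of baseline) per category
DEFAULT_HR_PEAK_PCT: dict[str, float] = {
    "segmental": 5.4, "upper_body": 17.4, "lower_body": 8.5,
    "cross_regional": 12.1, "global": 25.0,
}
DEFAULT_PWA_TROUGH_PCT: dict[str, float] = {
    "segmental": -5.8, "upper_body": -10.0, "lower_body": -10.0,
    "cross_regional": -12.0, "global": -20.0,
}
DEFAULT_N_EVENTS: dict[str, int] = {
    "segmental": 60, "upper_body": 15, "lower_body": 20,
    "cross_regional": 15, "global": 40,
}

_UPPER_SETS = [{"LW", "RW"}, {"LW", "T"}, {"RW", "T"}, {"LW", "RW", "T"}]
_LOWER_SETS = [{"LA", "RA"}, {"LA", "T"}, {"RA", "T"}, {"LA", "RA", "T"}]
_ALL = {"LW", "RW", "LA", "RA", "T"}
_CROSS_SETS = [s for k in range(2, 5)
               for s in map(set, itertools.combinations(sorted(_ALL), k))
               if s not in _UPPER_SETS and s not in _LOWER_SETS and s != _ALL]


@dataclass
class SimConfig:
    """Study conditions of one synthetic night."""

    duration_h: float = 8.0
    fs: float = 100.0
    seed: int = 0
    baseline_hr_bpm: float = 60.0
    baseline_pwa: float = 1.0
    noise_sd_mg: float = 5.0
    n_events: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_N_EVENTS))
    half_rate_ratio: float = 2.0
    amp_range_mg: tuple[float, float] = (25.0, 400.0)
    duration_range_s: tuple[float, float] = (1.5, 12.0)
    event_slot_s: float = 60.0
    hr_peak_pct: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_HR_PEAK_PCT))
    pwa_trough_pct: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_PWA_TROUGH_PCT))
    hr_template: ResponseTemplate = field(default_factory=ResponseTemplate)
    pwa_template: ResponseTemplate = field(
        default_factory=lambda: ResponseTemplate(lead_s=2.0, peak_latency_s=4.0, end_s=25.0))
    magnitude_coupling: float = 0.3
    shared_gain_sd: float = 0.15
    rsa_pct: float = 1.5
    drift_pct: float = 1.0
    pwa_beat_noise_frac: float = 0.03
    postural_fraction: float = 0.35
    postural_angle_deg: float = 45.0
    n_wake_bouts: int = 20
    wake_bout_min: float = 2.0
    n_upright_bouts: int = 0
    upright_bout_min: float = 5.0
    dominant_hand: str = "right"

    @property
    def duration_s(self) -> float:
        return self.duration_h * 3600.0

    def validate(self) -> None:
        if self.duration_h <= 0 or self.fs <= 0 or self.noise_sd_mg < 0:
            raise ConfigError("durations, rates and noise levels must be positive")
        n_tot = sum(self.n_events.values())
        n_slots = int(self.duration_s / self.event_slot_s) - 2
        if n_tot > n_slots:
            raise ConfigError(
                f"{n_tot} events do not fit {n_slots} isolation-respecting slots; "
                "reduce n_events or duration of isolation")
        max_dur = self.duration_range_s[1]
        if self.event_slot_s - max_dur - 10.0 < 30.0:
            raise ConfigError("event slots too short to guarantee 30 s isolation")


@dataclass
class GroundTruthEvent:
    """One injected movement with its scripted cardiovascular response."""

    onset: float
    offset: float
    segments: frozenset[str]
    amplitude_per_segment: dict[str, float]
    category: str
    is_postural: bool
    hr_response_amplitude: float   # % of baseline HR at the template peak
    pwa_response_amplitude: float  # % of baseline PWA at the template trough

    @property
    def magnitude(self) -> float:
        return float(sum(self.amplitude_per_segment.values()))


@dataclass
class NightDataset:
    config: SimConfig
    recordings: dict[Segment, TriaxialRecording]
    r_peak_times: np.ndarray
    ppg_peak_t: np.ndarray
    ppg_peak_amp: np.ndarray
    ppg_foot_t: np.ndarray
    ppg_foot_amp: np.ndarray
    diary: DiaryRecord
    events: list[GroundTruthEvent]
    wake_bouts: list[tuple[float, float]]
    upright_bouts: list[tuple[float, float]]

    def truth_intervals(self, segment: Segment) -> list[tuple[float, float]]:
        """Ground-truth burst intervals involving ``segment``, time-sorted."""
        return sorted((e.onset, e.offset) for e in self.events
                      if segment.value in e.segments)


def _pick_segments(category: str, rng: np.random.Generator) -> frozenset[str]:
    if category == "segmental":
        return frozenset([rng.choice(sorted(_ALL))])
    if category == "global":
        return frozenset(_ALL)
    pool = {"upper_body": _UPPER_SETS, "lower_body": _LOWER_SETS,
            "cross_regional": _CROSS_SETS}[category]
    return frozenset(pool[rng.integers(len(pool))])


def _place_events(cfg: SimConfig, rng: np.random.Generator) -> list[GroundTruthEvent]:
    slot = cfg.event_slot_s
    T = cfg.duration_s
    slots = np.arange(slot, T - 2 * slot, slot)
    first = slots[slots < T / 2.0]
    second = slots[slots >= T / 2.0]
    first = list(rng.permutation(first))
    second = list(rng.permutation(second))
    events: list[GroundTruthEvent] = []
    r = cfg.half_rate_ratio
    for cat, n in cfg.n_events.items():
        n1 = int(round(n / (1.0 + r)))
        n2 = n - n1
        if n1 > len(first) or n2 > len(second):
            raise ConfigError("not enough event slots in one night half")
        for half, k in ((first, n1), (second, n2)):
            for _ in range(k):
                base = half.pop()
                onset = base + rng.uniform(0.0, 10.0)
                lo, hi = cfg.duration_range_s
                dur = float(np.clip(rng.lognormal(np.log(4.0), 0.5), lo, hi))
                segs = _pick_segments(cat, rng)
                amps = {s: float(np.exp(rng.uniform(*np.log(cfg.amp_range_mg))))
                        for s in segs}
                events.append(GroundTruthEvent(
                    onset=onset, offset=onset + dur, segments=segs,
                    amplitude_per_segment=amps, category=cat,
                    is_postural=False, hr_response_amplitude=0.0,
                    pwa_response_amplitude=0.0))
    events.sort(key=lambda e: e.onset)
    # couple cardiovascular response amplitudes to magnitude (log-magnitude
    # standardized within category, so each category's mean response stays at
    # its configured value) with a shared per-event autonomic gain
    logm = np.log([e.magnitude for e in events])
    z = np.zeros(len(events))
    cats = np.array([e.category for e in events])
    for cat in np.unique(cats):
        m = cats == cat
        sd = logm[m].std()
        z[m] = (logm[m] - logm[m].mean()) / (sd if sd > 0 else 1.0)
    for i, e in enumerate(events):
        gain = max(0.2, 1.0 + cfg.shared_gain_sd * rng.standard_normal())
        scale = gain * (1.0 + cfg.magnitude_coupling * z[i])
        e.hr_response_amplitude = float(np.clip(
            cfg.hr_peak_pct[e.category] * scale, 0.5, 80.0))
        e.pwa_response_amplitude = float(np.clip(
            cfg.pwa_trough_pct[e.category] * scale, -60.0, -0.5))
        if e.category == "global":
            e.is_postural = bool(rng.uniform() < cfg.postural_fraction)
    return events


def _tukey(n: int, taper_samples: int) -> np.ndarray:
    w = np.ones(n)
    k = min(taper_samples, n // 2)
    if k > 0:
        ramp = 0.5 * (1 - np.cos(np.pi * np.arange(k) / k))
        w[:k] = ramp
        w[-k:] = ramp[::-1]
    return w


def _burst_wave(dur: float, fs: float, amp_mg: float,
                rng: np.random.Generator) -> np.ndarray:
    """Oscillatory burst (g): FM tone in 2-6 Hz, peak-to-peak ``amp_mg``."""
    n = max(4, int(round(dur * fs)))
    t = np.arange(n) / fs
    f = rng.uniform(2.0, 6.0)
    phase = rng.uniform(0, 2 * np.pi)
    carrier = np.sin(2 * np.pi * f * t + phase)
    window = _tukey(n, int(0.5 * fs))
    return (amp_mg / 2.0 / 1000.0) * window * carrier


def _orientation_series(n: int, fs: float, base_dir: np.ndarray,
                        changes: Sequence[tuple[float, np.ndarray, float]]) -> np.ndarray:
    """(n, 3) unit gravity directions from a change script.

    Each change is ``(t_start, new_dir, ramp_s)``: the direction blends from
    its current value to ``new_dir`` over ``ramp_s`` seconds (0 = step) and
    stays there. The result is renormalized so the norm is exactly 1 g and
    reorientations are invisible to the SVM.
    """
    dirs = np.tile(base_dir / np.linalg.norm(base_dir), (n, 1))
    for t_start, new_dir, ramp_s in sorted(changes, key=lambda c: c[0]):
        i0 = int(round(t_start * fs))
        if i0 >= n:
            continue
        new_dir = np.asarray(new_dir, float)
        new_dir = new_dir / np.linalg.norm(new_dir)
        i1 = min(n, i0 + max(1, int(round(ramp_s * fs))))
        old = dirs[i0].copy()
        if i1 > i0 + 1:
            w = 0.5 * (1 - np.cos(np.pi * np.arange(i1 - i0) / (i1 - i0 - 1)))
            dirs[i0:i1] = (1 - w)[:, None] * old + w[:, None] * new_dir
        dirs[i1:] = new_dir
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    return dirs


def _elev_dir(elev_deg: float, azim_deg: float) -> np.ndarray:
    e, a = np.radians(elev_deg), np.radians(azim_deg)
    return np.array([np.cos(e) * np.cos(a), np.cos(e) * np.sin(a), np.sin(e)])


def generate_night(cfg: SimConfig) -> NightDataset:
    """Generate one synthetic night. All randomness flows from ``cfg.seed``."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration_s * cfg.fs))
    events = _place_events(cfg, rng)

    # --- scripted wake bouts (non-dominant wrist reorientations) ----------
    diary = DiaryRecord(0.0, cfg.duration_s, cfg.dominant_hand)
    nd_wrist = diary.nondominant_wrist
    wake_bouts: list[tuple[float, float]] = []
    if cfg.n_wake_bouts > 0:
        chunk = cfg.duration_s / cfg.n_wake_bouts
        for k in range(cfg.n_wake_bouts):
            margin = 0.15 * chunk
            start = k * chunk + rng.uniform(margin, chunk - margin
                                            - cfg.wake_bout_min * 60.0)
            wake_bouts.append((start, start + cfg.wake_bout_min * 60.0))

    upright_bouts: list[tuple[float, float]] = []
    if cfg.n_upright_bouts > 0:
        chunk = cfg.duration_s / cfg.n_upright_bouts
        for k in range(cfg.n_upright_bouts):
            start = (k + 0.45) * chunk
            upright_bouts.append((start, start + cfg.upright_bout_min * 60.0))

    # --- accelerometer traces ---------------------------------------------
    recordings: dict[Segment, TriaxialRecording] = {}
    base_elev = {seg: rng.uniform(-40.0, 40.0) for seg in Segment}
    base_azim = {seg: rng.uniform(0.0, 360.0) for seg in Segment}
    # trunk lies flat: longitudinal (x) axis horizontal, gravity on z
    trunk_rest = np.array([0.0, 0.0, 1.0])
    trunk_alt = np.array([0.0,
                          np.sin(np.radians(cfg.postural_angle_deg)),
                          np.cos(np.radians(cfg.postural_angle_deg))])

    for seg in Segment:
        changes: list[tuple[float, np.ndarray, float]] = []
        if seg is Segment.T:
            base_dir = trunk_rest
            flip = False
            for e in events:
                if e.is_postural:
                    flip = not flip
                    target = trunk_alt if flip else trunk_rest
                    changes.append((e.onset + 0.2, target,
                                    max(0.5, e.offset - e.onset - 0.4)))
            for a, b in upright_bouts:
                changes.append((a, np.array([-1.0, 0.0, 0.0]), 2.0))
                changes.append((b, trunk_rest, 2.0))
        else:
            base_dir = _elev_dir(base_elev[seg], base_azim[seg])
            if seg is nd_wrist:
                elev = base_elev[seg]
                for a, b in wake_bouts:
                    for t_ch in np.arange(a, b + 1e-9, 15.0):
                        step = rng.uniform(8.0, 20.0)
                        elev = elev + step if abs(elev + step) < 60 else elev - step
                        changes.append((t_ch, _elev_dir(elev, base_azim[seg]), 0.0))
        dirs = _orientation_series(n, cfg.fs, base_dir, changes)
        acc = dirs.copy()
        # movement bursts along the instantaneous gravity axis
        for e in events:
            if seg.value not in e.segments:
                continue
            i0 = int(round(e.onset * cfg.fs))
            wave = _burst_wave(e.offset - e.onset, cfg.fs,
                               e.amplitude_per_segment[seg.value], rng)
            i1 = min(n, i0 + wave.size)
            acc[i0:i1] += dirs[i0:i1] * wave[: i1 - i0, None]
        acc += rng.normal(0.0, cfg.noise_sd_mg / 1000.0, size=acc.shape)
        recordings[seg] = TriaxialRecording(seg, cfg.fs, 0.0,
                                            acc[:, 0], acc[:, 1], acc[:, 2])

    # --- beat processes ----------------------------------------------------
    dt = 0.05
    tg = np.arange(0.0, cfg.duration_s + dt, dt)
    hr_mod = np.zeros_like(tg)
    pwa_mod = np.zeros_like(tg)
    for e in events:
        lo = max(0, int((e.onset - 25.0) / dt))
        hi = min(tg.size, int((e.onset + 45.0) / dt))
        tau = tg[lo:hi] - e.onset
        hr_mod[lo:hi] += (e.hr_response_amplitude / 100.0) * cfg.hr_template(tau)
        pwa_mod[lo:hi] += (e.pwa_response_amplitude / 100.0) * cfg.pwa_template(tau)
    ph1, ph2 = rng.uniform(0, 2 * np.pi, 2)
    rsa = (cfg.rsa_pct / 100.0) * np.sin(2 * np.pi * 0.25 * tg + ph1) \
        + (cfg.drift_pct / 100.0) * np.sin(2 * np.pi * 0.0013 * tg + ph2)
    hr_inst = cfg.baseline_hr_bpm * (1.0 + hr_mod) * (1.0 + rsa)
    beats = cumulative_trapezoid(hr_inst / 60.0, tg, initial=0.0)
    r_peaks = np.interp(np.arange(1.0, beats[-1]), beats, tg)

    foot_t = r_peaks + 0.25
    peak_t = r_peaks + 0.45
    pwa_at_peak = cfg.baseline_pwa * (1.0 + np.interp(peak_t, tg, pwa_mod))
    pwa_at_peak *= 1.0 + cfg.pwa_beat_noise_frac * rng.standard_normal(peak_t.size)
    foot_amp = 0.2 * cfg.baseline_pwa * np.ones_like(foot_t)
    peak_amp = foot_amp + pwa_at_peak

    return NightDataset(config=cfg, recordings=recordings,
                        r_peak_times=r_peaks,
                        ppg_peak_t=peak_t, ppg_peak_amp=peak_amp,
                        ppg_foot_t=foot_t, ppg_foot_amp=foot_amp,
                        diary=diary, events=events,
                        wake_bouts=wake_bouts, upright_bouts=upright_bouts)


def inject_artifacts(series: BeatSeries, n_short: int, n_long: int,
                     seed: int) -> tuple[BeatSeries, list[tuple[float, float]]]:
    """Corrupt beats in random artifact intervals; return the interval list.

    Short intervals are 3-9 s (below the 10 s spline-correction cut), long
    intervals 12-20 s (discarded downstream). Intervals never overlap.
    """
    rng = np.random.default_rng(seed)
    t0, t1 = series.beat_t[0], series.beat_t[-1]
    durs = list(rng.uniform(3.0, 9.0, n_short)) + list(rng.uniform(12.0, 20.0, n_long))
    total = sum(durs)
    if total >= t1 - t0:
        raise ConfigError("artifact time exceeds series duration")
    intervals: list[tuple[float, float]] = []
    for d in durs:
        for _ in range(1000):
            a = rng.uniform(t0, t1 - d)
            cand = (a, a + d)
            if all(cand[0] > b + 5.0 or cand[1] < aa - 5.0
                   for aa, b in intervals):
                intervals.append(cand)
                break
        else:
            raise ConfigError("could not place non-overlapping artifact intervals")
    v = series.value.copy()
    for a, b in intervals:
        m = (series.beat_t >= a) & (series.beat_t <= b)
        v[m] = v[m] * rng.uniform(1.5, 3.0, m.sum()) + \
            0.5 * np.abs(v[m]).mean() * rng.standard_normal(m.sum())
    out = BeatSeries(kind=series.kind, beat_t=series.beat_t.copy(), value=v)
    return out, sorted(intervals)


# ---------------------------------------------------------------------------
# serialization (matching the io_sync dialects)


def events_to_frame(events: Sequence[GroundTruthEvent]) -> pd.DataFrame:
    return pd.DataFrame([{
        "onset": e.onset, "offset": e.offset,
        "segments": "+".join(sorted(e.segments)),
        "magnitude_mg": e.magnitude, "category": e.category,
        "is_postural": e.is_postural,
        "hr_response_pct": e.hr_response_amplitude,
        "pwa_response_pct": e.pwa_response_amplitude,
    } for e in events])


def write_night(ds: NightDataset, out_dir: str | Path) -> None:
    """Write one night in the CSV/JSON dialects the pipeline reads."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for seg, rec in ds.recordings.items():
        write_recording(rec, out / f"acc_{seg.value}.csv")
    pd.DataFrame({"time": ds.r_peak_times}).to_csv(out / "r_peaks.csv", index=False)
    pd.DataFrame({"peak_t": ds.ppg_peak_t, "peak_amp": ds.ppg_peak_amp,
                  "foot_t": ds.ppg_foot_t, "foot_amp": ds.ppg_foot_amp}
                 ).to_csv(out / "ppg_fiducials.csv", index=False)
    write_diary(ds.diary, out / "diary.json")
    events_to_frame(ds.events).to_csv(out / "ground_truth_events.csv", index=False)
    with open(out / "sim_config.json", "w") as fh:
        cfg = asdict(ds.config)
        json.dump(cfg, fh, indent=1, default=str)
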