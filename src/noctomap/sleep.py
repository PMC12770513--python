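"""Actigraphic sleep/wake scoring from the non-dominant wrist accelerometer.

Implements the arm-angle inactivity heuristic: the arm elevation angle is
estimated from 5-s rolling medians of the raw triaxial acceleration,

    angle = atan( z_med / sqrt(x_med^2 + y_med^2) )  [degrees],

averaged per non-overlapping 5-s epoch. Epochs whose angle differs from the
previous epoch by no more than 5 degrees are inactive; maximal inactive runs
lasting at least 5 minutes are scored as actigraphy-defined sleep (aS), all
other epochs as wakefulness (aW). From the label series we derive aS/aW
durations, sleep efficiency (percent of the diary-defined sleep period spent
in aS) and awakenings — maximal aW runs flanked by aS on both sides —
normalized per hour of aS.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_sync import DiaryRecord, Segment, TriaxialRecording
from .taxonomy import State

EPOCH_S = 5.0
ANGLE_THRESHOLD_DEG = 5.0
MIN_SLEEP_BOUT_S = 300.0


@dataclass
class SleepWakeSeries:
    """Per-epoch aS/aW labels over the diary-defined sleep period."""

    epoch_start: np.ndarray   # absolute seconds, one per epoch
    labels: np.ndarray        # array of "aS"/"aW" strings
    epoch_len: float = EPOCH_S

    def state_at(self, t: float) -> State:
        """Label of the epoch containing time ``t`` (clamped to the series)."""
        i = int(np.clip((t - self.epoch_start[0]) // self.epoch_len,
                        0, len(self.labels) - 1))
        return State(self.labels[i])


@dataclass
class SleepMetrics:
    aS_min: float
    aW_min: float
    dSPT_min: float
    efficiency_pct: float
    awakenings_per_h_aS: float | None
    n_awakenings: int


def arm_angle_epochs(rec: TriaxialRecording, diary: DiaryRecord,
                     epoch_len: float = EPOCH_S,
                     median_window: float = 5.0) -> tuple[np.ndarray, np.ndarray]:
    """Per-epoch arm elevation angle (degrees) over the dSPT.

    Returns ``(epoch_start_times, angles)``. The rolling median length is
    ``median_window`` seconds (centred); the per-sample angle is averaged
    within each consecutive ``epoch_len``-second epoch anchored at dSPT start.
    """
    sub = rec.slice(diary.dspt_start, diary.dspt_end)
    if sub.n < 2:
        raise ValueError("recording does not cover the sleep period")
    w = max(1, int(round(median_window * sub.fs)))
    med = [pd.Series(a).rolling(w, center=True, min_periods=1).median().to_numpy()
           for a in (sub.ax, sub.ay, sub.az)]
    xm, ym, zm = med
    angle = np.degrees(np.arctan2(zm, np.sqrt(xm ** 2 + ym ** 2)))
    per_epoch = int(round(epoch_len * sub.fs))
    n_epochs = int(np.ceil(diary.duration / epoch_len))
    starts = diary.dspt_start + epoch_len * np.arange(n_epochs)
    out = np.full(n_epochs, np.nan)
    for e in range(n_epochs):
        a, b = e * per_epoch, min((e + 1) * per_epoch, sub.n)
        if b > a:
            out[e] = angle[a:b].mean()
    return starts, out


def score_sleep(epoch_start: np.ndarray, angles: np.ndarray,
                angle_threshold: float = ANGLE_THRESHOLD_DEG,
                min_bout: float = MIN_SLEEP_BOUT_S,
                epoch_len: float = EPOCH_S) -> SleepWakeSeries:
    """Score epochs as aS/aW from the arm-angle series.

    An epoch is inactive when its angle differs from the previous epoch's by
    at most ``angle_threshold`` degrees (the first epoch is inactive by
    convention). Maximal inactive runs of at least ``min_bout`` seconds are
    aS; everything else is aW.
    """
    angles = np.asarray(angles, dtype=float)
    if angles.size < 1:
        raise ValueError("empty epoch series")
    d = np.abs(np.diff(angles, prepend=angles[:1]))
    inactive = d <= angle_threshold
    inactive &= ~np.isnan(angles)
    labels = np.full(angles.size, State.AW.value, dtype="<U2")
    min_epochs = int(np.ceil(min_bout / epoch_len))
    i = 0
    while i < inactive.size:
        if inactive[i]:
            j = i
            while j < inactive.size and inactive[j]:
                j += 1
            if j - i >= min_epochs:
                labels[i:j] = State.AS.value
            i = j
        else:
            i += 1
    return SleepWakeSeries(epoch_start=np.asarray(epoch_start, float),
                           labels=labels, epoch_len=epoch_len)


def sleep_metrics(series: SleepWakeSeries) -> SleepMetrics:
    """Durations, efficiency and awakenings/h of aS from the label series."""
    lab = series.labels
    n = lab.size
    e_min = series.epoch_len / 60.0
    aS_min = float(np.sum(lab == State.AS.value)) * e_min
    aW_min = float(np.sum(lab == State.AW.value)) * e_min
    dspt_min = n * e_min
    eff = 100.0 * aS_min / dspt_min if dspt_min > 0 else float("nan")
    # awakenings: maximal aW runs with aS on both sides
    is_w = (lab == State.AW.value).astype(np.int8)
    edges = np.diff(np.r_[0, is_w, 0])
    starts, stops = np.flatnonzero(edges == 1), np.flatnonzero(edges == -1)
    n_awake = sum(1 for a, b in zip(starts, stops) if a > 0 and b < n)
    per_h = (n_awake / (aS_min / 60.0)) if aS_min > 0 else None
    return SleepMetrics(aS_min=aS_min, aW_min=aW_min, dSPT_min=dspt_min,
                        efficiency_pct=eff, awakenings_per_h_aS=per_h,
                        n_awakenings=n_awake)


def score_night(rec: TriaxialRecording, diary: DiaryRecord,
                **kwargs) -> tuple[SleepWakeSeries, SleepMetrics]:
    """Convenience chain: arm angles -> labels -> metrics."""
    starts, ang = arm_angle_epochs(rec, diary)
    series = score_sleep(starts, ang, **kwargs)
    return series, sleep_metrics(series)


def exposure_hours(series: SleepWakeSeries) -> dict[str, float]:
    """Hours spent in dSPT / aS / aW, for movement-index normalization."""
    e_h = series.epoch_len / 3600.0
    return {
        "dSPT": series.labels.size * e_h,
        "aS": float(np.sum(series.labels == State.AS.value)) * e_h,
        "aW": float(np.sum(series.labels == State.AW.value)) * e_h,
    }


def labels_to_frame(series: SleepWakeSeries) -> pd.DataFrame:
    return pd.DataFrame({"epoch_start": series.epoch_start,
                         "label": series.labels})
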