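"""Reading, writing and clock alignment of wearable multi-sensor data.

All devices record on their own clocks. Synchronization relies on a mechanical
tap protocol: each device is tapped against a reference accelerometer, which
produces a sharp, high-amplitude acceleration burst on both units. The abrupt
burst onset serves as a temporal marker; offsets between device clocks are the
differences between paired onset times.

File dialects are deliberately simple and lossless:

* triaxial recordings — CSV with header ``time,x,y,z`` (seconds, g)
* beat series / annotations — CSV
* diary and sync events — JSON
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import signal


class Segment(str, Enum):
    """Instrumented body segments (L/R wrist, L/R ankle, trunk at L5)."""

    LW = "LW"
    RW = "RW"
    LA = "LA"
    RA = "RA"
    T = "T"


SEGMENTS: tuple[Segment, ...] = tuple(Segment)
WRISTS = frozenset({Segment.LW, Segment.RW})
ANKLES = frozenset({Segment.LA, Segment.RA})


class FormatError(ValueError):
    """Input file does not conform to the expected dialect."""


class SyncError(RuntimeError):
    """Tap-burst synchronization could not be established."""


@dataclass
class TriaxialRecording:
    """One body segment's triaxial acceleration on a uniform grid.

    Attributes
    ----------
    segment : Segment
        Body location of the sensor.
    fs : float
        Sampling rate in Hz.
    t0 : float
        Absolute start time in seconds (common clock after alignment).
    ax, ay, az : ndarray
        Acceleration components in g.
    """

    segment: Segment
    fs: float
    t0: float
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray

    def __post_init__(self) -> None:
        self.ax = np.asarray(self.ax, dtype=float)
        self.ay = np.asarray(self.ay, dtype=float)
        self.az = np.asarray(self.az, dtype=float)
        if not (len(self.ax) == len(self.ay) == len(self.az)):
            raise ValueError("axis arrays must have equal length")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n(self) -> int:
        return len(self.ax)

    @property
    def t(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.fs

    @property
    def duration(self) -> float:
        return self.n / self.fs

    def shifted(self, offset: float) -> "TriaxialRecording":
        """Return a copy with the clock shifted by ``offset`` seconds."""
        return TriaxialRecording(self.segment, self.fs, self.t0 + offset,
                                 self.ax.copy(), self.ay.copy(), self.az.copy())

    def slice(self, t_start: float, t_end: float) -> "TriaxialRecording":
        i0 = max(0, int(np.ceil((t_start - self.t0) * self.fs)))
        i1 = min(self.n, int(np.floor((t_end - self.t0) * self.fs)) + 1)
        return TriaxialRecording(self.segment, self.fs, self.t0 + i0 / self.fs,
                                 self.ax[i0:i1], self.ay[i0:i1], self.az[i0:i1])


@dataclass
class DiaryRecord:
    """Diary-defined sleep period (dSPT) and handedness."""

    dspt_start: float
    dspt_end: float
    dominant_hand: str = "right"

    def __post_init__(self) -> None:
        if self.dspt_end <= self.dspt_start:
            raise ValueError("dspt_end must exceed dspt_start")
        if self.dominant_hand not in ("left", "right"):
            raise ValueError("dominant_hand must be 'left' or 'right'")

    @property
    def nondominant_wrist(self) -> Segment:
        return Segment.RW if self.dominant_hand == "left" else Segment.LW

    @property
    def duration(self) -> float:
        return self.dspt_end - self.dspt_start

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.dspt_start + self.dspt_end)


@dataclass
class SyncEvent:
    """Tap-burst onset time on one device's clock."""

    device_id: str
    burst_onset: float


# ---------------------------------------------------------------------------
# recordings


def read_recording(path: str | Path, segment: Segment | str) -> TriaxialRecording:
    """Read a ``time,x,y,z`` CSV recording.

    The sampling rate is inferred from the median time step. Time must be
    strictly increasing; files violating this are rejected rather than
    silently reordered.
    """
    df = pd.read_csv(path)
    missing = {"time", "x", "y", "z"} - set(df.columns)
    if missing:
        raise FormatError(f"missing column(s) {sorted(missing)} in {path}")
    if len(df) < 2:
        raise ValueError(f"recording {path} has fewer than 2 samples")
    t = df["time"].to_numpy(float)
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise FormatError(f"non-monotone time column in {path}")
    fs = 1.0 / float(np.median(dt))
    return TriaxialRecording(Segment(segment), fs, float(t[0]),
                             df["x"].to_numpy(float),
                             df["y"].to_numpy(float),
                             df["z"].to_numpy(float))


def write_recording(rec: TriaxialRecording, path: str | Path) -> None:
    """Write a recording in the ``time,x,y,z`` CSV dialect."""
    df = pd.DataFrame({"time": rec.t, "x": rec.ax, "y": rec.ay, "z": rec.az})
    df.to_csv(path, index=False, float_format="%.9g")


def read_diary(path: str | Path) -> DiaryRecord:
    with open(path) as fh:
        d = json.load(fh)
    return DiaryRecord(float(d["dspt_start"]), float(d["dspt_end"]),
                       d.get("dominant_hand", "right"))


def write_diary(diary: DiaryRecord, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump({"dspt_start": diary.dspt_start, "dspt_end": diary.dspt_end,
                   "dominant_hand": diary.dominant_hand}, fh, indent=1)


def read_intervals(path: str | Path) -> pd.DataFrame:
    """Read an annotation CSV with at least ``onset,offset`` columns."""
    df = pd.read_csv(path)
    if not {"onset", "offset"} <= set(df.columns):
        raise FormatError(f"annotation file {path} needs onset,offset columns")
    return df


def write_intervals(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# tap synchronization


def detect_tap_onset(rec: TriaxialRecording,
                     search_window: tuple[float, float] | None = None,
                     threshold_mg: float = 500.0,
                     min_samples: int = 3,
                     highpass_hz: float = 5.0) -> SyncEvent:
    """Locate the onset of a tap burst in a recording.

    The signal vector magnitude is high-pass filtered (> ``highpass_hz``) to
    remove gravity and rectified; a short moving average over ``min_samples``
    samples bridges the zero crossings of the ringing impulse response. The
    onset is the first sample where this envelope exceeds ``threshold_mg``.

    Raises
    ------
    SyncError
        If no crossing occurs in the search window.
    """
    sub = rec if search_window is None else rec.slice(*search_window)
    if sub.n < 3 * min_samples:
        raise SyncError("search window too short for tap detection")
    svm = np.sqrt(sub.ax ** 2 + sub.ay ** 2 + sub.az ** 2)
    sos = signal.butter(4, highpass_hz, "highpass", fs=sub.fs, output="sos")
    hp = np.abs(signal.sosfiltfilt(sos, svm)) * 1000.0  # mg
    env = np.convolve(hp, np.ones(min_samples) / min_samples, mode="same")
    idx = np.flatnonzero(env >= threshold_mg)
    if idx.size == 0:
        raise SyncError(f"no tap burst above {threshold_mg} mg found")
    onset = sub.t0 + idx[0] / sub.fs
    return SyncEvent(device_id=str(sub.segment.value), burst_onset=onset)


def align_clocks(events: Iterable[SyncEvent],
                 reference_device: str) -> dict[str, float]:
    """Map each device to its clock offset relative to the reference.

    ``offset = reference_onset - device_onset``; adding the offset to a
    device's timestamps moves them onto the reference clock.
    """
    by_dev: dict[str, float] = {}
    for ev in events:
        by_dev[ev.device_id] = ev.burst_onset
    if reference_device not in by_dev:
        raise SyncError(f"reference device {reference_device!r} has no sync event")
    ref = by_dev[reference_device]
    return {dev: ref - onset for dev, onset in by_dev.items()}


def read_sync_events(path: str | Path) -> list[SyncEvent]:
    with open(path) as fh:
        data = json.load(fh)
    return [SyncEvent(d["device_id"], float(d["burst_onset"])) for d in data]


def write_sync_events(events: Iterable[SyncEvent], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump([{"device_id": e.device_id, "burst_onset": e.burst_onset}
                   for e in events], fh, indent=1)
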