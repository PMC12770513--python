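"""Composite movements: merging, topography, posture and summary metrics.

Per-segment bursts that overlap in time — or whose gap is shorter than the
0.5 s distinctness rule — are merged into composite movements. Composites are
classified by the set of involved segments:

* segmental      — a single segment
* global         — both wrists, both ankles and the trunk (whole-body)
* upper_body     — both wrists, or one wrist and the trunk
* lower_body     — both ankles, or one ankle and the trunk
* cross_regional — any other multi-segment combination

Global movements accompanied by a >= 30 degree reorientation of the trunk
accelerometer's gravity vector are flagged as postural changes. Intervals
where the trunk's vertical axis reads below -0.66 g indicate upright posture
(sitting/standing) and are excluded from analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .detection import MovementBurst
from .io_sync import ANKLES, WRISTS, Segment, TriaxialRecording

UPRIGHT_THRESHOLD_G = -0.66
POSTURAL_ANGLE_DEG = 30.0


class Category(str, Enum):
    SEGMENTAL = "segmental"
    GLOBAL = "global"
    UPPER_BODY = "upper_body"
    LOWER_BODY = "lower_body"
    CROSS_REGIONAL = "cross_regional"


class State(str, Enum):
    AS = "aS"   # actigraphy-defined sleep
    AW = "aW"   # actigraphy-defined wakefulness


@dataclass
class CompositeMovement:
    """A merged multi-segment movement.

    ``magnitude`` is the sum over contributing segments of each segment's
    maximum envelope difference within the composite. Onset is the upward
    threshold crossing of the first sensor involved; offset the downward
    crossing of the last.
    """

    segments: frozenset[Segment]
    onset: float
    offset: float
    magnitude: float
    category: Category | None = None
    is_postural: bool | None = None
    state: State | None = None
    night_half: int | None = None  # 1 or 2

    @property
    def duration(self) -> float:
        return self.offset - self.onset


def merge_segments(per_segment: Mapping[Segment, Sequence[MovementBurst]],
                   min_gap: float = 0.5) -> list[CompositeMovement]:
    """Merge per-segment bursts into composite movements.

    Bursts are connected when they overlap in time or are separated by less
    than ``min_gap`` seconds; the transitive closure of this relation defines
    the composites, so chains of pairwise-close bursts collapse into one
    event. Per-segment magnitude contributions are the maximum over that
    segment's bursts in the composite; the composite magnitude is their sum.
    """
    bursts: list[MovementBurst] = []
    for seg, lst in per_segment.items():
        for b in lst:
            if b.segment != seg:
                raise ValueError("burst filed under wrong segment")
            bursts.append(b)
    bursts.sort(key=lambda b: (b.onset, b.offset))
    composites: list[CompositeMovement] = []
    group: list[MovementBurst] = []
    group_end = -np.inf
    for b in bursts + [None]:  # type: ignore[list-item]
        if b is not None and (not group or b.onset - group_end < min_gap):
            group.append(b)
            group_end = max(group_end, b.offset)
            continue
        if group:
            per_seg_mag: dict[Segment, float] = {}
            for g in group:
                per_seg_mag[g.segment] = max(per_seg_mag.get(g.segment, 0.0),
                                             g.magnitude)
            composites.append(CompositeMovement(
                segments=frozenset(per_seg_mag),
                onset=min(g.onset for g in group),
                offset=max(g.offset for g in group),
                magnitude=float(sum(per_seg_mag.values())),
            ))
        if b is not None:
            group = [b]
            group_end = b.offset
    return composites


def classify(segments: frozenset[Segment] | set[Segment]) -> Category:
    """Topographic category of a segment set (total on all 31 subsets)."""
    segs = frozenset(segments)
    if not segs:
        raise ValueError("empty segment set")
    if len(segs) == 1:
        return Category.SEGMENTAL
    if segs == frozenset(Segment):
        return Category.GLOBAL
    wrists = segs & WRISTS
    ankles = segs & ANKLES
    trunk = Segment.T in segs
    if not ankles and (len(wrists) == 2 or (len(wrists) == 1 and trunk)):
        return Category.UPPER_BODY
    if not wrists and (len(ankles) == 2 or (len(ankles) == 1 and trunk)):
        return Category.LOWER_BODY
    return Category.CROSS_REGIONAL


def gravity_vector(trunk: TriaxialRecording, t_start: float, t_end: float,
                   cutoff_hz: float = 0.5) -> np.ndarray:
    """Low-pass gravity estimate averaged over [t_start, t_end]."""
    sub = trunk.slice(t_start - 2.0, t_end + 2.0)
    if sub.n < 8:
        raise ValueError("insufficient trunk data for gravity estimation")
    sos = signal.butter(2, cutoff_hz, "lowpass", fs=sub.fs, output="sos")
    comp = [signal.sosfiltfilt(sos, a) for a in (sub.ax, sub.ay, sub.az)]
    mask = (sub.t >= t_start) & (sub.t <= t_end)
    if not mask.any():
        raise ValueError("window contains no samples")
    return np.array([c[mask].mean() for c in comp])


def angle_between_deg(u: np.ndarray, v: np.ndarray) -> float:
    """Angle between two 3-vectors in degrees."""
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("zero-length gravity vector")
    c = float(np.dot(u, v) / (nu * nv))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def detect_postural_change(mov: CompositeMovement, trunk: TriaxialRecording,
                           angle_deg: float = POSTURAL_ANGLE_DEG,
                           quiet_window: float = 3.0,
                           guard: float = 1.0) -> bool | None:
    """Flag a global movement as a postural change.

    Compares low-passed trunk gravity vectors averaged over ``quiet_window``
    seconds before onset and after offset (with a ``guard`` band around the
    movement); returns ``None`` with a warning when the surrounding data do
    not cover the comparison windows.
    """
    pre = (mov.onset - guard - quiet_window, mov.onset - guard)
    post = (mov.offset + guard, mov.offset + guard + quiet_window)
    t_lo, t_hi = trunk.t0, trunk.t0 + trunk.duration
    if pre[0] < t_lo or post[1] > t_hi:
        warnings.warn("insufficient surrounding data for postural comparison")
        return None
    g_pre = gravity_vector(trunk, *pre)
    g_post = gravity_vector(trunk, *post)
    return angle_between_deg(g_pre, g_post) >= angle_deg


def detect_upright(trunk: TriaxialRecording, axis: str = "x",
                   threshold_g: float = UPRIGHT_THRESHOLD_G,
                   cutoff_hz: float = 0.5) -> list[tuple[float, float]]:
    """Intervals where the trunk's vertical axis reads below ``threshold_g``.

    The vertical axis is the device axis aligned with the body's longitudinal
    axis per the L5 mounting convention (x by default); when the wearer is
    upright, gravity pulls that axis to about -1 g. Detected intervals are
    excluded from all downstream analyses.
    """
    a = {"x": trunk.ax, "y": trunk.ay, "z": trunk.az}[axis]
    sos = signal.butter(2, cutoff_hz, "lowpass", fs=trunk.fs, output="sos")
    lp = signal.sosfiltfilt(sos, a)
    mask = lp < threshold_g
    out: list[tuple[float, float]] = []
    m = mask.astype(np.int8)
    edges = np.diff(np.r_[0, m, 0])
    for a_i, b_i in zip(np.flatnonzero(edges == 1), np.flatnonzero(edges == -1)):
        out.append((trunk.t0 + a_i / trunk.fs, trunk.t0 + (b_i - 1) / trunk.fs))
    return out


def overlaps_any(onset: float, offset: float,
                 intervals: Iterable[tuple[float, float]]) -> bool:
    return any(onset <= b and a <= offset for a, b in intervals)


def annotate(composites: Sequence[CompositeMovement],
             trunk: TriaxialRecording | None,
             state_lookup=None,
             dspt_midpoint: float | None = None,
             upright_intervals: Sequence[tuple[float, float]] = ()) -> list[CompositeMovement]:
    """Classify, posture-flag, state-tag and half-tag composites in place.

    ``state_lookup`` maps an onset time to a :class:`State` (typically the
    sleep scorer's epoch labels). Movements overlapping upright-posture
    intervals are dropped.
    """
    kept: list[CompositeMovement] = []
    for m in composites:
        if overlaps_any(m.onset, m.offset, upright_intervals):
            continue
        m.category = classify(m.segments)
        if m.category is Category.GLOBAL and trunk is not None:
            m.is_postural = detect_postural_change(m, trunk)
        else:
            m.is_postural = False
        if state_lookup is not None:
            m.state = state_lookup(m.onset)
        if dspt_midpoint is not None:
            m.night_half = 1 if m.onset < dspt_midpoint else 2
        kept.append(m)
    return kept


def summarize(composites: Sequence[CompositeMovement],
              exposure_h: Mapping[str, float]) -> pd.DataFrame:
    """Movement index (/h), mean duration (s) and mean magnitude (mg).

    One row per (state, category) plus per-state totals. ``exposure_h`` maps
    "dSPT", "aS", "aW" to hours of exposure; strata with zero exposure are
    reported with missing metrics.
    """
    rows = []
    by_state: dict[str, list[CompositeMovement]] = {"dSPT": list(composites)}
    by_state["aS"] = [m for m in composites if m.state is State.AS]
    by_state["aW"] = [m for m in composites if m.state is State.AW]
    for state, movs in by_state.items():
        hours = exposure_h.get(state, np.nan)
        for cat in list(Category) + [None]:
            sel = movs if cat is None else [m for m in movs if m.category is cat]
            n = len(sel)
            rows.append({
                "state": state,
                "category": "total" if cat is None else cat.value,
                "n": n,
                "index_per_h": n / hours if hours and hours > 0 else np.nan,
                "mean_duration_s": float(np.mean([m.duration for m in sel])) if n else np.nan,
                "mean_magnitude_mg": float(np.mean([m.magnitude for m in sel])) if n else np.nan,
            })
    return pd.DataFrame(rows)


def half_indices(composites: Sequence[CompositeMovement],
                 half_hours: tuple[float, float]) -> pd.DataFrame:
    """Per-category movement index in the first vs second half of the night."""
    rows = []
    for cat in Category:
        for half, hours in zip((1, 2), half_hours):
            n = sum(1 for m in composites
                    if m.category is cat and m.night_half == half)
            rows.append({"category": cat.value, "half": half,
                         "index_per_h": n / hours if hours > 0 else np.nan,
                         "n": n})
    return pd.DataFrame(rows)


_COMPOSITE_COLUMNS = ["onset", "offset", "duration", "segments",
                      "magnitude_mg", "category", "is_postural", "state",
                      "half"]


def composites_to_frame(composites: Sequence[CompositeMovement]) -> pd.DataFrame:
    """Flat table of composites (CSV-friendly)."""
    if not composites:
        return pd.DataFrame(columns=_COMPOSITE_COLUMNS)
    return pd.DataFrame([{
        "onset": m.onset,
        "offset": m.offset,
        "duration": m.duration,
        "segments": "+".join(sorted(s.value for s in m.segments)),
        "magnitude_mg": m.magnitude,
        "category": m.category.value if m.category else "",
        "is_postural": m.is_postural,
        "state": m.state.value if m.state else "",
        "half": m.night_half,
    } for m in composites])
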