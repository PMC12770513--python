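"""Event-locked heart-rate and pulse-wave-amplitude responses to movements.

Beat-to-beat series are built from detector outputs (R-peak times for HR;
PPG systolic-peak / diastolic-foot fiducials for PWA, with PWA = peak - foot
within the same cardiac cycle). Motion-artifact intervals shorter than 10 s
are corrected by cubic-spline interpolation over neighbouring clean beats;
longer intervals are discarded.

Responses are extracted in fixed windows from 19 s before to 40 s after the
onset of each isolated movement (no other movement within 30 s before or
after, and no discarded artifact inside the window), linearly interpolated
at 1 Hz, and expressed as percent change from the pre-movement baseline (the
mean over -19 to -9 s, set at 0%). Curves are averaged within and then
across subjects; per-second one-sample t-tests vs 0% assess deviations from
baseline. Per event, the HR peak (maximum increase after onset) and PWA
trough (maximum decrease after onset) are extracted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.interpolate import CubicSpline

from .taxonomy import CompositeMovement

WINDOW_S = (-19.0, 40.0)
BASELINE_S = (-19.0, -9.0)
ISOLATION_S = 30.0
ARTIFACT_CUT_S = 10.0
GRID = np.arange(WINDOW_S[0], WINDOW_S[1] + 1.0, 1.0)  # 60 points at 1 Hz


class BeatKind(str, Enum):
    HR = "HR"
    PWA = "PWA"


@dataclass
class BeatSeries:
    """Beat-timestamped values with artifact bookkeeping.

    ``artifact_intervals`` holds ``(start, end, action)`` with action either
    ``"interpolated"`` (short, corrected) or ``"discarded"`` (long, unusable).
    """

    kind: BeatKind
    beat_t: np.ndarray
    value: np.ndarray
    artifact_intervals: list[tuple[float, float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.beat_t = np.asarray(self.beat_t, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if self.beat_t.size != self.value.size:
            raise ValueError("beat times and values must align")
        if np.any(np.diff(self.beat_t) <= 0):
            raise ValueError("beat times must be strictly increasing")

    @property
    def discarded_intervals(self) -> list[tuple[float, float]]:
        return [(a, b) for a, b, act in self.artifact_intervals
                if act == "discarded"]


@dataclass
class EventLockedMatrix:
    """events x 60-point grid of percent-change responses plus metadata."""

    kind: BeatKind
    grid: np.ndarray
    rows: np.ndarray                 # shape (n_events, len(grid))
    meta: pd.DataFrame               # one row per event

    @property
    def n_events(self) -> int:
        return self.rows.shape[0]


def hr_from_rpeaks(r_peak_times: np.ndarray) -> BeatSeries:
    """Beat-to-beat heart rate from R-peak times.

    Each R-R interval yields HR = 60/RR bpm, timestamped at the interval end.
    """
    t = np.asarray(r_peak_times, dtype=float)
    if t.size < 2:
        raise ValueError("need at least two R-peaks")
    rr = np.diff(t)
    if np.any(rr <= 0):
        raise ValueError("R-peak times must be strictly increasing")
    return BeatSeries(kind=BeatKind.HR, beat_t=t[1:], value=60.0 / rr)


def pwa_from_fiducials(peak_t: np.ndarray, peak_amp: np.ndarray,
                       foot_t: np.ndarray, foot_amp: np.ndarray) -> BeatSeries:
    """Pulse wave amplitude per cardiac cycle: systolic peak minus the
    immediately preceding diastolic foot, timestamped at the peak.

    Cycles whose peak has no preceding foot (or whose nearest foot belongs to
    an earlier, already-consumed cycle) are skipped.
    """
    peak_t = np.asarray(peak_t, float)
    foot_t = np.asarray(foot_t, float)
    peak_amp = np.asarray(peak_amp, float)
    foot_amp = np.asarray(foot_amp, float)
    times, values = [], []
    skipped = 0
    last_foot = -1
    for pt, pa in zip(peak_t, peak_amp):
        j = np.searchsorted(foot_t, pt) - 1
        if j <= last_foot or j < 0:
            skipped += 1
            continue
        last_foot = j
        times.append(pt)
        values.append(pa - foot_amp[j])
    if skipped:
        import warnings
        warnings.warn(f"{skipped} PPG cycles without a matching foot skipped")
    return BeatSeries(kind=BeatKind.PWA, beat_t=np.array(times),
                      value=np.array(values))


def apply_artifacts(series: BeatSeries,
                    intervals: Sequence[tuple[float, float]],
                    cut_s: float = ARTIFACT_CUT_S) -> BeatSeries:
    """Apply the short-interpolate / long-discard artifact rule.

    Beats inside intervals shorter than ``cut_s`` are replaced by a cubic
    spline fitted on clean beats; intervals of at least ``cut_s`` are marked
    discarded (their beats keep their values but any event window touching
    them is excluded downstream).
    """
    t, v = series.beat_t.copy(), series.value.copy()
    dirty = np.zeros(t.size, dtype=bool)
    actions: list[tuple[float, float, str]] = []
    for a, b in sorted(intervals):
        inside = (t >= a) & (t <= b)
        if b - a < cut_s:
            actions.append((a, b, "interpolated"))
            dirty |= inside
        else:
            actions.append((a, b, "discarded"))
    short_mask = np.zeros(t.size, dtype=bool)
    for a, b, act in actions:
        if act == "interpolated":
            short_mask |= (t >= a) & (t <= b)
    if short_mask.any():
        clean = ~short_mask
        if clean.sum() < 4:
            raise ValueError("too few clean beats for spline correction")
        cs = CubicSpline(t[clean], v[clean])
        v[short_mask] = cs(t[short_mask])
    out = BeatSeries(kind=series.kind, beat_t=t, value=v,
                     artifact_intervals=actions)
    return out


def artifact_fractions(series: BeatSeries) -> dict[str, float]:
    """Fractions of beats interpolated / discarded (diagnostics)."""
    n = series.beat_t.size
    frac = {"interpolated": 0.0, "discarded": 0.0}
    for a, b, act in series.artifact_intervals:
        inside = np.sum((series.beat_t >= a) & (series.beat_t <= b))
        frac[act] += inside / n if n else 0.0
    return frac


def select_isolated(composites: Sequence[CompositeMovement],
                    isolation_s: float = ISOLATION_S,
                    discarded_intervals: Sequence[tuple[float, float]] = (),
                    window: tuple[float, float] = WINDOW_S) -> list[CompositeMovement]:
    """Movements with no neighbour within ``isolation_s`` and a clean window.

    A movement is kept iff no other movement's interval intersects
    [onset - isolation, offset + isolation] and its response window
    [onset + window[0], onset + window[1]] contains no discarded artifact.
    """
    movs = sorted(composites, key=lambda m: m.onset)
    kept = []
    for i, m in enumerate(movs):
        lo, hi = m.onset - isolation_s, m.offset + isolation_s
        crowded = False
        for j in (i - 1, i + 1):
            if 0 <= j < len(movs):
                o = movs[j]
                if o.onset <= hi and lo <= o.offset:
                    crowded = True
        if crowded:
            continue
        w = (m.onset + window[0], m.onset + window[1])
        if any(w[0] <= b and a <= w[1] for a, b in discarded_intervals):
            continue
        kept.append(m)
    return kept


def event_lock(series: BeatSeries, events: Sequence[CompositeMovement],
               window: tuple[float, float] = WINDOW_S,
               baseline: tuple[float, float] = BASELINE_S,
               meta_extra: pd.DataFrame | None = None) -> EventLockedMatrix:
    """Event-locked percent-change matrix on the 1 Hz grid.

    Per event, beat values are linearly interpolated onto the grid; the mean
    over the baseline window is subtracted and the result divided by it,
    giving percent change (baseline = 0%). Events whose baseline window
    contains no beats, or that extend past the series, are dropped.
    """
    grid = np.arange(window[0], window[1] + 1.0, 1.0)
    bmask = (grid >= baseline[0]) & (grid <= baseline[1])
    rows, meta_rows, kept_idx = [], [], []
    for i, m in enumerate(events):
        tt = m.onset + grid
        if tt[0] < series.beat_t[0] or tt[-1] > series.beat_t[-1]:
            continue
        in_base = (series.beat_t >= m.onset + baseline[0]) & \
                  (series.beat_t <= m.onset + baseline[1])
        if not in_base.any():
            continue
        v = np.interp(tt, series.beat_t, series.value)
        b = v[bmask].mean()
        if b == 0:
            continue
        rows.append(100.0 * (v - b) / b)
        meta_rows.append({
            "onset": m.onset,
            "category": m.category.value if m.category else "",
            "state": m.state.value if m.state else "",
            "magnitude_mg": m.magnitude,
        })
        kept_idx.append(i)
    meta = pd.DataFrame(meta_rows)
    if meta_extra is not None and len(meta):
        meta = meta.join(meta_extra.iloc[kept_idx].reset_index(drop=True))
    return EventLockedMatrix(kind=series.kind, grid=grid,
                             rows=np.array(rows).reshape(len(rows), grid.size),
                             meta=meta)


def summarize_response(row: np.ndarray, grid: np.ndarray = GRID,
                       search: tuple[float, float] = (0.0, 40.0)) -> dict[str, float]:
    """Signed HR-peak / PWA-trough statistics of one normalized row.

    ``peak`` is the maximum and ``trough`` the minimum over the post-onset
    search window; both are reported signed (a non-responder may have a
    negative peak), with latencies at the arg-extremum.
    """
    m = (grid >= search[0]) & (grid <= search[1])
    seg, tt = row[m], grid[m]
    i_max, i_min = int(np.argmax(seg)), int(np.argmin(seg))
    return {"peak_pct": float(seg[i_max]), "peak_latency_s": float(tt[i_max]),
            "trough_pct": float(seg[i_min]), "trough_latency_s": float(tt[i_min])}


def response_table(matrix: EventLockedMatrix,
                   search: tuple[float, float] = (0.0, 40.0)) -> pd.DataFrame:
    """Per-event response summary joined with event metadata."""
    recs = [summarize_response(r, matrix.grid, search) for r in matrix.rows]
    return pd.concat([matrix.meta.reset_index(drop=True),
                      pd.DataFrame(recs)], axis=1)


def grand_average(matrix: EventLockedMatrix,
                  subject_col: str = "subject") -> pd.DataFrame:
    """Grand-average curve with SEM and per-second one-sample t-tests.

    Curves are first averaged within subjects and then across subjects
    (N = number of subjects), so subjects with many events do not dominate.
    Requires at least two subjects; the per-time-point t-test is of the
    subject means against 0%.
    """
    if subject_col not in matrix.meta.columns:
        raise ValueError(f"metadata lacks a {subject_col!r} column")
    subjects = matrix.meta[subject_col].to_numpy()
    uniq = np.unique(subjects)
    if uniq.size < 2:
        raise ValueError("grand average requires at least two subjects")
    per_subj = np.vstack([matrix.rows[subjects == s].mean(axis=0) for s in uniq])
    mean = per_subj.mean(axis=0)
    sem = per_subj.std(axis=0, ddof=1) / np.sqrt(uniq.size)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat, pval = sps.ttest_1samp(per_subj, 0.0, axis=0)
    return pd.DataFrame({"t": matrix.grid, "mean_pct": mean, "sem_pct": sem,
                         "t_stat": tstat, "p": pval,
                         "n_subjects": uniq.size})


def naive_rpeak_detect(ecg: np.ndarray, fs: float,
                       min_rr_s: float = 0.3) -> np.ndarray:
    """Naive local-maximum R-peak fallback (plumbing only).

    Dedicated detectors (e.g. the Neurokit family) are the intended source
    of R-peak times; this fallback thresholds the signal at mean + 2 SD and
    keeps local maxima separated by at least ``min_rr_s``. It is not
    validated against clinical ECG.
    """
    from scipy.signal import find_peaks
    ecg = np.asarray(ecg, float)
    height = ecg.mean() + 2.0 * ecg.std()
    idx, _ = find_peaks(ecg, height=height, distance=int(min_rr_s * fs))
    return idx / fs
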