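"""Movement-burst detection from the acceleration signal vector magnitude.

The detector works per body segment:

1. ``compute_svm`` — Euclidean norm of the three acceleration axes
   (ACC_SVM = sqrt(ax^2 + ay^2 + az^2)), in mg.
2. ``bandpass`` — zero-phase 0.1–10 Hz band-pass, removing the gravity DC
   component and high-frequency noise.
3. ``extract_envelopes`` — local extrema of the filtered SVM are grouped into
   fixed windows; the global maximum (minimum) per window is retained and
   linearly interpolated to form a smooth upper (lower) envelope.
4. ``detect_bursts`` — maximal intervals where the envelope difference stays
   at or above a per-segment threshold; intervals separated by less than
   0.5 s are merged into one burst.

Thresholds (20 mg wrists, 15 mg ankles/trunk by default) can be optimized
against manual annotations by maximizing the mean F1-score across subjects.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import signal

from .io_sync import Segment, TriaxialRecording

#: per-segment detection thresholds in mg selected by mean-F1 optimization
DEFAULT_THRESHOLDS_MG: dict[Segment, float] = {
    Segment.LW: 20.0, Segment.RW: 20.0,
    Segment.LA: 15.0, Segment.RA: 15.0,
    Segment.T: 15.0,
}

#: minimum separation between distinct movements of the same segment
MERGE_GAP_S = 0.5


@dataclass
class SvmSeries:
    """Signal vector magnitude on a uniform time grid (mg)."""

    t: np.ndarray
    v: np.ndarray
    fs: float
    filtered: bool = False

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.t.shape != self.v.shape:
            raise ValueError("t and v must have the same shape")


@dataclass
class EnvelopePair:
    """Upper/lower envelopes of the filtered SVM and their difference (mg)."""

    t: np.ndarray
    upper: np.ndarray
    lower: np.ndarray
    fs: float

    @property
    def diff(self) -> np.ndarray:
        return np.clip(self.upper - self.lower, 0.0, None)


@dataclass
class MovementBurst:
    """A detected per-segment movement burst.

    ``magnitude`` is the maximum envelope difference inside the burst, the
    per-segment movement magnitude measure used throughout the pipeline.
    """

    segment: Segment
    onset: float
    offset: float
    magnitude: float

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass
class DetectionMetrics:
    """Validation metrics of detected against annotated movements."""

    tp: int
    fp: int
    fn: int

    @property
    def sensitivity(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else float("nan")

    @property
    def precision(self) -> float:
        d = self.tp + self.fp
        return self.tp / d if d else float("nan")

    @property
    def f1(self) -> float:
        d = self.tp + (self.fp + self.fn) / 2.0
        return self.tp / d if d else float("nan")


def compute_svm(rec: TriaxialRecording) -> SvmSeries:
    """Signal vector magnitude of the raw triaxial acceleration, in mg."""
    v = np.sqrt(rec.ax ** 2 + rec.ay ** 2 + rec.az ** 2) * 1000.0
    return SvmSeries(t=rec.t, v=v, fs=rec.fs, filtered=False)


def bandpass(svm: SvmSeries, low: float = 0.1, high: float = 10.0,
             order: int = 4) -> SvmSeries:
    """Zero-phase Butterworth band-pass of the SVM series.

    Zero-phase (forward-backward) filtering preserves burst onset timing,
    which matters because cardiovascular responses are onset-locked.
    """
    if svm.fs <= 2.0 * high:
        raise ValueError(f"sampling rate {svm.fs} Hz too low for {high} Hz band edge")
    sos = signal.butter(order, [low, high], "bandpass", fs=svm.fs, output="sos")
    return SvmSeries(t=svm.t, v=signal.sosfiltfilt(sos, svm.v), fs=svm.fs,
                     filtered=True)


def _window_extrema(idx: np.ndarray, val: np.ndarray, win: np.ndarray,
                    take_max: bool) -> np.ndarray:
    """Indices of the per-window global extremum among candidate extrema."""
    if idx.size == 0:
        return idx
    # sort by (window, value); the last entry of each window group is its max
    key = val if take_max else -val
    order = np.lexsort((key, win))
    win_sorted = win[order]
    last = np.r_[win_sorted[1:] != win_sorted[:-1], True]
    return np.sort(idx[order[last]])


def extract_envelopes(svm: SvmSeries, group_window: float = 1.0) -> EnvelopePair:
    """Noise-robust upper/lower envelopes of a filtered SVM series.

    Local maxima (minima) are samples where the first derivative changes
    sign from positive to negative (negative to positive). Extrema are
    grouped into consecutive ``group_window``-second windows and only the
    global extremum per window is kept; retained extrema are linearly
    interpolated over the full grid, with constant extension beyond the
    first/last retained point.
    """
    v = svm.v
    n = v.size
    if n < 3:
        raise ValueError("series too short for envelope extraction")
    s = np.sign(np.diff(v))
    # carry the sign of the previous nonzero step through flat stretches so a
    # plateau counts as a single extremum
    flat = s == 0
    if flat.any():
        idx_nz = np.where(~flat, np.arange(s.size), -1)
        np.maximum.accumulate(idx_nz, out=idx_nz)
        s = np.where(idx_nz >= 0, s[np.clip(idx_nz, 0, None)], 0.0)
    interior = np.arange(1, n - 1)
    maxima = interior[(s[interior - 1] > 0) & (s[interior] < 0)]
    minima = interior[(s[interior - 1] < 0) & (s[interior] > 0)]

    nwin = max(1, int(np.ceil(n / (group_window * svm.fs))))
    win_of = lambda i: np.minimum((i / (group_window * svm.fs)).astype(int), nwin - 1)
    maxima = _window_extrema(maxima, v[maxima], win_of(maxima), take_max=True)
    minima = _window_extrema(minima, v[minima], win_of(minima), take_max=False)

    grid = np.arange(n, dtype=float)
    if maxima.size == 0 or minima.size == 0:
        # strictly monotone or constant signal: envelopes hug the data range
        upper = np.full(n, v.max())
        lower = np.full(n, v.min())
    else:
        upper = np.interp(grid, maxima.astype(float), v[maxima])
        lower = np.interp(grid, minima.astype(float), v[minima])
    return EnvelopePair(t=svm.t, upper=upper, lower=lower, fs=svm.fs)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index runs of True in a boolean mask."""
    if mask.size == 0:
        return []
    m = mask.astype(np.int8)
    edges = np.diff(np.r_[0, m, 0])
    starts = np.flatnonzero(edges == 1)
    stops = np.flatnonzero(edges == -1)
    return list(zip(starts, stops))


def detect_bursts(env: EnvelopePair, threshold_mg: float,
                  segment: Segment | None = None,
                  merge_gap: float = MERGE_GAP_S) -> list[MovementBurst]:
    """Threshold-crossing burst detection on the envelope difference.

    Returns maximal intervals where ``diff >= threshold_mg``; intervals of the
    same segment closer than ``merge_gap`` seconds (offset to next onset) are
    merged into a single burst before output.
    """
    if threshold_mg <= 0:
        raise ValueError("threshold must be positive")
    seg = segment if segment is not None else Segment.T
    diff = env.diff
    runs = _runs(diff >= threshold_mg)
    if not runs:
        return []
    merged: list[list[int]] = [list(runs[0])]
    gap_samples = merge_gap * env.fs
    for a, b in runs[1:]:
        if a - merged[-1][1] < gap_samples:
            merged[-1][1] = b
        else:
            merged.append([a, b])
    t0, fs = env.t[0], env.fs
    out = []
    for a, b in merged:
        out.append(MovementBurst(segment=seg,
                                 onset=t0 + a / fs,
                                 offset=t0 + (b - 1) / fs,
                                 magnitude=float(diff[a:b].max())))
    return out


def detect_segment(rec: TriaxialRecording,
                   threshold_mg: float | None = None,
                   band: tuple[float, float] = (0.1, 10.0),
                   group_window: float = 1.0,
                   merge_gap: float = MERGE_GAP_S) -> list[MovementBurst]:
    """Full per-segment chain: SVM → band-pass → envelopes → bursts."""
    if threshold_mg is None:
        threshold_mg = DEFAULT_THRESHOLDS_MG[rec.segment]
    env = extract_envelopes(bandpass(compute_svm(rec), *band), group_window)
    return detect_bursts(env, threshold_mg, segment=rec.segment,
                         merge_gap=merge_gap)


def _check_sorted_disjoint(intervals: Sequence[tuple[float, float]],
                           name: str) -> None:
    for i in range(1, len(intervals)):
        if intervals[i][0] < intervals[i - 1][1]:
            raise ValueError(f"{name} intervals overlap or are unsorted")


def match_and_score(detected: Sequence[tuple[float, float]],
                    annotated: Sequence[tuple[float, float]]) -> DetectionMetrics:
    """Score detections by at-least-partial overlap with annotations.

    TP: detected intervals overlapping >= 1 annotation; FP: detected with no
    overlap; FN: annotations with no overlapping detection. Both lists must
    be time-sorted and internally non-overlapping.
    """
    detected = [(float(a), float(b)) for a, b in detected]
    annotated = [(float(a), float(b)) for a, b in annotated]
    _check_sorted_disjoint(detected, "detected")
    _check_sorted_disjoint(annotated, "annotated")

    def overlaps(x: tuple[float, float], y: tuple[float, float]) -> bool:
        return x[0] <= y[1] and y[0] <= x[1]

    ann_hit = [False] * len(annotated)
    tp = fp = 0
    j = 0
    for d in detected:
        # advance past annotations that end before this detection starts
        while j < len(annotated) and annotated[j][1] < d[0]:
            j += 1
        hit = False
        k = j
        while k < len(annotated) and annotated[k][0] <= d[1]:
            if overlaps(d, annotated[k]):
                hit = True
                ann_hit[k] = True
            k += 1
        if hit:
            tp += 1
        else:
            fp += 1
    fn = ann_hit.count(False)
    return DetectionMetrics(tp=tp, fp=fp, fn=fn)


def optimize_threshold(candidates: Sequence[float],
                       subjects: Sequence[Mapping[str, object]],
                       group_window: float = 1.0,
                       merge_gap: float = MERGE_GAP_S) -> float:
    """Select the candidate threshold maximizing mean F1 across subjects.

    ``subjects`` is a sequence of mappings with keys ``envelope``
    (:class:`EnvelopePair`) and ``annotations`` (list of (onset, offset)).
    Ties are broken toward the smaller threshold.
    """
    if not candidates:
        raise ValueError("no candidate thresholds")
    if not subjects:
        raise ValueError("no subjects")
    table = mean_f1_table(candidates, subjects, merge_gap=merge_gap)
    best = max(sorted(table), key=lambda thr: (table[thr], -thr))
    return best


def mean_f1_table(candidates: Sequence[float],
                  subjects: Sequence[Mapping[str, object]],
                  merge_gap: float = MERGE_GAP_S) -> dict[float, float]:
    """Mean F1 across subjects for each candidate threshold."""
    out: dict[float, float] = {}
    for thr in candidates:
        f1s = []
        for sub in subjects:
            env: EnvelopePair = sub["envelope"]  # type: ignore[assignment]
            ann = sub["annotations"]
            bursts = detect_bursts(env, thr, merge_gap=merge_gap)
            m = match_and_score([(b.onset, b.offset) for b in bursts], ann)  # type: ignore[arg-type]
            f1s.append(0.0 if np.isnan(m.f1) else m.f1)
        out[float(thr)] = float(np.mean(f1s))
    return out
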