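"""Composite merging, topographic classification, posture and summaries."""

import itertools
import warnings

import numpy as np
import pytest

from noctomap.detection import MovementBurst
from noctomap.io_sync import Segment
from noctomap.taxonomy import (Category, CompositeMovement, State,
                               angle_between_deg, classify,
                               detect_postural_change, detect_upright,
                               merge_segments, summarize)
from .conftest import make_recording


def _b(seg, onset, offset, mag):
    return MovementBurst(Segment(seg), onset, offset, mag)


class TestMergeSegments:
    def test_worked_example_ankle_then_trunk(self):
        comps = merge_segments({Segment.LA: [_b("LA", 10, 13, 80.0)],
                                Segment.T: [_b("T", 12, 16, 40.0)]})
        assert len(comps) == 1
        c = comps[0]
        assert c.segments == {Segment.LA, Segment.T}
        assert (c.onset, c.offset) == (10, 16)
        assert c.magnitude == pytest.approx(120.0)

    @pytest.mark.parametrize("gap,n_expected", [(0.6, 2), (0.4, 1)])
    def test_half_second_rule_boundary(self, gap, n_expected):
        comps = merge_segments({Segment.LW: [_b("LW", 0.0, 2.0, 50.0),
                                             _b("LW", 2.0 + gap, 4.0, 60.0)]})
        assert len(comps) == n_expected

    def test_chain_is_transitive(self):
        # A-B overlap, B-C overlap, A and C disjoint -> one composite
        comps = merge_segments({
            Segment.LW: [_b("LW", 0.0, 2.0, 10.0)],
            Segment.T: [_b("T", 1.5, 5.0, 20.0)],
            Segment.RA: [_b("RA", 4.5, 7.0, 30.0)],
        })
        assert len(comps) == 1
        assert comps[0].segments == {Segment.LW, Segment.T, Segment.RA}
        assert comps[0].magnitude == pytest.approx(60.0)

    def test_repeated_segment_counts_max_not_sum(self):
        comps = merge_segments({Segment.LW: [_b("LW", 0.0, 1.0, 30.0),
                                             _b("LW", 1.2, 2.0, 50.0)]})
        assert len(comps) == 1
        assert comps[0].magnitude == pytest.approx(50.0)

    def test_output_pairwise_separated(self, rng):
        onsets = np.sort(rng.uniform(0, 1000, 60))
        per_seg = {}
        for seg in Segment:
            bs, last = [], -10.0
            for o in onsets[rng.uniform(size=60) < 0.4]:
                if o > last + 0.1:
                    bs.append(_b(seg.value, o, o + rng.uniform(0.1, 2.0), 10.0))
                    last = bs[-1].offset
            per_seg[seg] = bs
        comps = merge_segments(per_seg)
        for a, b in zip(comps, comps[1:]):
            assert b.onset - a.offset >= 0.5


def _oracle_category(segs: set) -> Category:
    """Independent re-statement of the classification rules."""
    upper = [{"LW", "RW"}, {"LW", "T"}, {"RW", "T"}, {"LW", "RW", "T"}]
    lower = [{"LA", "RA"}, {"LA", "T"}, {"RA", "T"}, {"LA", "RA", "T"}]
    if len(segs) == 1:
        return Category.SEGMENTAL
    if segs == {"LW", "RW", "LA", "RA", "T"}:
        return Category.GLOBAL
    if segs in upper:
        return Category.UPPER_BODY
    if segs in lower:
        return Category.LOWER_BODY
    return Category.CROSS_REGIONAL


class TestClassify:
    def test_examples(self):
        assert classify({Segment.RA}) is Category.SEGMENTAL
        assert classify({Segment.LW, Segment.RA}) is Category.CROSS_REGIONAL
        assert classify(set(Segment)) is Category.GLOBAL

    def test_all_31_subsets_match_enumerated_rules(self):
        names = ["LW", "RW", "LA", "RA", "T"]
        counts = {c: 0 for c in Category}
        total = 0
        for k in range(1, 6):
            for combo in itertools.combinations(names, k):
                got = classify({Segment(s) for s in combo})
                assert got is _oracle_category(set(combo)), combo
                counts[got] += 1
                total += 1
        assert total == 31
        assert counts == {Category.SEGMENTAL: 5, Category.GLOBAL: 1,
                          Category.UPPER_BODY: 4, Category.LOWER_BODY: 4,
                          Category.CROSS_REGIONAL: 17}

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            classify(set())


def _rotating_trunk(angle_deg, dur=30.0, fs=100.0, onset=12.0, offset=16.0,
                    noise=0.002, seed=0):
    """Trunk at rest on z; gravity rotates by angle_deg during the movement."""
    rng = np.random.default_rng(seed)
    n = int(dur * fs)
    t = np.arange(n) / fs
    frac = np.clip((t - onset) / (offset - onset), 0, 1)
    theta = np.radians(angle_deg) * frac
    ay = np.sin(theta) + rng.normal(0, noise, n)
    az = np.cos(theta) + rng.normal(0, noise, n)
    return make_recording(rng.normal(0, noise, n), ay, az, fs=fs,
                          segment=Segment.T)


class TestPosture:
    def _mov(self, onset=12.0, offset=16.0):
        return CompositeMovement(segments=frozenset(Segment), onset=onset,
                                 offset=offset, magnitude=500.0,
                                 category=Category.GLOBAL)

    def test_45_degree_rotation_flagged(self):
        assert detect_postural_change(self._mov(), _rotating_trunk(45.0)) is True

    def test_10_degree_rotation_not_flagged(self):
        assert detect_postural_change(self._mov(), _rotating_trunk(10.0)) is False

    def test_insufficient_context_returns_none(self):
        trunk = _rotating_trunk(45.0, dur=18.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            got = detect_postural_change(self._mov(onset=1.0, offset=16.0), trunk)
        assert got is None

    def test_angle_against_brute_force(self, rng):
        for _ in range(50):
            u, v = rng.normal(size=3), rng.normal(size=3)
            expected = np.degrees(np.arctan2(np.linalg.norm(np.cross(u, v)),
                                             np.dot(u, v)))
            assert angle_between_deg(u, v) == pytest.approx(expected, abs=1e-9)


class TestUpright:
    def test_supine_trace_empty(self, rng):
        n = 6000
        trunk = make_recording(rng.normal(0, 0.002, n), np.zeros(n),
                               1.0 + rng.normal(0, 0.002, n),
                               segment=Segment.T)
        assert detect_upright(trunk) == []

    def test_standing_trace_fully_flagged(self, rng):
        n = 6000
        trunk = make_recording(-1.0 + rng.normal(0, 0.002, n), np.zeros(n),
                               rng.normal(0, 0.002, n), segment=Segment.T)
        (a, b), = detect_upright(trunk)
        assert a < 1.0 and b > 58.0

    def test_single_bout_recovered(self, rng):
        fs, total = 100.0, 1800.0
        n = int(total * fs)
        t = np.arange(n) / fs
        ax = rng.normal(0, 0.002, n)
        up = (t >= 600.0) & (t <= 900.0)
        ramp = np.clip((t - 598.0) / 2.0, 0, 1) * np.clip((902.0 - t) / 2.0, 0, 1)
        ax -= ramp
        az = np.sqrt(np.clip(1 - ax ** 2, 0, None))
        trunk = make_recording(ax, np.zeros(n), az, segment=Segment.T)
        ivs = detect_upright(trunk)
        assert len(ivs) == 1
        assert ivs[0][0] == pytest.approx(600.0, abs=5.0)
        assert ivs[0][1] == pytest.approx(900.0, abs=5.0)


class TestSummarize:
    def test_index_arithmetic(self):
        movs = [CompositeMovement(frozenset({Segment.LW}), 10.0 * i, 10.0 * i + 1,
                                  50.0, Category.SEGMENTAL, False, State.AW)
                for i in range(20)]
        df = summarize(movs, {"dSPT": 2.0, "aS": 1.0, "aW": 1.0})
        aw_total = df[(df.state == "aW") & (df.category == "total")].iloc[0]
        assert aw_total["index_per_h"] == pytest.approx(20.0)
        assert aw_total["n"] == 20

    def test_empty_list_all_zero(self):
        df = summarize([], {"dSPT": 8.0, "aS": 7.0, "aW": 1.0})
        assert (df["n"] == 0).all()
        assert (df["index_per_h"] == 0).all()

    def test_category_counts_sum_to_total(self):
        movs = []
        for i, cat in enumerate(Category):
            segs = {Segment.LW} if cat is Category.SEGMENTAL else set(Segment)
            movs.append(CompositeMovement(frozenset(segs), 100.0 * i,
                                          100.0 * i + 2, 50.0, cat, False,
                                          State.AS))
        df = summarize(movs, {"dSPT": 8.0, "aS": 7.0, "aW": 1.0})
        d = df[df.state == "dSPT"]
        assert d[d.category == "total"]["n"].iloc[0] == \
            d[d.category != "total"]["n"].sum()
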