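import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fetalmotion.artifact_rejection import (
    AnalysisMask,
    MaskInterval,
    apply_artifact_rejection,
    classify_wake_and_restroom,
    detect_hiccup_bouts,
    detect_plm,
    mask_maternal_movement,
    mask_plm,
    mask_wake,
)
from fetalmotion.errors import InputError
from fetalmotion.io_formats import PipelineConfig

from conftest import make_event


def brute_force_intersects(a0, a1, b0, b1, guard=0.0):
    return a0 < b1 + guard and b0 - guard < a1


class TestAnalysisMask:
    def test_analysis_time_excludes_wake_not_hiccup(self):
        mask = AnalysisMask(
            intervals=[
                MaskInterval(100.0, 160.0, "wake"),
                MaskInterval(300.0, 720.0, "restroom"),
                MaskInterval(1000.0, 1600.0, "hiccup_bout"),
            ],
            total_recording_s=3600.0,
        )
        assert mask.analysis_time_s == pytest.approx(3600.0 - 60.0 - 420.0)

    def test_overlapping_same_reason_rejected(self):
        with pytest.raises(InputError, match="overlap"):
            AnalysisMask(
                intervals=[MaskInterval(0, 100, "wake"), MaskInterval(50, 150, "wake")],
                total_recording_s=200.0,
            )

    def test_analysis_time_bounded(self):
        mask = AnalysisMask(
            intervals=[MaskInterval(0.0, 500.0, "restroom")], total_recording_s=100.0
        )
        assert 0.0 <= mask.analysis_time_s <= 100.0


class TestMaternalMovement:
    def test_no_mm_events_all_retained(self):
        fm = [make_event(10, 11), make_event(20, 21)]
        out = mask_maternal_movement(fm, [], guard_s=1.0)
        assert all(e.status == "accepted" for e in out)

    def test_direct_overlap_rejected(self):
        fm = [make_event(100.0, 101.5)]
        mm = [make_event(100.5, 103.0, channel="MM")]
        out = mask_maternal_movement(fm, mm, guard_s=1.0)
        assert out[0].status == "rejected"
        assert out[0].reason == "maternal_movement"

    def test_guard_dilation(self):
        # MM [101.2, 102) dilated by 1.0 starts at 100.2, catching FM [100, 100.5)
        fm = [make_event(100.0, 100.5)]
        mm = [make_event(101.2, 102.0, channel="MM")]
        assert mask_maternal_movement(fm, mm, guard_s=1.0)[0].status == "rejected"
        assert mask_maternal_movement(fm, mm, guard_s=0.5)[0].status == "accepted"

    def test_rejected_mm_events_do_not_mask(self):
        fm = [make_event(100.0, 101.0)]
        mm = [make_event(100.0, 101.0, channel="MM", status="rejected", reason="edge_transient")]
        assert mask_maternal_movement(fm, mm, guard_s=1.0)[0].status == "accepted"

    @settings(max_examples=50, deadline=None)
    @given(
        fm_starts=st.lists(st.floats(0, 1000), min_size=0, max_size=20),
        mm_starts=st.lists(st.floats(0, 1000), min_size=0, max_size=20),
        guard=st.floats(0, 5),
    )
    def test_interval_oracle(self, fm_starts, mm_starts, guard):
        fm = [make_event(s, s + 1.0) for s in sorted(fm_starts)]
        mm = [make_event(s, s + 2.0, channel="MM") for s in sorted(mm_starts)]
        out = mask_maternal_movement(fm, mm, guard_s=guard)
        for ev_in, ev_out in zip(fm, out):
            expected = any(
                brute_force_intersects(ev_in.start_s, ev_in.end_s, m.start_s, m.end_s, guard)
                for m in mm
            )
            assert (ev_out.status == "rejected") == expected

    def test_monotone_in_mm_events(self):
        fm = [make_event(10, 11), make_event(50, 51), make_event(90, 91)]
        mm1 = [make_event(50.5, 52, channel="MM")]
        mm2 = mm1 + [make_event(89.5, 92, channel="MM")]
        out1 = mask_maternal_movement(fm, mm1, 1.0)
        out2 = mask_maternal_movement(fm, mm2, 1.0)
        rejected1 = {e.start_s for e in out1 if e.status == "rejected"}
        rejected2 = {e.start_s for e in out2 if e.status == "rejected"}
        assert rejected1 <= rejected2


class TestPlm:
    def make_train(self, n, interval, duration=1.2, start=100.0):
        return [
            make_event(start + i * interval, start + i * interval + duration, channel="MM")
            for i in range(n)
        ]

    def test_five_movements_30s_interval_one_run(self, cfg):
        runs = detect_plm(self.make_train(5, 30.0), cfg)
        assert len(runs) == 1
        assert len(runs[0]) == 5

    def test_three_movements_no_run(self, cfg):
        assert detect_plm(self.make_train(3, 30.0), cfg) == []

    def test_short_interval_no_run(self, cfg):
        assert detect_plm(self.make_train(6, 3.0), cfg) == []

    def test_interval_above_90_breaks_run(self, cfg):
        events = self.make_train(3, 30.0) + self.make_train(3, 30.0, start=500.0)
        assert detect_plm(events, cfg) == []  # two fragments of 3, gap 310 s

    def test_duration_bounds(self, cfg):
        too_short = self.make_train(5, 30.0, duration=0.5)
        too_long = self.make_train(5, 30.0, duration=6.0)
        assert detect_plm(too_short, cfg) == []
        assert detect_plm(too_long, cfg) == []

    def test_brute_force_maximal_subsequences(self, cfg, rng):
        # random MM events; oracle enumerates maximal qualifying chains
        starts = np.cumsum(rng.uniform(2, 100, size=40))
        durations = rng.uniform(0.5, 3.0, size=40)
        events = [
            make_event(float(s), float(s + d), channel="MM")
            for s, d in zip(starts, durations)
        ]
        p = cfg.plm
        cand = [e for e in events if p.min_duration_s <= e.duration_s <= p.max_duration_s]
        expected_runs = []
        run = [cand[0]] if cand else []
        for prev, cur in zip(cand, cand[1:]):
            if p.min_interval_s <= cur.start_s - prev.start_s <= p.max_interval_s:
                run.append(cur)
            else:
                if len(run) >= p.min_run_length:
                    expected_runs.append(tuple(run))
                run = [cur]
        if len(run) >= p.min_run_length:
            expected_runs.append(tuple(run))
        got = detect_plm(events, cfg)
        assert [r.events for r in got] == expected_runs

    def test_mask_plm_rejects_concurrent_fm(self, cfg):
        train = self.make_train(5, 30.0)
        runs = detect_plm(train, cfg)
        fm = [make_event(100.2, 100.8), make_event(115.0, 116.0)]
        out = mask_plm(fm, runs, guard_s=1.0)
        assert out[0].status == "rejected" and out[0].reason == "plm"
        assert out[1].status == "accepted"


class TestWakeRestroom:
    def minute_events(self, minute, n, duration=1.0):
        base = minute * 60.0
        return [
            make_event(base + i * (50.0 / max(n, 1)), base + i * (50.0 / max(n, 1)) + duration, channel="MM")
            for i in range(n)
        ]

    def test_three_events_not_wake(self, cfg):
        intervals = classify_wake_and_restroom(self.minute_events(2, 3), 600.0, cfg)
        assert intervals == []

    def test_four_events_wake(self, cfg):
        intervals = classify_wake_and_restroom(self.minute_events(2, 4), 600.0, cfg)
        assert len(intervals) == 1
        iv = intervals[0]
        assert (iv.start_s, iv.end_s, iv.reason) == (120.0, 180.0, "wake")

    def test_no_mm_events_full_analysis_time(self, cfg):
        intervals = classify_wake_and_restroom([], 600.0, cfg)
        mask = AnalysisMask(intervals=intervals, total_recording_s=600.0)
        assert mask.analysis_time_s == 600.0

    def test_seven_minutes_becomes_restroom(self, cfg):
        events = []
        for m in range(3, 10):
            events.extend(self.minute_events(m, 5))
        intervals = classify_wake_and_restroom(events, 900.0, cfg)
        assert len(intervals) == 1
        iv = intervals[0]
        assert iv.reason == "restroom"
        assert iv.end_s - iv.start_s == pytest.approx(420.0)

    def test_brute_force_minute_scan(self, cfg, rng):
        total = 1800.0
        onsets = np.sort(rng.uniform(0, total - 2, size=120))
        events = [make_event(float(t), float(t) + 0.8, channel="MM") for t in onsets]
        intervals = classify_wake_and_restroom(events, total, cfg)
        counts = [
            int(np.sum((onsets >= 60 * m) & (onsets < 60 * (m + 1)))) for m in range(30)
        ]
        wake_minutes = {m for m, c in enumerate(counts) if c >= cfg.wake_events_per_minute}
        covered = set()
        for iv in intervals:
            covered.update(range(int(iv.start_s // 60), int(np.ceil(iv.end_s / 60))))
        assert covered == wake_minutes

    def test_mask_wake_rejects_events(self, cfg):
        intervals = [MaskInterval(120.0, 180.0, "wake")]
        fm = [make_event(125.0, 126.0), make_event(300.0, 301.0)]
        out = mask_wake(fm, intervals)
        assert out[0].reason == "wake"
        assert out[1].status == "accepted"


class TestHiccups:
    def train(self, start, period, n, duration=0.4):
        return [make_event(start + i * period, start + i * period + duration) for i in range(n)]

    def test_thirty_per_minute_excluded(self, cfg):
        events = self.train(120.0, 2.0, 30)
        bouts, updated = detect_hiccup_bouts(events, 600.0, cfg)
        assert len(bouts) == 1
        assert all(e.reason == "hiccup" for e in updated if e.intersects(120.0, 180.0))

    def test_ten_per_minute_not_excluded(self, cfg):
        events = self.train(120.0, 6.0, 10)
        bouts, updated = detect_hiccup_bouts(events, 600.0, cfg)
        assert bouts == []
        assert all(e.status == "accepted" for e in updated)

    def test_exactly_fifteen_not_excluded(self, cfg):
        # strict "> 15 per minute"
        events = self.train(120.0, 60.0 / 15.0, 15)
        bouts, _ = detect_hiccup_bouts(events, 600.0, cfg)
        assert bouts == []

    def test_short_events_not_candidates(self, cfg):
        events = self.train(120.0, 2.0, 30, duration=0.1)  # below 0.2 s
        bouts, _ = detect_hiccup_bouts(events, 600.0, cfg)
        assert bouts == []

    def test_sustained_train_single_bout(self, cfg):
        # 16/min for 10 consecutive minutes -> one 600-s bout, 160 rejections
        events = []
        for m in range(10):
            events.extend(self.train(60.0 * (m + 1), 60.0 / 16.0, 16))
        bouts, updated = detect_hiccup_bouts(events, 3600.0, cfg)
        assert len(bouts) == 1
        b = bouts[0]
        assert b.end_s - b.start_s == pytest.approx(600.0)
        assert b.n_signals == 160
        assert sum(e.reason == "hiccup" for e in updated) == 160

    def test_brute_force_minute_counts(self, cfg, rng):
        total = 1800.0
        onsets = np.sort(rng.uniform(0, total - 1, size=400))
        events = [make_event(float(t), float(t) + 0.3, channel="FM") for t in onsets]
        bouts, updated = detect_hiccup_bouts(events, total, cfg)
        counts = [
            int(np.sum((onsets >= 60 * m) & (onsets < 60 * (m + 1)))) for m in range(30)
        ]
        hiccup_minutes = {m for m, c in enumerate(counts) if c > 15}
        covered = set()
        for b in bouts:
            covered.update(range(int(b.start_s // 60), int(np.ceil(b.end_s / 60))))
        assert covered == hiccup_minutes


class TestCascade:
    def test_event_conservation_and_single_reason(self, cfg, rng):
        fm = [make_event(float(t), float(t) + 0.5) for t in np.sort(rng.uniform(20, 3500, 150))]
        mm = [make_event(float(t), float(t) + 1.2, channel="MM") for t in np.sort(rng.uniform(20, 3500, 40))]
        out, mask, runs, bouts = apply_artifact_rejection(fm, mm, 3600.0, cfg)
        assert len(out) == len(fm)
        for e in out:
            if e.status == "rejected":
                assert e.reason != "none"
            else:
                assert e.reason == "none"

    def test_precedence_wake_over_maternal(self, cfg):
        # dense MM minute makes wake; FM event inside gets reason wake, not maternal
        mm = [make_event(120.0 + i * 10.0, 120.0 + i * 10.0 + 1.0, channel="MM") for i in range(5)]
        fm = [make_event(125.0, 125.5)]
        out, mask, _, _ = apply_artifact_rejection(fm, mm, 600.0, cfg)
        assert out[0].reason == "wake"
        assert any(iv.reason == "wake" for iv in mask.intervals)

    def test_edge_intervals_in_mask(self, cfg):
        out, mask, _, _ = apply_artifact_rejection([], [], 600.0, cfg)
        edges = mask.by_reason("edge_transient")
        assert len(edges) == 2
        assert mask.analysis_time_s == pytest.approx(600.0 - 2 * cfg.edge_transient_s)
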