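"""Rejection of maternal and non-gross-movement artifacts (pipeline step 4).

FM events explained by maternal body movement or periodic limb movement
(PLM) are rejected; maternal wake and restroom periods are excised from
analysis time; fetal hiccup trains are excluded from the movement count
without reducing analysis time.

Rejection precedence is fixed: wake/restroom > maternal_movement > plm >
hiccup — the first applicable reason wins and later passes never touch an
already-rejected event.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .detection import ACCEPTED, SignalEvent, accepted
from .errors import InputError
from .io_formats import PipelineConfig

#: Mask reasons that reduce analysis time (hiccup bouts do not).
TIME_EXCLUDING_REASONS = frozenset({"wake", "restroom", "edge_transient"})
MASK_REASONS = ("wake", "restroom", "hiccup_bout", "edge_transient")


@dataclass(frozen=True)
class MaskInterval:
    start_s: float
    end_s: float
    reason: str

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise InputError("mask interval end_s must exceed start_s")
        if self.reason not in MASK_REASONS:
            raise InputError(f"unknown mask reason {self.reason!r}")


@dataclass
class AnalysisMask:
    """Excluded time intervals plus the resulting analysis-time budget."""

    intervals: list[MaskInterval]
    total_recording_s: float

    def __post_init__(self) -> None:
        self.intervals = sorted(self.intervals, key=lambda iv: (iv.start_s, iv.reason))
        by_reason: dict[str, list[MaskInterval]] = {}
        for iv in self.intervals:
            by_reason.setdefault(iv.reason, []).append(iv)
        for reason, ivs in by_reason.items():
            for a, b in zip(ivs, ivs[1:]):
                if b.start_s < a.end_s:
                    raise InputError(f"{reason} intervals overlap: {a} and {b}")

    def by_reason(self, reason: str) -> list[MaskInterval]:
        return [iv for iv in self.intervals if iv.reason == reason]

    @property
    def analysis_time_s(self) -> float:
        """Total recording time minus merged wake/restroom/edge exclusions."""
        spans = sorted(
            (iv.start_s, min(iv.end_s, self.total_recording_s))
            for iv in self.intervals
            if iv.reason in TIME_EXCLUDING_REASONS
        )
        excluded = 0.0
        cur_start, cur_end = None, None
        for s, e in spans:
            if cur_end is None or s > cur_end:
                if cur_end is not None:
                    excluded += cur_end - cur_start
                cur_start, cur_end = s, e
            else:
                cur_end = max(cur_end, e)
        if cur_end is not None:
            excluded += cur_end - cur_start
        return max(self.total_recording_s - excluded, 0.0)


@dataclass(frozen=True)
class HiccupBout:
    start_s: float
    end_s: float
    n_signals: int


@dataclass(frozen=True)
class PlmRun:
    """A maximal series of qualifying limb movements at 5-90-s intervals."""

    events: tuple[SignalEvent, ...]

    @property
    def start_s(self) -> float:
        return self.events[0].start_s

    @property
    def end_s(self) -> float:
        return self.events[-1].end_s

    def __len__(self) -> int:
        return len(self.events)


def _check_sorted(events: list[SignalEvent], name: str) -> None:
    starts = [e.start_s for e in events]
    if starts != sorted(starts):
        raise InputError(f"{name} must be sorted by start_s")


def _intersects_any(
    event: SignalEvent, intervals: list[tuple[float, float]], guard_s: float = 0.0
) -> bool:
    return any(
        event.intersects(s - guard_s, e + guard_s) for s, e in intervals
    )


def mask_maternal_movement(
    fm_events: list[SignalEvent],
    mm_events: list[SignalEvent],
    guard_s: float = 1.0,
) -> list[SignalEvent]:
    """Reject accepted FM events overlapping any accepted MM event ±guard_s."""
    _check_sorted(fm_events, "fm_events")
    _check_sorted(mm_events, "mm_events")
    mm_spans = [(e.start_s, e.end_s) for e in accepted(mm_events)]
    out = []
    for ev in fm_events:
        if ev.status == ACCEPTED and _intersects_any(ev, mm_spans, guard_s):
            ev = ev.reject("maternal_movement")
        out.append(ev)
    return out


def detect_plm(mm_events: list[SignalEvent], cfg: PipelineConfig) -> list[PlmRun]:
    """Find maximal runs of ≥ min_run_length qualifying limb movements.

    A qualifying movement is an accepted MM event with duration within
    ``[min_duration_s, max_duration_s]``; successive onset-to-onset
    intervals within a run must fall in ``[min_interval_s, max_interval_s]``.
    Non-qualifying MM events between candidates do not break a run.
    """
    _check_sorted(mm_events, "mm_events")
    p = cfg.plm
    candidates = [
        e
        for e in accepted(mm_events)
        if p.min_duration_s <= e.duration_s <= p.max_duration_s
    ]
    runs: list[PlmRun] = []
    i = 0
    while i < len(candidates):
        j = i
        while (
            j + 1 < len(candidates)
            and p.min_interval_s
            <= candidates[j + 1].start_s - candidates[j].start_s
            <= p.max_interval_s
        ):
            j += 1
        if j - i + 1 >= p.min_run_length:
            runs.append(PlmRun(events=tuple(candidates[i : j + 1])))
        i = j + 1
    return runs


def mask_plm(
    fm_events: list[SignalEvent], plm_runs: list[PlmRun], guard_s: float = 1.0
) -> list[SignalEvent]:
    """Reject accepted FM events overlapping any PLM run member ±guard_s."""
    _check_sorted(fm_events, "fm_events")
    spans = [(e.start_s, e.end_s) for run in plm_runs for e in run.events]
    out = []
    for ev in fm_events:
        if ev.status == ACCEPTED and _intersects_any(ev, spans, guard_s):
            ev = ev.reject("plm")
        out.append(ev)
    return out


def _minute_counts(onsets: list[float], total_s: float) -> np.ndarray:
    """Events per fixed 60-s clock minute, binned by onset."""
    n_minutes = int(np.ceil(total_s / 60.0)) if total_s > 0 else 0
    counts = np.zeros(n_minutes, dtype=int)
    for t in onsets:
        m = int(t // 60)
        if 0 <= m < n_minutes:
            counts[m] += 1
    return counts


def _minute_runs(flags: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of consecutive True minutes as (first, last) index pairs."""
    runs = []
    start = None
    for m, f in enumerate(flags):
        if f and start is None:
            start = m
        elif not f and start is not None:
            runs.append((start, m - 1))
            start = None
    if start is not None:
        runs.append((start, len(flags) - 1))
    return runs


def classify_wake_and_restroom(
    mm_events: list[SignalEvent], total_s: float, cfg: PipelineConfig
) -> list[MaskInterval]:
    """Label wake minutes (≥ 4 MM events/min) and long wake runs as restroom.

    A clock minute is wake when it contains at least
    ``wake_events_per_minute`` accepted MM events (by onset).  Maximal runs
    of wake minutes spanning at least ``restroom_min_duration_s`` are
    relabeled restroom.  Both subtract from analysis time.
    """
    if total_s <= 0:
        raise InputError("total_s must be positive")
    _check_sorted(mm_events, "mm_events")
    onsets = [e.start_s for e in accepted(mm_events)]
    counts = _minute_counts(onsets, total_s)
    wake_minutes = counts >= cfg.wake_events_per_minute
    intervals = []
    for first, last in _minute_runs(wake_minutes):
        start = first * 60.0
        end = min((last + 1) * 60.0, total_s)
        reason = "restroom" if end - start >= cfg.restroom_min_duration_s else "wake"
        intervals.append(MaskInterval(start, end, reason))
    return intervals


def mask_wake(
    fm_events: list[SignalEvent], wake_intervals: list[MaskInterval]
) -> list[SignalEvent]:
    """Reject accepted FM events inside wake or restroom intervals."""
    spans = [(iv.start_s, iv.end_s) for iv in wake_intervals]
    out = []
    for ev in fm_events:
        if ev.status == ACCEPTED and _intersects_any(ev, spans):
            ev = ev.reject("wake")
        out.append(ev)
    return out


def detect_hiccup_bouts(
    fm_events: list[SignalEvent], total_s: float, cfg: PipelineConfig
) -> tuple[list[HiccupBout], list[SignalEvent]]:
    """Exclude minutes dominated by short rhythmic FM signals (fetal hiccups).

    Candidates are accepted FM events of duration ≥ ``min_event_duration_s``.
    A clock minute with strictly more than ``events_per_minute_threshold``
    candidates is a hiccup minute; maximal runs of hiccup minutes form
    bouts.  Every accepted FM event intersecting a bout is rejected with
    reason ``hiccup``; bout time stays in the analysis denominator.
    """
    _check_sorted(fm_events, "fm_events")
    h = cfg.hiccup
    candidates = [
        e for e in accepted(fm_events) if e.duration_s >= h.min_event_duration_s
    ]
    counts = _minute_counts([e.start_s for e in candidates], total_s)
    hiccup_minutes = counts > h.events_per_minute_threshold
    bouts = []
    updated = list(fm_events)
    for first, last in _minute_runs(hiccup_minutes):
        start = first * 60.0
        end = min((last + 1) * 60.0, total_s)
        n_rejected = 0
        for i, ev in enumerate(updated):
            if ev.status == ACCEPTED and ev.intersects(start, end):
                updated[i] = ev.reject("hiccup")
                n_rejected += 1
        bouts.append(HiccupBout(start_s=start, end_s=end, n_signals=n_rejected))
    return bouts, updated


def apply_artifact_rejection(
    fm_events: list[SignalEvent],
    mm_events: list[SignalEvent],
    total_s: float,
    cfg: PipelineConfig,
) -> tuple[list[SignalEvent], AnalysisMask, list[PlmRun], list[HiccupBout]]:
    """Run the full rejection cascade in precedence order and build the mask."""
    edge_intervals = []
    e = cfg.edge_transient_s
    if e > 0 and total_s > 2 * e:
        edge_intervals = [
            MaskInterval(0.0, e, "edge_transient"),
            MaskInterval(total_s - e, total_s, "edge_transient"),
        ]
    wake_intervals = classify_wake_and_restroom(mm_events, total_s, cfg)
    fm_events = mask_wake(fm_events, wake_intervals)
    fm_events = mask_maternal_movement(fm_events, mm_events, cfg.mm_guard_s)
    plm_runs = detect_plm(mm_events, cfg)
    fm_events = mask_plm(fm_events, plm_runs, cfg.plm.guard_s)
    bouts, fm_events = detect_hiccup_bouts(fm_events, total_s, cfg)
    bout_intervals = [MaskInterval(b.start_s, b.end_s, "hiccup_bout") for b in bouts]
    mask = AnalysisMask(
        intervals=edge_intervals + wake_intervals + bout_intervals,
        total_recording_s=total_s,
    )
    return fm_events, mask, plm_runs, bouts
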