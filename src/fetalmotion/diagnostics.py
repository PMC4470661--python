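"""Inter-event-interval histogram and artifact-suspect flags.

The histogram of onset-to-onset intervals between accepted FM events is the
quality-control instrument: residual maternal respiration piles counts into
the 3-5-s columns and fetal hiccups into the 2-s column.  Flags report a
deterministic surrogate for the visual "extremely high column" judgment: a
suspect column group must exceed ``flag_factor`` times the median of the
other non-zero columns and contain at least ``flag_min_count`` intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .detection import SignalEvent
from .errors import InputError
from .io_formats import PipelineConfig

#: 1-s histogram bins from 0 to 40 s; index 40 is the overflow bin (≥ 40 s).
BIN_EDGES = np.arange(0.0, 41.0)
N_BINS = 41

_RESPIRATION_BINS = slice(3, 6)  # intervals in [3, 6) s
_HICCUP_BINS = slice(2, 3)       # intervals in [2, 3) s


@dataclass(frozen=True)
class QCFlags:
    respiration_suspect: bool = False
    hiccup_suspect: bool = False

    def any(self) -> bool:
        return self.respiration_suspect or self.hiccup_suspect

    def as_dict(self) -> dict[str, bool]:
        return {
            "respiration_suspect": self.respiration_suspect,
            "hiccup_suspect": self.hiccup_suspect,
        }


@dataclass(frozen=True)
class IntervalHistogram:
    """Counts of onset-to-onset intervals in 1-s bins plus an overflow bin."""

    counts: np.ndarray
    n_events: int
    flags: QCFlags = field(default_factory=QCFlags)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        object.__setattr__(self, "counts", counts)
        if len(counts) != N_BINS:
            raise InputError(f"histogram must have {N_BINS} bins")
        if np.any(counts < 0):
            raise InputError("histogram counts must be non-negative")
        if counts.sum() != max(0, self.n_events - 1):
            raise InputError("histogram counts must sum to n_events - 1")


def interval_histogram(
    events: list[SignalEvent], cfg: PipelineConfig | None = None
) -> IntervalHistogram:
    """Histogram of successive onset-to-onset intervals of accepted FM events.

    With fewer than two events the histogram is all-zero and unflagged.
    When a config is supplied the suspect flags are evaluated and attached.
    """
    onsets = np.array([e.start_s for e in events], dtype=float)
    if np.any(np.diff(onsets) < 0):
        raise InputError("events must be sorted by start_s")
    counts = np.zeros(N_BINS, dtype=int)
    if len(onsets) >= 2:
        intervals = np.diff(onsets)
        edges = np.concatenate([BIN_EDGES, [np.inf]])
        counts, _ = np.histogram(intervals, bins=edges)
        counts = counts.astype(int)
    hist = IntervalHistogram(counts=counts, n_events=len(onsets))
    if cfg is not None:
        hist = IntervalHistogram(
            counts=counts, n_events=len(onsets), flags=flag_artifacts(hist, cfg)
        )
    return hist


def _column_group_suspect(
    counts: np.ndarray, group: slice, factor: float, min_count: int
) -> bool:
    group_sum = int(counts[group].sum())
    if group_sum < min_count:
        return False
    others = np.delete(counts, np.arange(N_BINS)[group])
    nonzero = others[others > 0]
    reference = float(np.median(nonzero)) if nonzero.size else 0.0
    return group_sum > factor * reference


def flag_artifacts(hist: IntervalHistogram, cfg: PipelineConfig) -> QCFlags:
    """Evaluate respiration (3-5-s columns) and hiccup (2-s column) flags."""
    return QCFlags(
        respiration_suspect=_column_group_suspect(
            hist.counts, _RESPIRATION_BINS, cfg.flag_factor, cfg.flag_min_count
        ),
        hiccup_suspect=_column_group_suspect(
            hist.counts, _HICCUP_BINS, cfg.flag_factor, cfg.flag_min_count
        ),
    )
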