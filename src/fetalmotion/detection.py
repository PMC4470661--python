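"""Burst detection on 50-ms rectified integrals with an adaptive 200% rule.

Each filtered channel is reduced to per-bin rectified integrals.  A bin is a
movement candidate when its integral exceeds ``ratio_threshold`` times the
mean integral of the surrounding ±3 s (the bin itself excluded, windows
truncated at the series edges) *and* clears a fixed per-channel minimum
integral that suppresses low-amplitude residual artifacts such as REM-sleep
respiration.  Nearby supra-threshold bins are merged into events.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import ConfigurationError, InputError
from .io_formats import PipelineConfig

ACCEPTED = "accepted"
REJECTED = "rejected"

#: Rejection reasons an event may carry (exactly one when rejected).
REASONS = (
    "none",
    "below_min_threshold",
    "maternal_movement",
    "plm",
    "hiccup",
    "wake",
    "edge_transient",
)


@dataclass(frozen=True)
class IntegralSeries:
    """Per-channel rectified integrals; bin ``k`` covers ``[k*bin_s, (k+1)*bin_s)``."""

    channel: str
    bin_s: float
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.channel not in ("FM", "MM"):
            raise InputError(f"unknown channel {self.channel!r}")
        if self.bin_s <= 0:
            raise ConfigurationError("bin_s must be positive")
        if np.any(self.values < 0):
            raise InputError("integral values must be non-negative")

    @property
    def duration_s(self) -> float:
        return len(self.values) * self.bin_s


@dataclass(frozen=True)
class SignalEvent:
    """One supra-threshold burst on a channel, half-open in seconds."""

    channel: str
    start_s: float
    end_s: float
    peak_integral: float
    status: str = ACCEPTED
    reason: str = "none"

    def __post_init__(self) -> None:
        object.__setattr__(self, "start_s", float(self.start_s))
        object.__setattr__(self, "end_s", float(self.end_s))
        object.__setattr__(self, "peak_integral", float(self.peak_integral))
        if self.end_s <= self.start_s:
            raise InputError("event end_s must exceed start_s")
        if self.status not in (ACCEPTED, REJECTED):
            raise InputError(f"unknown status {self.status!r}")
        if self.reason not in REASONS:
            raise InputError(f"unknown reason {self.reason!r}")
        if self.status == ACCEPTED and self.reason != "none":
            raise InputError("accepted events must carry reason 'none'")
        if self.status == REJECTED and self.reason == "none":
            raise InputError("rejected events must carry a reason")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    def reject(self, reason: str) -> "SignalEvent":
        return replace(self, status=REJECTED, reason=reason)

    def intersects(self, start_s: float, end_s: float) -> bool:
        """Half-open interval intersection test."""
        return self.start_s < end_s and start_s < self.end_s


def compute_bin_integrals(
    signal: np.ndarray, sampling_rate: float, bin_ms: float = 50.0, channel: str = "FM"
) -> IntegralSeries:
    """Rectified integral per bin: sum of ``|sample|`` over each 50-ms bin.

    A trailing partial bin is dropped.  The number of samples per bin must
    be a whole number ≥ 1.
    """
    spb_real = sampling_rate * bin_ms / 1000.0
    spb = int(round(spb_real))
    if spb < 1:
        raise ConfigurationError(
            f"bin of {bin_ms} ms holds less than one sample at {sampling_rate} Hz"
        )
    if abs(spb_real - spb) > 1e-9:
        raise ConfigurationError(
            f"bin of {bin_ms} ms is not a whole number of samples at {sampling_rate} Hz"
        )
    x = np.abs(np.asarray(signal, dtype=float))
    n_bins = len(x) // spb
    values = x[: n_bins * spb].reshape(n_bins, spb).sum(axis=1)
    return IntegralSeries(channel=channel, bin_s=bin_ms / 1000.0, values=values)


def adaptive_baseline(values: np.ndarray, window_bins: int) -> np.ndarray:
    """Mean of the ±window_bins neighbourhood of each bin, bin itself excluded.

    Windows are truncated (not padded) at the series edges.  The result is
    floored at machine epsilon so the ratio test never divides by zero.
    """
    v = np.asarray(values, dtype=float)
    n = len(v)
    csum = np.concatenate([[0.0], np.cumsum(v)])
    k = np.arange(n)
    lo = np.maximum(k - window_bins, 0)
    hi = np.minimum(k + window_bins, n - 1)
    window_sum = csum[hi + 1] - csum[lo]
    count = hi - lo  # window size minus the excluded centre bin
    baseline = np.where(count > 0, (window_sum - v) / np.maximum(count, 1), 0.0)
    return np.maximum(baseline, np.finfo(float).eps)


def supra_threshold_bins(
    values: np.ndarray,
    window_bins: int,
    ratio_threshold: float,
    min_integral: float,
) -> np.ndarray:
    """Boolean mask of bins passing both the adaptive-ratio and minimum rules."""
    v = np.asarray(values, dtype=float)
    baseline = adaptive_baseline(v, window_bins)
    return (v > ratio_threshold * baseline) & (v >= min_integral)


def detect_candidate_events(
    integrals: IntegralSeries, cfg: PipelineConfig
) -> list[SignalEvent]:
    """Detect supra-threshold bursts on one channel.

    Consecutive supra-threshold bins separated by gaps of at most
    ``merge_gap_s`` merge into one event.  Events intersecting the
    edge-transient zones (first/last ``edge_transient_s`` seconds) are
    emitted with status rejected / reason ``edge_transient``.
    """
    v = integrals.values
    bin_s = integrals.bin_s
    if len(v) == 0:
        raise InputError("cannot detect events on an empty integral series")
    window_bins = int(round(cfg.baseline_window_s / bin_s))
    if len(v) <= 2 * window_bins:
        raise InputError(
            f"series of {len(v)} bins is too short for a ±{window_bins}-bin baseline"
        )
    min_integral = cfg.min_integral_fm if integrals.channel == "FM" else cfg.min_integral_mm
    supra = supra_threshold_bins(v, window_bins, cfg.ratio_threshold, min_integral)
    idx = np.flatnonzero(supra)
    if idx.size == 0:
        return []
    gap_bins = int(round(cfg.merge_gap_s / bin_s))
    # split where more than gap_bins empty bins separate supra bins
    breaks = np.flatnonzero(np.diff(idx) > gap_bins + 1)
    groups = np.split(idx, breaks + 1)
    total_s = integrals.duration_s
    events = []
    for g in groups:
        start_s = g[0] * bin_s
        end_s = (g[-1] + 1) * bin_s
        peak = float(v[g[0] : g[-1] + 1].max())
        ev = SignalEvent(
            channel=integrals.channel,
            start_s=start_s,
            end_s=end_s,
            peak_integral=peak,
        )
        in_edge = start_s < cfg.edge_transient_s or end_s > total_s - cfg.edge_transient_s
        if in_edge:
            ev = ev.reject("edge_transient")
        events.append(ev)
    return events


def accepted(events: list[SignalEvent]) -> list[SignalEvent]:
    """Convenience filter for accepted events."""
    return [e for e in events if e.status == ACCEPTED]
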