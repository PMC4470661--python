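"""Plain-text interchange formats for recordings, events, masks and configs.

A recording is a CSV file (columns ``fm,mm`` or ``time_s,fm,mm``) with a JSON
sidecar of the same stem holding ``sampling_rate``, ``subject_id`` and
``gestational_week``.  Events and masks are CSV with a fixed column order;
the pipeline configuration is a single JSON document.  All writers emit
full-precision floats (shortest round-tripping repr) so read(write(x)) == x.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .errors import ConfigurationError, FormatError, InputError, SamplingError
from .preprocessing import EDGE_TRANSIENT_S, FilterConfig

if TYPE_CHECKING:  # pragma: no cover
    from .artifact_rejection import AnalysisMask
    from .detection import SignalEvent

#: Tolerance (seconds) for verifying a uniform explicit time column.
_TIME_TOL_S = 1e-6

_EVENT_COLUMNS = ["channel", "start_s", "end_s", "peak_integral", "status", "reason"]
_MASK_COLUMNS = ["start_s", "end_s", "reason"]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Recording:
    """Two-channel uniformly sampled acceleration series.

    Sample ``i`` is at ``start_offset + i / sampling_rate`` seconds; all
    downstream intervals are half-open ``[start, end)`` in seconds from the
    recording start.
    """

    subject_id: str
    gestational_week: int
    sampling_rate: float
    fm: np.ndarray
    mm: np.ndarray
    start_offset: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "fm", np.asarray(self.fm, dtype=float))
        object.__setattr__(self, "mm", np.asarray(self.mm, dtype=float))
        if self.sampling_rate <= 0:
            raise FormatError("sampling_rate must be positive")
        if self.fm.ndim != 1 or self.mm.ndim != 1:
            raise FormatError("channels must be one-dimensional")
        if len(self.fm) != len(self.mm):
            raise FormatError(
                f"channel length mismatch: fm has {len(self.fm)} samples, "
                f"mm has {len(self.mm)}"
            )
        if len(self.fm) < 1:
            raise FormatError("recording must contain at least one sample")

    @property
    def n_samples(self) -> int:
        return len(self.fm)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Recording):
            return NotImplemented
        return (
            self.subject_id == other.subject_id
            and self.gestational_week == other.gestational_week
            and self.sampling_rate == other.sampling_rate
            and self.start_offset == other.start_offset
            and np.array_equal(self.fm, other.fm)
            and np.array_equal(self.mm, other.mm)
        )


class PlmConfig(BaseModel):
    """Periodic-limb-movement detection parameters (ASDA-style series)."""

    model_config = ConfigDict(extra="forbid")

    min_duration_s: float = 1.0
    max_duration_s: float = 5.0
    min_interval_s: float = 5.0
    max_interval_s: float = 90.0
    min_run_length: int = 4
    guard_s: float = 1.0

    @model_validator(mode="after")
    def _check(self) -> "PlmConfig":
        if not (0 < self.min_duration_s < self.max_duration_s):
            raise ConfigurationError("PLM duration bounds must satisfy 0 < min < max")
        if not (0 < self.min_interval_s < self.max_interval_s):
            raise ConfigurationError("PLM interval bounds must satisfy 0 < min < max")
        if self.min_run_length < 2:
            raise ConfigurationError("PLM run length must be at least 2")
        return self


class HiccupRuleConfig(BaseModel):
    """Fetal-hiccup exclusion parameters."""

    model_config = ConfigDict(extra="forbid")

    min_event_duration_s: float = 0.2
    events_per_minute_threshold: int = 15

    @model_validator(mode="after")
    def _check(self) -> "HiccupRuleConfig":
        if self.min_event_duration_s <= 0:
            raise ConfigurationError("hiccup minimum event duration must be positive")
        if self.events_per_minute_threshold <= 0:
            raise ConfigurationError("hiccup per-minute threshold must be positive")
        return self


class PipelineConfig(BaseModel):
    """All tunable constants of the detection/rejection pipeline.

    Unknown keys are rejected on load so stale config files fail loudly.
    """

    model_config = ConfigDict(extra="forbid")

    filters: FilterConfig = Field(default_factory=FilterConfig)
    bin_ms: float = 50.0
    ratio_threshold: float = 2.0
    baseline_window_s: float = 3.0
    min_integral_fm: float = 15.0
    min_integral_mm: float = 20.0
    merge_gap_s: float = 0.25
    edge_transient_s: float = EDGE_TRANSIENT_S
    mm_guard_s: float = 1.0
    plm: PlmConfig = Field(default_factory=PlmConfig)
    hiccup: HiccupRuleConfig = Field(default_factory=HiccupRuleConfig)
    wake_events_per_minute: int = 4
    restroom_min_duration_s: float = 300.0
    epoch_s: float = 10.0
    flag_factor: float = 3.0
    flag_min_count: int = 20
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "PipelineConfig":
        positive = {
            "bin_ms": self.bin_ms,
            "baseline_window_s": self.baseline_window_s,
            "min_integral_fm": self.min_integral_fm,
            "min_integral_mm": self.min_integral_mm,
            "restroom_min_duration_s": self.restroom_min_duration_s,
            "epoch_s": self.epoch_s,
            "flag_factor": self.flag_factor,
            "wake_events_per_minute": self.wake_events_per_minute,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ConfigurationError(f"{name} must be strictly positive")
        if self.ratio_threshold <= 1:
            raise ConfigurationError("ratio_threshold must exceed 1")
        if self.merge_gap_s < 0 or self.mm_guard_s < 0 or self.edge_transient_s < 0:
            raise ConfigurationError("gap/guard/edge durations must be non-negative")
        return self


# ---------------------------------------------------------------------------
# Recording I/O
# ---------------------------------------------------------------------------

def _sidecar_path(csv_path: Path) -> Path:
    return csv_path.with_suffix(".json")


def read_recording(path: str | Path) -> Recording:
    """Read a recording CSV plus its JSON metadata sidecar.

    Accepts columns ``(fm, mm)`` or ``(time_s, fm, mm)``.  When ``time_s``
    is present, uniform sampling at the sidecar rate is verified to within
    one microsecond.
    """
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FormatError(f"metadata sidecar {sidecar} not found")
    meta = json.loads(sidecar.read_text())
    for key in ("sampling_rate", "subject_id", "gestational_week"):
        if key not in meta:
            raise FormatError(f"sidecar missing required field {key!r}")
    df = pd.read_csv(path, float_precision="round_trip")
    cols = list(df.columns)
    if cols not in (["fm", "mm"], ["time_s", "fm", "mm"]):
        raise FormatError(
            f"expected columns (fm, mm) or (time_s, fm, mm); found {cols}"
        )
    rate = float(meta["sampling_rate"])
    start_offset = float(meta.get("start_offset", 0.0))
    if "time_s" in cols:
        t = df["time_s"].to_numpy(dtype=float)
        expected = start_offset + np.arange(len(t)) / rate
        if len(t) and np.max(np.abs(t - expected)) > _TIME_TOL_S:
            raise SamplingError(
                f"time_s is not uniform at {rate} Hz within {_TIME_TOL_S} s"
            )
    return Recording(
        subject_id=str(meta["subject_id"]),
        gestational_week=int(meta["gestational_week"]),
        sampling_rate=rate,
        start_offset=start_offset,
        fm=df["fm"].to_numpy(dtype=float),
        mm=df["mm"].to_numpy(dtype=float),
    )


def write_recording(
    recording: Recording, path: str | Path, include_time: bool = False
) -> None:
    """Write a recording to CSV plus JSON sidecar (inverse of read_recording)."""
    path = Path(path)
    data: dict[str, np.ndarray] = {}
    if include_time:
        data["time_s"] = recording.start_offset + (
            np.arange(recording.n_samples) / recording.sampling_rate
        )
    data["fm"] = recording.fm
    data["mm"] = recording.mm
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.17g")
    meta = {
        "subject_id": recording.subject_id,
        "gestational_week": recording.gestational_week,
        "sampling_rate": recording.sampling_rate,
        "start_offset": recording.start_offset,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# Event I/O
# ---------------------------------------------------------------------------

def write_events(events: list["SignalEvent"], path: str | Path) -> None:
    """Write events to CSV (columns channel,start_s,end_s,peak_integral,status,reason).

    Events must already be sorted by start time.
    """
    starts = [e.start_s for e in events]
    if starts != sorted(starts):
        raise InputError("events must be sorted by start_s before writing")
    rows = [
        (e.channel, repr(e.start_s), repr(e.end_s), repr(e.peak_integral), e.status, e.reason)
        for e in events
    ]
    df = pd.DataFrame(rows, columns=_EVENT_COLUMNS)
    df.to_csv(path, index=False)


def read_events(path: str | Path) -> list["SignalEvent"]:
    """Read events written by :func:`write_events`."""
    from .detection import SignalEvent

    df = pd.read_csv(
        path,
        dtype={"channel": str, "status": str, "reason": str},
        keep_default_na=False,
        float_precision="round_trip",
    )
    if list(df.columns) != _EVENT_COLUMNS:
        raise FormatError(f"expected event columns {_EVENT_COLUMNS}; found {list(df.columns)}")
    events = [
        SignalEvent(
            channel=row.channel,
            start_s=float(row.start_s),
            end_s=float(row.end_s),
            peak_integral=float(row.peak_integral),
            status=row.status,
            reason=row.reason if row.reason else "none",
        )
        for row in df.itertuples(index=False)
    ]
    starts = [e.start_s for e in events]
    if starts != sorted(starts):
        raise FormatError("event file is not sorted by start_s")
    return events


# ---------------------------------------------------------------------------
# Mask I/O
# ---------------------------------------------------------------------------

def write_mask(mask: "AnalysisMask", path: str | Path) -> None:
    """Write an analysis mask; the total duration rides in a comment line."""
    path = Path(path)
    lines = [f"# total_recording_s={mask.total_recording_s!r}"]
    lines.append(",".join(_MASK_COLUMNS))
    for iv in mask.intervals:
        lines.append(f"{iv.start_s!r},{iv.end_s!r},{iv.reason}")
    path.write_text("\n".join(lines) + "\n")


def read_mask(path: str | Path) -> "AnalysisMask":
    from .artifact_rejection import AnalysisMask, MaskInterval

    path = Path(path)
    text = path.read_text().splitlines()
    if not text or not text[0].startswith("# total_recording_s="):
        raise FormatError("mask file missing total_recording_s header comment")
    total = float(text[0].split("=", 1)[1])
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    if list(df.columns) != _MASK_COLUMNS:
        raise FormatError(f"expected mask columns {_MASK_COLUMNS}; found {list(df.columns)}")
    intervals = [
        MaskInterval(float(r.start_s), float(r.end_s), str(r.reason))
        for r in df.itertuples(index=False)
    ]
    return AnalysisMask(intervals=intervals, total_recording_s=total)


# ---------------------------------------------------------------------------
# Config I/O
# ---------------------------------------------------------------------------

def write_config(cfg: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(cfg.model_dump_json(indent=2) + "\n")


def read_config(path: str | Path) -> PipelineConfig:
    """Load a pipeline config; unknown keys are rejected."""
    try:
        return PipelineConfig.model_validate_json(Path(path).read_text())
    except ValidationError as exc:
        raise ConfigurationError(str(exc)) from exc
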