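"""End-to-end orchestration: filter -> integrate -> detect -> reject -> QC -> summary."""

from __future__ import annotations

import hashlib
import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .artifact_rejection import AnalysisMask, HiccupBout, PlmRun, apply_artifact_rejection
from .detection import SignalEvent, accepted, compute_bin_integrals, detect_candidate_events
from .diagnostics import IntervalHistogram, flag_artifacts, interval_histogram
from .io_formats import PipelineConfig, Recording, write_events, write_mask
from .preprocessing import apply_preprocessing
from .summary_stats import EpochLabels, SessionSummary, epoch_labels, session_summary

logger = logging.getLogger(__name__)


@dataclass
class RunManifest:
    """Audit trail of one pipeline run; counts reconcile by construction."""

    input_path: str
    config_sha256: str
    version: str
    n_detected_fm: int
    n_accepted_fm: int
    rejected_by_reason: dict[str, int]
    n_detected_mm: int
    flags: dict[str, bool]
    output_paths: dict[str, str] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "input_path": self.input_path,
            "config_sha256": self.config_sha256,
            "version": self.version,
            "n_detected_fm": self.n_detected_fm,
            "n_accepted_fm": self.n_accepted_fm,
            "rejected_by_reason": dict(sorted(self.rejected_by_reason.items())),
            "n_detected_mm": self.n_detected_mm,
            "flags": self.flags,
            "output_paths": self.output_paths,
        }


@dataclass
class PipelineResult:
    fm_events: list[SignalEvent]
    mm_events: list[SignalEvent]
    mask: AnalysisMask
    plm_runs: list[PlmRun]
    hiccup_bouts: list[HiccupBout]
    histogram: IntervalHistogram
    labels: EpochLabels
    summary: SessionSummary
    manifest: RunManifest


def config_hash(cfg: PipelineConfig) -> str:
    canonical = json.dumps(cfg.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()


def run_pipeline(
    recording: Recording,
    cfg: PipelineConfig,
    input_path: str = "<memory>",
) -> PipelineResult:
    """Run the full analysis chain on one recording."""
    filtered = apply_preprocessing(recording, cfg.filters)
    total_s = recording.duration_s
    fm_int = compute_bin_integrals(filtered.fm, filtered.sampling_rate, cfg.bin_ms, "FM")
    mm_int = compute_bin_integrals(filtered.mm, filtered.sampling_rate, cfg.bin_ms, "MM")
    fm_events = detect_candidate_events(fm_int, cfg)
    mm_events = detect_candidate_events(mm_int, cfg)
    logger.info("detected %d FM / %d MM candidate events", len(fm_events), len(mm_events))
    fm_events, mask, plm_runs, bouts = apply_artifact_rejection(
        fm_events, mm_events, total_s, cfg
    )
    hist = interval_histogram(accepted(fm_events), cfg)
    flags = flag_artifacts(hist, cfg)
    labels = epoch_labels(fm_events, mask, total_s, cfg.epoch_s)
    summary = session_summary(
        fm_events,
        mask,
        subject_id=recording.subject_id,
        gestational_week=recording.gestational_week,
        flags=flags.as_dict(),
    )
    reasons = Counter(e.reason for e in fm_events if e.status == "rejected")
    for ev in fm_events:
        logger.debug("FM event %s status=%s reason=%s", ev, ev.status, ev.reason)
    manifest = RunManifest(
        input_path=input_path,
        config_sha256=config_hash(cfg),
        version=__version__,
        n_detected_fm=len(fm_events),
        n_accepted_fm=len(accepted(fm_events)),
        rejected_by_reason=dict(reasons),
        n_detected_mm=len(mm_events),
        flags=flags.as_dict(),
    )
    return PipelineResult(
        fm_events=fm_events,
        mm_events=mm_events,
        mask=mask,
        plm_runs=plm_runs,
        hiccup_bouts=bouts,
        histogram=hist,
        labels=labels,
        summary=summary,
        manifest=manifest,
    )


def write_outputs(result: PipelineResult, out_dir: str | Path) -> RunManifest:
    """Write events, mask, histogram, summary and manifest into a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "fm_events": out / "fm_events.csv",
        "mm_events": out / "mm_events.csv",
        "mask": out / "mask.csv",
        "histogram": out / "histogram.csv",
        "summary": out / "summary.json",
        "manifest": out / "manifest.json",
    }
    write_events(result.fm_events, paths["fm_events"])
    write_events(result.mm_events, paths["mm_events"])
    write_mask(result.mask, paths["mask"])
    lines = ["bin_start_s,bin_end_s,count"]
    for k, c in enumerate(result.histogram.counts):
        hi = "inf" if k == 40 else str(float(k + 1))
        lines.append(f"{float(k)},{hi},{int(c)}")
    paths["histogram"].write_text("\n".join(lines) + "\n")
    s = result.summary
    summary_doc = {
        "subject_id": s.subject_id,
        "gestational_week": s.gestational_week,
        "n_movements": s.n_movements,
        "analysis_time_h": s.analysis_time_h,
        "movements_per_hour": s.movements_per_hour,
        "n_hiccup_bouts": s.n_hiccup_bouts,
        "flags": s.flags,
    }
    paths["summary"].write_text(json.dumps(summary_doc, indent=2, sort_keys=True) + "\n")
    # file names only, so runs into different directories stay byte-identical
    result.manifest.output_paths = {k: v.name for k, v in paths.items()}
    paths["manifest"].write_text(
        json.dumps(result.manifest.as_dict(), indent=2, sort_keys=True) + "\n"
    )
    return result.manifest
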