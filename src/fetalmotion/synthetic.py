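"""Ground-truth-labeled simulator for two-channel overnight recordings.

Generates every signal class the pipeline must handle: fetal movement
bursts, ~1 Hz maternal heartbeat, 3-5-s-interval respiration with
REM-irregular episodes, maternal gross movements visible on both channels,
periodic limb movement trains, fetal hiccup trains, and wake/restroom
periods of dense maternal activity.  Waveform shapes are arbitrary but
self-consistent: device units are calibrated so the default minimum
integral thresholds (15 FM / 20 MM) sit between the noise-floor integral
and typical burst integrals.

Everything is driven by a single :class:`numpy.random.Generator` seeded
from the config, so identical configs produce bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator
from scipy import signal as sps

from .errors import ConfigurationError
from .io_formats import Recording

CLASSES = (
    "fetal_burst",
    "heartbeat",
    "respiration",
    "maternal_move",
    "plm",
    "hiccup",
    "wake",
    "restroom",
)


class FetalBurstConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    rate_per_hour: float = 60.0
    duration_range: tuple[float, float] = (0.5, 3.0)
    amplitude_range: tuple[float, float] = (10.0, 25.0)
    min_separation_s: float = 10.0


class HeartbeatConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    frequency_hz: float = 1.0
    amplitude: float = 0.0
    jitter_s: float = 0.02
    # one biphasic cycle; width chosen so energy sits at the fundamental
    # (notched) and second harmonic, which survives filtering as a smooth
    # quasi-continuous wave the adaptive ratio rule ignores
    pulse_duration_s: float = 0.6
    mm_gain: float = 1.0 / 6.0


class RespirationConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    period_range: tuple[float, float] = (3.0, 5.0)
    amplitude: float = 0.0          # per-breath fast transient, FM channel
    slow_amplitude: float = 0.0     # continuous quasi-sinusoid near 0.3 Hz
    rem_episodes: int = 0
    rem_duration_range: tuple[float, float] = (600.0, 1200.0)
    quiet_gain: float = 0.3         # amplitude scale outside REM episodes


class MaternalMoveConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    rate_per_hour: float = 0.0
    duration_range: tuple[float, float] = (2.0, 8.0)
    amplitude: float = 30.0
    fm_crosstalk: float = 0.5


class PlmTrainConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_trains: int = 0
    run_length_range: tuple[int, int] = (5, 10)
    interval_range: tuple[float, float] = (20.0, 40.0)
    movement_duration_s: float = 1.2
    amplitude: float = 25.0
    fm_crosstalk: float = 0.4


class HiccupTrainConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_bouts: int = 0
    period_s: float = 2.0
    period_jitter_s: float = 0.15
    bout_duration_range: tuple[float, float] = (300.0, 900.0)
    pulse_duration_s: float = 0.6
    amplitude: float = 22.0


class WakeConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_episodes: int = 0
    duration_range: tuple[float, float] = (60.0, 180.0)
    events_per_minute: float = 6.0
    amplitude: float = 30.0
    fm_crosstalk: float = 0.5


class RestroomConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_episodes: int = 0
    duration_range: tuple[float, float] = (360.0, 600.0)
    events_per_minute: float = 8.0
    amplitude: float = 30.0
    fm_crosstalk: float = 0.5


class SimulationConfig(BaseModel):
    """Full parameterization of one simulated night."""

    model_config = ConfigDict(extra="forbid")

    duration_s: float = 3600.0
    sampling_rate: float = 100.0
    seed: int = 0
    subject_id: str = "sim"
    gestational_week: int = 32
    noise_amp: float = 0.2
    fm_mm_gain_ratio: float = 6.0
    fetal_bursts: FetalBurstConfig = FetalBurstConfig()
    heartbeat: HeartbeatConfig = HeartbeatConfig()
    respiration: RespirationConfig = RespirationConfig()
    maternal_moves: MaternalMoveConfig = MaternalMoveConfig()
    plm: PlmTrainConfig = PlmTrainConfig()
    hiccups: HiccupTrainConfig = HiccupTrainConfig()
    wake: WakeConfig = WakeConfig()
    restroom: RestroomConfig = RestroomConfig()

    @model_validator(mode="after")
    def _check(self) -> "SimulationConfig":
        if self.duration_s <= 60:
            raise ConfigurationError("duration_s must exceed 60 s")
        if self.sampling_rate < 20:
            raise ConfigurationError("sampling_rate must be at least 20 Hz")
        if self.noise_amp < 0:
            raise ConfigurationError("noise_amp must be non-negative")
        return self


@dataclass(frozen=True)
class Annotation:
    cls: str
    start_s: float
    end_s: float
    channel: str  # "FM", "MM" or "both"


@dataclass(frozen=True)
class GroundTruth:
    annotations: list[Annotation]

    def of_class(self, cls: str) -> list[Annotation]:
        return [a for a in self.annotations if a.cls == cls]


# ---------------------------------------------------------------------------
# Waveform primitives
# ---------------------------------------------------------------------------

def _bandlimited_burst(
    rng: np.random.Generator, n: int, fs: float, lo: float = 0.5, hi: float = 2.5
) -> np.ndarray:
    """Hann-windowed band-limited noise of unit peak amplitude."""
    if n < 4:
        return np.zeros(n)
    white = rng.standard_normal(n + int(2 * fs))
    sos = sps.butter(2, [lo, hi], btype="bandpass", fs=fs, output="sos")
    shaped = sps.sosfilt(sos, white)[int(fs) : int(fs) + n] * np.hanning(n)
    peak = np.max(np.abs(shaped))
    if peak > 0:
        shaped = shaped / peak
    return shaped


def _add(trace: np.ndarray, start_idx: int, wave: np.ndarray) -> None:
    """Add a waveform in place, clipped to the trace bounds."""
    if start_idx >= len(trace) or start_idx + len(wave) <= 0:
        return
    a = max(start_idx, 0)
    b = min(start_idx + len(wave), len(trace))
    trace[a:b] += wave[a - start_idx : b - start_idx]


def _poisson_times(
    rng: np.random.Generator,
    rate_per_hour: float,
    duration_s: float,
    margin_s: float,
    min_separation_s: float = 0.0,
) -> np.ndarray:
    """Homogeneous Poisson event onsets, thinned to a minimum separation."""
    n = rng.poisson(rate_per_hour * duration_s / 3600.0)
    times = np.sort(rng.uniform(margin_s, duration_s - margin_s, size=n))
    if min_separation_s > 0 and len(times) > 1:
        kept = [times[0]]
        for t in times[1:]:
            if t - kept[-1] >= min_separation_s:
                kept.append(t)
        times = np.array(kept)
    return times


# ---------------------------------------------------------------------------
# Simulator
# ---------------------------------------------------------------------------

def simulate_recording(cfg: SimulationConfig) -> tuple[Recording, GroundTruth]:
    """Render one simulated night and its exhaustive ground-truth annotations.

    The FM channel sums fetal bursts, hiccup pulses, heartbeat leak,
    respiration leak, maternal-movement crosstalk and the noise floor; the
    MM channel sums maternal movements, PLM, heartbeat at reduced gain and
    noise.  Continuous processes (heartbeat, respiration) are annotated as
    single covering intervals; discrete events are annotated individually.
    """
    rng = np.random.default_rng(cfg.seed)
    fs = cfg.sampling_rate
    n = int(round(cfg.duration_s * fs))
    fm = np.zeros(n)
    mm = np.zeros(n)
    ann: list[Annotation] = []
    margin = 15.0  # keep injected events clear of edge transients

    # --- occupancy map so episodic processes do not overlap each other ---
    busy: list[tuple[float, float]] = []

    def _place(duration: float, tries: int = 50) -> float | None:
        for _ in range(tries):
            t0 = rng.uniform(margin, cfg.duration_s - margin - duration)
            if all(t0 + duration <= s or t0 >= e for s, e in busy):
                busy.append((t0, t0 + duration))
                return t0
        return None

    # --- wake / restroom episodes (dense MM activity) ---
    for kind, kcfg in (("restroom", cfg.restroom), ("wake", cfg.wake)):
        for _ in range(kcfg.n_episodes):
            dur = rng.uniform(*kcfg.duration_range)
            t0 = _place(dur)
            if t0 is None:
                continue
            # align to minute grid so every covered clock minute is dense
            t0 = np.floor(t0 / 60.0) * 60.0
            n_moves = max(int(kcfg.events_per_minute * dur / 60.0), 1)
            onsets = np.sort(rng.uniform(t0, t0 + dur - 1.5, size=n_moves))
            for t in onsets:
                mdur = rng.uniform(0.5, 1.5)
                w = _bandlimited_burst(rng, int(mdur * fs), fs) * kcfg.amplitude
                _add(mm, int(t * fs), w)
                _add(fm, int(t * fs), w * kcfg.fm_crosstalk)
            ann.append(Annotation(kind, t0, t0 + dur, "both"))

    # --- hiccup bouts (rhythmic short FM pulses) ---
    for _ in range(cfg.hiccups.n_bouts):
        dur = rng.uniform(*cfg.hiccups.bout_duration_range)
        t0 = _place(dur)
        if t0 is None:
            continue
        t = t0
        while t < t0 + dur:
            pdur = cfg.hiccups.pulse_duration_s
            w = _bandlimited_burst(rng, int(pdur * fs), fs) * cfg.hiccups.amplitude
            _add(fm, int(t * fs), w)
            ann.append(Annotation("hiccup", t, t + pdur, "FM"))
            t += cfg.hiccups.period_s + rng.normal(0, cfg.hiccups.period_jitter_s)

    # --- PLM trains on the MM channel ---
    for _ in range(cfg.plm.n_trains):
        run_len = int(rng.integers(*cfg.plm.run_length_range, endpoint=True))
        intervals = rng.uniform(*cfg.plm.interval_range, size=run_len - 1)
        train_dur = float(np.sum(intervals)) + cfg.plm.movement_duration_s
        t0 = _place(train_dur)
        if t0 is None:
            continue
        t = t0
        for k in range(run_len):
            mdur = cfg.plm.movement_duration_s + rng.uniform(-0.1, 0.1)
            w = _bandlimited_burst(rng, int(mdur * fs), fs) * cfg.plm.amplitude
            _add(mm, int(t * fs), w)
            _add(fm, int(t * fs), w * cfg.plm.fm_crosstalk)
            ann.append(Annotation("plm", t, t + mdur, "both"))
            if k < run_len - 1:
                t += intervals[k]

    # --- isolated maternal gross movements ---
    mv = cfg.maternal_moves
    for t in _poisson_times(rng, mv.rate_per_hour, cfg.duration_s, margin, 12.0):
        if not all(t + 10.0 <= s or t >= e for s, e in busy):
            continue
        dur = rng.uniform(*mv.duration_range)
        w = _bandlimited_burst(rng, int(dur * fs), fs) * mv.amplitude
        _add(mm, int(t * fs), w)
        _add(fm, int(t * fs), w * mv.fm_crosstalk)
        ann.append(Annotation("maternal_move", t, t + dur, "both"))

    # --- fetal movement bursts ---
    fb = cfg.fetal_bursts
    for t in _poisson_times(
        rng, fb.rate_per_hour, cfg.duration_s, margin, fb.min_separation_s
    ):
        if not all(t + 5.0 <= s or t >= e for s, e in busy):
            continue
        dur = rng.uniform(*fb.duration_range)
        amp = rng.uniform(*fb.amplitude_range)
        w = _bandlimited_burst(rng, int(dur * fs), fs) * amp
        _add(fm, int(t * fs), w)
        ann.append(Annotation("fetal_burst", t, t + dur, "FM"))

    # --- maternal heartbeat (continuous, both channels) ---
    hb = cfg.heartbeat
    if hb.amplitude > 0:
        period = 1.0 / hb.frequency_hz
        pulse_n = max(int(hb.pulse_duration_s * fs), 2)
        pulse = np.sin(2 * np.pi * np.arange(pulse_n) / pulse_n)  # one biphasic cycle
        t = 0.0
        while t < cfg.duration_s:
            jt = t + rng.normal(0, hb.jitter_s)
            _add(fm, int(jt * fs), pulse * hb.amplitude)
            _add(mm, int(jt * fs), pulse * hb.amplitude * hb.mm_gain)
            t += period
        ann.append(Annotation("heartbeat", 0.0, cfg.duration_s, "both"))

    # --- maternal respiration (continuous; irregular/large during REM) ---
    rp = cfg.respiration
    if rp.amplitude > 0 or rp.slow_amplitude > 0:
        rem: list[tuple[float, float]] = []
        # REM episodes concentrate in the final third of the night
        rem_lo = max(margin, 2.0 * cfg.duration_s / 3.0)
        for _ in range(rp.rem_episodes):
            dur = rng.uniform(*rp.rem_duration_range)
            dur = min(dur, cfg.duration_s - margin - rem_lo)
            if dur <= 60:
                continue
            t0 = rng.uniform(rem_lo, cfg.duration_s - margin - dur)
            rem.append((t0, t0 + dur))
            ann.append(Annotation("respiration", t0, t0 + dur, "FM"))
        t = 0.0
        while t < cfg.duration_s:
            period = rng.uniform(*rp.period_range)
            in_rem = any(s <= t < e for s, e in rem)
            gain = 1.0 if in_rem else rp.quiet_gain
            if rp.slow_amplitude > 0:
                k = np.arange(int(period * fs))
                slow = np.sin(2 * np.pi * k / max(len(k), 1))
                _add(fm, int(t * fs), slow * rp.slow_amplitude * gain)
            if rp.amplitude > 0:
                fast_n = int(0.5 * fs)
                amp = rp.amplitude * gain * rng.uniform(0.7, 1.3)
                _add(fm, int(t * fs), _bandlimited_burst(rng, fast_n, fs) * amp)
            t += period
        if not rem:
            ann.append(Annotation("respiration", 0.0, cfg.duration_s, "FM"))

    # --- noise floor ---
    if cfg.noise_amp > 0:
        fm += rng.normal(0, cfg.noise_amp, size=n)
        mm += rng.normal(0, cfg.noise_amp / cfg.fm_mm_gain_ratio * 6.0, size=n)

    ann.sort(key=lambda a: (a.start_s, a.cls))
    rec = Recording(
        subject_id=cfg.subject_id,
        gestational_week=cfg.gestational_week,
        sampling_rate=fs,
        fm=fm,
        mm=mm,
    )
    return rec, GroundTruth(annotations=ann)


def scenario_library() -> dict[str, SimulationConfig]:
    """Named fixed-seed scenarios spanning every artifact class."""
    lib = {
        "quiet_night": SimulationConfig(
            seed=101,
            duration_s=3600.0,
            fetal_bursts=FetalBurstConfig(
                rate_per_hour=60.0, amplitude_range=(12.0, 25.0)
            ),
            heartbeat=HeartbeatConfig(amplitude=1.5),
        ),
        "rem_breathing": SimulationConfig(
            seed=202,
            duration_s=3600.0,
            fetal_bursts=FetalBurstConfig(rate_per_hour=30.0),
            heartbeat=HeartbeatConfig(amplitude=1.5),
            respiration=RespirationConfig(
                amplitude=1.6,
                slow_amplitude=1.0,
                rem_episodes=1,
                rem_duration_range=(900.0, 1100.0),
            ),
        ),
        "plm_sleeper": SimulationConfig(
            seed=303,
            duration_s=3600.0,
            fetal_bursts=FetalBurstConfig(rate_per_hour=30.0),
            heartbeat=HeartbeatConfig(amplitude=1.5),
            plm=PlmTrainConfig(n_trains=2),
        ),
        "hiccup_night": SimulationConfig(
            seed=404,
            duration_s=3600.0,
            fetal_bursts=FetalBurstConfig(rate_per_hour=30.0),
            heartbeat=HeartbeatConfig(amplitude=1.5),
            hiccups=HiccupTrainConfig(n_bouts=1, bout_duration_range=(480.0, 720.0)),
        ),
        "restless_night": SimulationConfig(
            seed=505,
            duration_s=3600.0,
            fetal_bursts=FetalBurstConfig(rate_per_hour=40.0),
            heartbeat=HeartbeatConfig(amplitude=1.5),
            maternal_moves=MaternalMoveConfig(rate_per_hour=20.0),
            wake=WakeConfig(n_episodes=2),
            restroom=RestroomConfig(n_episodes=1),
        ),
    }
    return lib
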