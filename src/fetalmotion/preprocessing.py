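"""Band-limiting and notch filtering of the two accelerometer channels.

The fetal-movement (FM) channel is high-passed at 0.5 Hz, low-passed at
2.5 Hz and notched at 1.0 Hz (maternal heartbeat) and 0.3 Hz (maternal
respiration).  The maternal-movement (MM) channel receives the same chain
without the 0.3 Hz notch.  Filters default to zero-phase (forward-backward)
application so event timings stay aligned across channels.
"""

from __future__ import annotations

from dataclasses import replace
from typing import TYPE_CHECKING

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator
from scipy import signal

from .errors import ConfigurationError, InputError

if TYPE_CHECKING:  # pragma: no cover
    from .io_formats import Recording

#: Seconds of output flagged as unreliable at each end of a filtered record.
EDGE_TRANSIENT_S = 10.0


class FilterConfig(BaseModel):
    """Corner/notch frequencies of the pre-processing chain (Hz)."""

    model_config = ConfigDict(extra="forbid")

    highpass_hz: float = 0.5          # 1st order, -6 dB/oct
    lowpass_hz: float = 2.5           # 2nd order, -12 dB/oct
    notch_heartbeat_hz: float = 1.0   # both channels
    notch_respiration_hz: float = 0.3  # FM channel only
    notch_heartbeat_bw_hz: float = 0.2
    notch_respiration_bw_hz: float = 0.1
    zero_phase: bool = True
    enable_respiration_notch: bool = True

    @model_validator(mode="after")
    def _check_ordering(self) -> "FilterConfig":
        # the respiration notch sits below the high-pass corner (0.3 < 0.5),
        # deepening the stop-band rejection there
        if not (0 < self.notch_respiration_hz < self.notch_heartbeat_hz < self.lowpass_hz):
            raise ConfigurationError(
                "notch frequencies must satisfy 0 < respiration < heartbeat < lowpass"
            )
        if not (0 < self.highpass_hz < self.lowpass_hz):
            raise ConfigurationError("highpass corner must lie below the lowpass corner")
        if self.notch_heartbeat_bw_hz <= 0 or self.notch_respiration_bw_hz <= 0:
            raise ConfigurationError("notch bandwidths must be positive")
        return self


def _design_chain(cfg: FilterConfig, fs: float, channel: str) -> list[tuple]:
    """Return the cascade of (b, a) sections for one channel."""
    if fs <= 2 * cfg.lowpass_hz:
        raise ConfigurationError(
            f"sampling rate {fs} Hz too low for lowpass at {cfg.lowpass_hz} Hz"
        )
    sections = []
    b, a = signal.butter(1, cfg.highpass_hz, btype="highpass", fs=fs)
    sections.append((b, a))
    b, a = signal.butter(2, cfg.lowpass_hz, btype="lowpass", fs=fs)
    sections.append((b, a))
    b, a = signal.iirnotch(
        cfg.notch_heartbeat_hz, cfg.notch_heartbeat_hz / cfg.notch_heartbeat_bw_hz, fs=fs
    )
    sections.append((b, a))
    if channel == "FM" and cfg.enable_respiration_notch:
        b, a = signal.iirnotch(
            cfg.notch_respiration_hz,
            cfg.notch_respiration_hz / cfg.notch_respiration_bw_hz,
            fs=fs,
        )
        sections.append((b, a))
    return sections


def filter_channel(
    x: np.ndarray, fs: float, cfg: FilterConfig, channel: str
) -> np.ndarray:
    """Apply the pre-processing chain to a single channel.

    Parameters
    ----------
    x : array of acceleration samples (device units)
    fs : sampling rate in Hz
    channel : ``"FM"`` or ``"MM"`` — selects whether the respiration notch
        is included.
    """
    if channel not in ("FM", "MM"):
        raise InputError(f"unknown channel {channel!r}")
    y = np.asarray(x, dtype=float)
    for b, a in _design_chain(cfg, fs, channel):
        if cfg.zero_phase:
            y = signal.filtfilt(b, a, y)
        else:
            y = signal.lfilter(b, a, y)
    return y


def apply_preprocessing(recording: "Recording", cfg: FilterConfig) -> "Recording":
    """Filter both channels of a recording, returning a new Recording.

    Raises
    ------
    InputError
        If the recording is shorter than ``10 / highpass_hz`` seconds, so
        that the filter transient would dominate the output.
    ConfigurationError
        If the sampling rate cannot support the low-pass corner.
    """
    min_duration = 10.0 / cfg.highpass_hz
    if recording.duration_s < min_duration:
        raise InputError(
            f"recording of {recording.duration_s:.1f} s is shorter than the "
            f"{min_duration:.1f} s needed to absorb filter transients"
        )
    fs = recording.sampling_rate
    return replace(
        recording,
        fm=filter_channel(recording.fm, fs, cfg, "FM"),
        mm=filter_channel(recording.mm, fs, cfg, "MM"),
    )
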