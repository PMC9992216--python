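"""Filtering, SRD truncation and overlapping window segmentation.

The analysis pipeline filters each recording (20–450 Hz band-pass plus a
power-line notch), truncates it to a signal-recording-duration (SRD) group,
and slices every channel into overlapping analysis windows (150 ms length,
100 ms increment by default) from which features are computed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .simulate import Recording

#: Canonical SRD groups studied (seconds).
SRD_LENGTHS_S: tuple[float, ...] = (1.0, 5.0, 10.0, 15.0, 20.0)


@dataclass(frozen=True)
class SegmentationParams:
    """Overlapping segmentation scheme: window length and increment (ms)."""

    window_ms: float = 150.0
    increment_ms: float = 100.0

    def __post_init__(self) -> None:
        if not (0 < self.increment_ms <= self.window_ms):
            raise ValueError("require 0 < increment_ms <= window_ms")

    def window_samples(self, fs: float) -> int:
        return int(round(fs * self.window_ms / 1000.0))

    def step_samples(self, fs: float) -> int:
        return int(round(fs * self.increment_ms / 1000.0))


@dataclass(frozen=True)
class SRDGroup:
    """A signal-recording-duration group (seconds of signal used)."""

    length_s: float

    def __post_init__(self) -> None:
        if self.length_s <= 0:
            raise ValueError("length_s must be positive")


@dataclass
class WindowSegment:
    """One analysis window of one channel; the unit all features consume."""

    x: np.ndarray
    channel_index: int
    window_index: int
    class_code: str


def n_windows(n_samples: int, window: int, step: int) -> int:
    """Number of full windows: floor((N - W)/S) + 1; trailing samples drop."""
    if n_samples < window:
        raise ValueError("signal shorter than one window")
    return (n_samples - window) // step + 1


def bandpass_notch(
    recording: Recording,
    low_hz: float = 20.0,
    high_hz: float = 450.0,
    notch_hz: float = 50.0,
    notch_q: float = 30.0,
) -> Recording:
    """Zero-phase 4th-order Butterworth band-pass + IIR notch.

    Forward-backward application keeps window boundaries phase-aligned with
    the raw signal. The notch removes power-line interference; default 50 Hz
    (set ``notch_hz=60`` for 60 Hz mains).
    """
    fs = recording.fs
    if not (0 < low_hz < high_hz < fs / 2):
        raise ValueError("require 0 < low < high < fs/2")
    if not (0 < notch_hz < fs / 2):
        raise ValueError("notch_hz must lie in (0, fs/2)")
    sos = sps.butter(4, (low_hz, high_hz), btype="bandpass", fs=fs, output="sos")
    out = sps.sosfiltfilt(sos, recording.data, axis=-1)
    b, a = sps.iirnotch(notch_hz, notch_q, fs=fs)
    out = sps.filtfilt(b, a, out, axis=-1)
    return Recording(
        data=out,
        fs=fs,
        subject_id=recording.subject_id,
        class_code=recording.class_code,
        trial_index=recording.trial_index,
    )


def truncate_to_srd(
    recording: Recording, srd: SRDGroup, offset_s: float = 0.0
) -> Recording:
    """Crop to ``srd.length_s`` seconds starting at ``offset_s`` (default: prefix).

    The prefix convention treats shorter SRD groups as nested leading
    portions of the full hold; ``offset_s`` allows random-offset crops.
    """
    n_keep = int(round(recording.fs * srd.length_s))
    start = int(round(recording.fs * offset_s))
    if start + n_keep > recording.n_samples:
        raise ValueError(
            f"requested {srd.length_s} s at offset {offset_s} s exceeds the "
            f"{recording.duration_s:.3f} s recording"
        )
    return Recording(
        data=recording.data[:, start : start + n_keep],
        fs=recording.fs,
        subject_id=recording.subject_id,
        class_code=recording.class_code,
        trial_index=recording.trial_index,
    )


def window_array(recording: Recording, params: SegmentationParams) -> np.ndarray:
    """All analysis windows as an array of shape (n_windows, n_channels, W)."""
    w = params.window_samples(recording.fs)
    s = params.step_samples(recording.fs)
    if recording.n_samples < w:
        raise ValueError("recording shorter than one analysis window")
    view = np.lib.stride_tricks.sliding_window_view(recording.data, w, axis=-1)
    return view[:, ::s, :].transpose(1, 0, 2)


def segment_windows(
    recording: Recording, params: SegmentationParams
) -> list[WindowSegment]:
    """Windows as labeled per-channel segments, ordered (window, channel)."""
    arr = window_array(recording, params)
    return [
        WindowSegment(
            x=arr[wi, ci],
            channel_index=ci,
            window_index=wi,
            class_code=recording.class_code,
        )
        for wi in range(arr.shape[0])
        for ci in range(arr.shape[1])
    ]
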