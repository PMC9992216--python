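"""Synthetic multichannel surface-EMG generator.

Emulates the statistical structure of an 8-electrode forearm sEMG acquisition:
15 finger-gesture classes (5 single-finger flexions, 10 combined gestures),
3 trials per class, 20 s of sustained contraction per trial, band-limited
20–450 Hz interference-pattern activity with class-specific per-channel
amplitude distribution, subject- and trial-level gain variability, additive
broadband noise, and optional fatigue-like drift that grows over the hold.

The carrier model is band-pass filtered white Gaussian noise — the standard
surrogate for the interference pattern of many superposed motor-unit action
potentials — amplitude-modulated per channel by a gesture-specific gain
vector. Each single finger projects a smooth spatial activation bump across
the electrode ring; combined gestures superpose the bumps of their component
fingers, which makes classes related in a physiologically plausible way
(combined gestures sharing fingers are closer in feature space).

Every recording is reproducible in isolation: its random stream is derived
from (master seed, subject, class, trial) via ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import signal as sps

#: The 15 gesture class codes: single-finger flexions (Thumb, Index, Middle,
#: Ring, Little), then the combined gestures including hand close (HC).
CLASS_CODES: tuple[str, ...] = (
    "T", "I", "M", "R", "L",
    "TI", "TM", "TR", "TL", "HC",
    "IM", "MR", "RL", "IMR", "MRL",
)

N_CHANNELS = 8

_FINGERS = ("T", "I", "M", "R", "L")

#: Component fingers of each gesture class.
GESTURE_COMPONENTS: dict[str, tuple[str, ...]] = {
    "T": ("T",), "I": ("I",), "M": ("M",), "R": ("R",), "L": ("L",),
    "TI": ("T", "I"), "TM": ("T", "M"), "TR": ("T", "R"), "TL": ("T", "L"),
    "HC": ("T", "I", "M", "R", "L"),
    "IM": ("I", "M"), "MR": ("M", "R"), "RL": ("R", "L"),
    "IMR": ("I", "M", "R"), "MRL": ("M", "R", "L"),
}

# Substream tags keep the per-purpose random streams disjoint.
_TAG_PROFILE, _TAG_SUBJECT, _TAG_RECORDING = 11, 23, 37


@dataclass(frozen=True)
class GestureProfile:
    """Spatial activation pattern of one gesture class over the 8 channels."""

    class_code: str
    channel_gains: np.ndarray  # shape (8,), non-negative amplitude multipliers
    envelope_shape: str = "constant"  # "constant" | "trapezoid"

    def __post_init__(self) -> None:
        gains = np.asarray(self.channel_gains, dtype=float)
        object.__setattr__(self, "channel_gains", gains)
        if self.class_code not in CLASS_CODES:
            raise ValueError(f"unknown class code {self.class_code!r}")
        if gains.shape != (N_CHANNELS,):
            raise ValueError(f"channel_gains must have shape ({N_CHANNELS},)")
        if np.any(gains < 0) or not np.any(gains > 0):
            raise ValueError("gains must be non-negative with at least one > 0")
        if self.envelope_shape not in ("constant", "trapezoid"):
            raise ValueError(f"unknown envelope shape {self.envelope_shape!r}")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic acquisition protocol.

    Defaults mirror the emulated protocol: 8 subjects, 3 trials, 4000 Hz,
    20 s of active contraction per class per trial, 20–450 Hz signal band.
    ``snr_db`` is the power ratio of the class-modulated carrier to the
    additive broadband noise floor; ``drift_strength`` scales the fatigue
    drift (0 disables it); ``subject_variability`` / ``trial_variability``
    are log-normal sigmas of per-channel gain perturbations; ``fluctuation``
    is the log-amplitude std of the slow (< 1 Hz) contraction-force
    fluctuation shared by all channels within a recording.
    """

    n_subjects: int = 8
    n_trials: int = 3
    fs: float = 4000.0
    duration_s: float = 20.0
    band: tuple[float, float] = (20.0, 450.0)
    snr_db: float = -3.0
    drift_strength: float = 2.0
    subject_variability: float = 0.10
    trial_variability: float = 0.05
    fluctuation: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        low, high = self.band
        if not (0 < low < high):
            raise ValueError("band must satisfy 0 < low < high")
        if self.fs <= 2 * high:
            raise ValueError("fs must exceed twice the upper band edge")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.n_trials < 1 or self.n_subjects < 1:
            raise ValueError("n_subjects and n_trials must be >= 1")
        if self.drift_strength < 0:
            raise ValueError("drift_strength must be >= 0")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.duration_s))


@dataclass
class Recording:
    """One subject/class/trial signal block: channels x samples."""

    data: np.ndarray  # shape (8, N)
    fs: float
    subject_id: int
    class_code: str
    trial_index: int  # 1-based

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != N_CHANNELS:
            raise ValueError(f"data must be ({N_CHANNELS}, N)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains NaN or Inf")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


def _finger_bumps(rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Spatial gain bump of each single finger across the electrode ring."""
    centers = {"T": 0.8, "I": 2.2, "M": 3.6, "R": 5.0, "L": 6.4}
    ch = np.arange(N_CHANNELS, dtype=float)
    bumps = {}
    for f in _FINGERS:
        c = centers[f] + rng.uniform(-0.3, 0.3)
        width = 1.4 + rng.uniform(-0.2, 0.2)
        bumps[f] = np.exp(-0.5 * ((ch - c) / width) ** 2)
    return bumps


def default_profiles(seed: int = 0) -> list[GestureProfile]:
    """Deterministic set of 15 separable gesture profiles.

    Single fingers get Gaussian spatial bumps over the channels; combined
    gestures superpose their component bumps (scaled by 1/sqrt(#fingers) to
    keep amplitudes comparable) with a small per-class multiplicative jitter
    so all 15 gain vectors are pairwise distinct.
    """
    rng = np.random.default_rng(np.random.SeedSequence([_TAG_PROFILE, int(seed)]))
    bumps = _finger_bumps(rng)
    profiles = []
    for code in CLASS_CODES:
        parts = GESTURE_COMPONENTS[code]
        gains = np.sum([bumps[f] for f in parts], axis=0) / np.sqrt(len(parts))
        gains = gains * np.exp(0.05 * rng.standard_normal(N_CHANNELS))
        profiles.append(GestureProfile(class_code=code, channel_gains=gains))
    return profiles


def _bandpass_sos(band: tuple[float, float], fs: float) -> np.ndarray:
    return sps.butter(4, band, btype="bandpass", fs=fs, output="sos")


def _drift_lowpass(x: np.ndarray, fs: float, drift: float, high: float) -> np.ndarray:
    """Blockwise first-order low-pass with cutoff falling over the recording.

    Cutoff schedule: fc(u) = high / (1 + drift * u^2) at time fraction u,
    applied in 20 blocks with filter state carried across block boundaries.
    """
    n = x.shape[-1]
    n_blocks = 20
    edges = np.linspace(0, n, n_blocks + 1).astype(int)
    out = np.empty_like(x)
    zi = np.zeros((x.shape[0], 1))
    for i in range(n_blocks):
        s, e = edges[i], edges[i + 1]
        if s == e:
            continue
        u = 0.5 * (s + e) / n
        fc = min(high / (1.0 + drift * u * u), 0.49 * fs)
        b, a = sps.butter(1, fc, btype="low", fs=fs)
        out[:, s:e], zi = sps.lfilter(b, a, x[:, s:e], axis=-1, zi=zi)
    return out


def _envelope(shape: str, n: int) -> np.ndarray:
    if shape == "constant":
        return np.ones(n)
    # trapezoid: 10% linear ramp up, plateau, 10% ramp down
    ramp = max(int(round(0.1 * n)), 1)
    env = np.ones(n)
    env[:ramp] = np.linspace(0.0, 1.0, ramp, endpoint=False)
    env[n - ramp:] = np.linspace(1.0, 0.0, ramp)
    return env


def _force_fluctuation(
    rng: np.random.Generator, n: int, fs: float, sigma: float
) -> np.ndarray:
    """Slow multiplicative contraction-force fluctuation, exp(sigma * z(t)).

    z is white noise low-passed at 0.8 Hz and renormalized to unit variance,
    so the 150 ms analysis windows see a locally constant gain that wanders
    over the recording the way voluntary contraction force does.
    """
    if sigma <= 0:
        return np.ones(n)
    z = rng.standard_normal(n)
    sos = sps.butter(2, min(0.8, 0.4 * fs / 2), btype="low", fs=fs, output="sos")
    z = sps.sosfiltfilt(sos, z)
    z /= max(np.std(z), 1e-12)
    return np.exp(sigma * z)


def _subject_gain(config: SimConfig, subject_id: int) -> np.ndarray:
    rng = np.random.default_rng(
        np.random.SeedSequence([_TAG_SUBJECT, int(config.seed), int(subject_id)])
    )
    return np.exp(config.subject_variability * rng.standard_normal(N_CHANNELS))


def generate_recording(
    profile: GestureProfile,
    config: SimConfig,
    subject_id: int = 0,
    trial_index: int = 1,
) -> Recording:
    """Generate one labeled recording.

    Each channel is a unit-RMS band-limited Gaussian carrier, amplitude
    modulated by ``profile gain x subject perturbation x trial perturbation
    x activation envelope x force fluctuation x drift``, plus white noise
    whose level is set by
    ``snr_db`` relative to the recording-mean clean-signal RMS (so channels
    with near-zero gesture gain still carry a realistic noise floor).
    Deterministic given (config.seed, subject_id, class_code, trial_index).
    """
    n = config.n_samples
    class_index = CLASS_CODES.index(profile.class_code)
    rng = np.random.default_rng(
        np.random.SeedSequence(
            [_TAG_RECORDING, int(config.seed), int(subject_id), class_index, int(trial_index)]
        )
    )

    trial_gain = np.exp(config.trial_variability * rng.standard_normal(N_CHANNELS))
    force = _force_fluctuation(rng, n, config.fs, config.fluctuation)
    carrier = rng.standard_normal((N_CHANNELS, n))
    carrier = sps.sosfiltfilt(_bandpass_sos(config.band, config.fs), carrier, axis=-1)
    carrier /= np.sqrt(np.mean(carrier**2, axis=-1, keepdims=True))

    if config.drift_strength > 0:
        carrier = _drift_lowpass(carrier, config.fs, config.drift_strength, config.band[1])

    u = np.arange(n) / n
    drift_amp = 1.0 + 0.5 * config.drift_strength * u**2
    env = _envelope(profile.envelope_shape, n)
    gains = profile.channel_gains * _subject_gain(config, subject_id) * trial_gain
    clean = carrier * gains[:, None] * (env * drift_amp * force)[None, :]
    if config.drift_strength > 0:
        # fatigue-induced co-contraction: a class-independent broad activation
        # component recruited progressively, blurring the spatial pattern late
        # in the hold
        cocon = rng.standard_normal((N_CHANNELS, n))
        cocon = sps.sosfiltfilt(_bandpass_sos(config.band, config.fs), cocon, axis=-1)
        cocon /= np.sqrt(np.mean(cocon**2, axis=-1, keepdims=True))
        cocon_amp = 0.5 * config.drift_strength * np.mean(gains) * u**2
        clean = clean + cocon * (cocon_amp * env * force)[None, :]

    ref_rms = np.sqrt(np.mean(clean**2))
    noise_std = ref_rms * 10.0 ** (-config.snr_db / 20.0)
    # noise passes the same acquisition band-pass as the signal, so snr_db is
    # the in-band signal-to-noise ratio (out-of-band noise is removed by the
    # recording chain before it ever reaches the pipeline)
    noise = sps.sosfiltfilt(_bandpass_sos(config.band, config.fs),
                            rng.standard_normal((N_CHANNELS, n)), axis=-1)
    noise /= np.sqrt(np.mean(noise**2, axis=-1, keepdims=True))
    data = clean + noise_std * noise
    return Recording(
        data=data,
        fs=config.fs,
        subject_id=int(subject_id),
        class_code=profile.class_code,
        trial_index=int(trial_index),
    )


def generate_dataset(
    config: SimConfig, profiles: Sequence[GestureProfile] | None = None
) -> list[Recording]:
    """Full factorial set: n_subjects x 15 classes x n_trials recordings."""
    if profiles is None:
        profiles = default_profiles(config.seed)
    return [
        generate_recording(p, config, subject_id=s, trial_index=t)
        for s in range(config.n_subjects)
        for p in profiles
        for t in range(1, config.n_trials + 1)
    ]


# ---------------------------------------------------------------------------
# Dataset persistence: one CSV (samples x channels) + JSON sidecar per
# recording, plus a manifest. Any loader producing Recording objects can
# replace this module — the pipeline depends only on the Recording contract.

def _rec_stem(rec: Recording) -> str:
    return f"s{rec.subject_id:02d}_{rec.class_code}_t{rec.trial_index}"


def save_dataset(recordings: Iterable[Recording], out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for rec in recordings:
        stem = _rec_stem(rec)
        np.savetxt(out / f"{stem}.csv", rec.data.T, delimiter=",", fmt="%.17g")
        sidecar = {
            "subject_id": rec.subject_id,
            "class_code": rec.class_code,
            "trial_index": rec.trial_index,
            "fs": rec.fs,
        }
        (out / f"{stem}.json").write_text(json.dumps(sidecar))
        entries.append({"data": f"{stem}.csv", "meta": f"{stem}.json"})
    manifest = out / "manifest.json"
    manifest.write_text(json.dumps({"recordings": entries}, indent=1))
    return manifest


def load_dataset(in_dir: str | Path) -> list[Recording]:
    root = Path(in_dir)
    manifest = json.loads((root / "manifest.json").read_text())
    recordings = []
    for entry in manifest["recordings"]:
        meta = json.loads((root / entry["meta"]).read_text())
        data = np.loadtxt(root / entry["data"], delimiter=",", ndmin=2).T
        recordings.append(Recording(data=data, **meta))
    return recordings
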