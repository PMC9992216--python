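"""Time-domain EMG feature sets: TD4 (Hudgins), NTDF, and RMS.

All operators act on the last axis, so the same function evaluates a single
window (1-D array or :class:`~emgsrd.preprocess.WindowSegment`) or a whole
batch of windows at once. Sample index convention is 1-based n in [1, k]
with k the window length; fractional powers are taken of |x_n| so negative
samples are well defined.

Feature sets
------------
TD4   : MAV, WL, ZC, SSC (zero crossings and slope-sign changes use an
        amplitude threshold, default 0.01).
NTDF  : SIS (integral square), normRSD1/normRSD2 (RMS of first/second
        differences, normalized by window length), normLogDet (length-
        normalized geometric mean of |x|), mMSR (mean square root), mASM
        (mean of |x| raised to a piecewise exponent: 0.50 in the middle half
        of the window, 0.75 in the outer quarters).
RMS   : root mean square.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .preprocess import SRDGroup, SegmentationParams, WindowSegment, truncate_to_srd, window_array
from .simulate import N_CHANNELS, Recording

_LOG_EPS = 1e-12


@dataclass(frozen=True)
class FeatureParams:
    """Amplitude thresholds for the crossing-count features."""

    zc_threshold: float = 0.01
    ssc_threshold: float = 0.01

    def __post_init__(self) -> None:
        if self.zc_threshold < 0 or self.ssc_threshold < 0:
            raise ValueError("thresholds must be >= 0")


def _samples(w) -> np.ndarray:
    x = w.x if isinstance(w, WindowSegment) else w
    return np.asarray(x, dtype=float)


def _require(x: np.ndarray, k_min: int, name: str) -> None:
    if x.shape[-1] < k_min:
        raise ValueError(f"{name} requires window length >= {k_min}")


def mav(w) -> float | np.ndarray:
    """Mean absolute value: (1/k) sum |x_n|."""
    x = _samples(w)
    _require(x, 1, "mav")
    return np.mean(np.abs(x), axis=-1)


def wl(w) -> float | np.ndarray:
    """Waveform length: sum of absolute successive differences."""
    x = _samples(w)
    _require(x, 2, "wl")
    return np.sum(np.abs(np.diff(x, axis=-1)), axis=-1)


def zc(w, params: FeatureParams = FeatureParams()) -> int | np.ndarray:
    """Thresholded zero crossings: sign changes with |x_n - x_{n+1}| >= thr."""
    x = _samples(w)
    _require(x, 2, "zc")
    crossing = (x[..., :-1] * x[..., 1:] < 0) & (
        np.abs(np.diff(x, axis=-1)) >= params.zc_threshold
    )
    return np.sum(crossing, axis=-1)


def ssc(w, params: FeatureParams = FeatureParams()) -> int | np.ndarray:
    """Thresholded slope-sign changes at interior samples."""
    x = _samples(w)
    _require(x, 3, "ssc")
    d_prev = x[..., 1:-1] - x[..., :-2]
    d_next = x[..., 1:-1] - x[..., 2:]
    return np.sum(d_prev * d_next >= params.ssc_threshold, axis=-1)


def td4_vector(w, params: FeatureParams = FeatureParams()) -> np.ndarray:
    """(MAV, WL, ZC, SSC) in fixed order."""
    return np.stack(
        [mav(w), wl(w), np.asarray(zc(w, params), float), np.asarray(ssc(w, params), float)],
        axis=-1,
    )


def sis(w) -> float | np.ndarray:
    """Simple integral square: sum x_n^2 (segment energy)."""
    x = _samples(w)
    _require(x, 1, "sis")
    return np.sum(x**2, axis=-1)


def norm_rsd(w, order: int) -> float | np.ndarray:
    """Normalized root squared descriptor of the 1st or 2nd difference.

    sqrt((1/k) sum d^(order)x[n]^2), normalizing by the window length k
    (not by the shorter difference length).
    """
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    x = _samples(w)
    _require(x, order + 1, f"norm_rsd{order}")
    d = np.diff(x, n=order, axis=-1)
    return np.sqrt(np.sum(d**2, axis=-1) / x.shape[-1])


def norm_logdet(w) -> float | np.ndarray:
    """Length-normalized geometric mean: exp(mean log(|x_n| + eps)) / k."""
    x = _samples(w)
    _require(x, 1, "norm_logdet")
    return np.exp(np.mean(np.log(np.abs(x) + _LOG_EPS), axis=-1)) / x.shape[-1]


def m_msr(w) -> float | np.ndarray:
    """Mean square root: (1/k) sum |x_n|^(1/2)."""
    x = _samples(w)
    _require(x, 1, "m_msr")
    return np.mean(np.sqrt(np.abs(x)), axis=-1)


def m_asm(w) -> float | np.ndarray:
    """Mean absolute-sample-to-power with piecewise exponent.

    |sum |x_n|^e(n)| / k with e(n) = 0.50 for 0.25k <= n <= 0.75k (1-based)
    and 0.75 elsewhere.
    """
    x = _samples(w)
    _require(x, 1, "m_asm")
    k = x.shape[-1]
    n = np.arange(1, k + 1)
    e = np.where((n >= 0.25 * k) & (n <= 0.75 * k), 0.50, 0.75)
    return np.abs(np.sum(np.abs(x) ** e, axis=-1)) / k


def ntdf_vector(w) -> np.ndarray:
    """(SIS, normRSD1, normRSD2, normLogDet, mMSR, mASM) in fixed order."""
    return np.stack(
        [sis(w), norm_rsd(w, 1), norm_rsd(w, 2), norm_logdet(w), m_msr(w), m_asm(w)],
        axis=-1,
    )


def rms(w) -> float | np.ndarray:
    """Root mean square: sqrt((1/k) sum x_n^2)."""
    x = _samples(w)
    _require(x, 1, "rms")
    return np.sqrt(np.mean(x**2, axis=-1))


FEATURE_SET_NAMES: tuple[str, ...] = ("TD4", "NTDF", "RMS")


def feature_set_functions(
    name: str, params: FeatureParams | None = None
) -> list[tuple[str, Callable[[np.ndarray], np.ndarray]]]:
    """(feature name, callable) pairs of a feature set, in fixed column order."""
    p = params or FeatureParams()
    if name == "TD4":
        return [
            ("mav", mav),
            ("wl", wl),
            ("zc", lambda x: zc(x, p)),
            ("ssc", lambda x: ssc(x, p)),
        ]
    if name == "NTDF":
        return [
            ("sis", sis),
            ("nrsd1", lambda x: norm_rsd(x, 1)),
            ("nrsd2", lambda x: norm_rsd(x, 2)),
            ("nlogdet", norm_logdet),
            ("mmsr", m_msr),
            ("masm", m_asm),
        ]
    if name == "RMS":
        return [("rms", rms)]
    raise ValueError(f"unknown feature set {name!r}; expected one of {FEATURE_SET_NAMES}")


@dataclass
class FeatureMatrix:
    """Windows x (channels * features) matrix with aligned per-row labels.

    Column order is channel-major: all features of channel 1, then channel 2,
    etc., so trained models are portable across runs.
    """

    values: np.ndarray
    labels: np.ndarray  # class code per row
    subjects: np.ndarray  # subject id per row
    trials: np.ndarray  # trial index per row
    columns: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.labels = np.asarray(self.labels)
        self.subjects = np.asarray(self.subjects)
        self.trials = np.asarray(self.trials)
        n = self.values.shape[0]
        if not (len(self.labels) == len(self.subjects) == len(self.trials) == n):
            raise ValueError("row metadata length mismatch")
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains NaN or Inf")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    def subset(self, mask: np.ndarray) -> "FeatureMatrix":
        return FeatureMatrix(
            values=self.values[mask],
            labels=self.labels[mask],
            subjects=self.subjects[mask],
            trials=self.trials[mask],
            columns=list(self.columns),
            meta=dict(self.meta),
        )

    @staticmethod
    def concat(parts: Sequence["FeatureMatrix"]) -> "FeatureMatrix":
        if not parts:
            raise ValueError("nothing to concatenate")
        cols = parts[0].columns
        if any(p.columns != cols for p in parts):
            raise ValueError("column mismatch between parts")
        return FeatureMatrix(
            values=np.concatenate([p.values for p in parts]),
            labels=np.concatenate([p.labels for p in parts]),
            subjects=np.concatenate([p.subjects for p in parts]),
            trials=np.concatenate([p.trials for p in parts]),
            columns=list(cols),
            meta=dict(parts[0].meta),
        )

    def to_csv(self, path: str | Path) -> None:
        """Write values as CSV plus a JSON sidecar with labels and metadata."""
        path = Path(path)
        np.savetxt(
            path, self.values, delimiter=",", fmt="%.17g", header=",".join(self.columns),
            comments="",
        )
        sidecar = {
            "labels": self.labels.tolist(),
            "subjects": np.asarray(self.subjects).tolist(),
            "trials": np.asarray(self.trials).tolist(),
            "columns": self.columns,
            "meta": self.meta,
        }
        path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(sidecar))

    @staticmethod
    def from_csv(path: str | Path) -> "FeatureMatrix":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(path.suffix + ".meta.json").read_text())
        values = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        return FeatureMatrix(
            values=values,
            labels=np.array(sidecar["labels"]),
            subjects=np.array(sidecar["subjects"]),
            trials=np.array(sidecar["trials"]),
            columns=sidecar["columns"],
            meta=sidecar["meta"],
        )


def build_feature_matrix(
    recordings: Sequence[Recording],
    srd: SRDGroup,
    seg_params: SegmentationParams,
    feature_set: str,
    feature_params: FeatureParams | None = None,
) -> FeatureMatrix:
    """Extract one feature set from all windows of all recordings.

    Each recording is truncated to the SRD group, segmented per channel, and
    the per-channel feature vectors of all 8 channels are concatenated
    channel-major. Rows are ordered by (recording, window index).
    """
    if not recordings:
        raise ValueError("no recordings given")
    fs = recordings[0].fs
    if any(r.fs != fs for r in recordings):
        raise ValueError("recordings have mixed sampling rates")
    funcs = feature_set_functions(feature_set, feature_params)
    names = [f"ch{c + 1}_{fname}" for c in range(N_CHANNELS) for fname, _ in funcs]

    blocks, labels, subjects, trials = [], [], [], []
    for rec in recordings:
        wins = window_array(truncate_to_srd(rec, srd), seg_params)  # (nw, C, W)
        feats = np.stack([np.asarray(f(wins), float) for _, f in funcs], axis=-1)
        nw = wins.shape[0]
        blocks.append(feats.reshape(nw, -1))  # channel-major flatten
        labels.append(np.full(nw, rec.class_code, dtype=object))
        subjects.append(np.full(nw, rec.subject_id))
        trials.append(np.full(nw, rec.trial_index))
    return FeatureMatrix(
        values=np.concatenate(blocks),
        labels=np.concatenate(labels).astype(str),
        subjects=np.concatenate(subjects),
        trials=np.concatenate(trials),
        columns=names,
        meta={
            "feature_set": feature_set,
            "srd_s": srd.length_s,
            "window_ms": seg_params.window_ms,
            "increment_ms": seg_params.increment_ms,
            "fs": fs,
        },
    )
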