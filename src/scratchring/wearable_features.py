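"""Windowing and spectral feature extraction for the wearable ring.

The ring carries a piezoelectric contact microphone (structure-borne
vibration, 10-bit counts 0-1023, 8 kHz) and a 3-axis accelerometer
(+-2 g, 400 Hz); the z axis, normal to the skin, is the one used.
Recordings are cut into 1-s windows with a 0.25-s stride, gaps are
linearly interpolated, and each window is described by the single-sided
DFT amplitude spectrum of each channel: amplitude at bin k of an N-point
channel is (2/N) |DFT(signal)|_k, so bin k of a 1-s window is k Hz.

Feature vectors concatenate microphone-then-accelerometer amplitudes:

* intensity task: mic bins 0-399 + acc bins 0-174 -> 575 features,
* detection task: mic bins 0-274 + acc bins 0-199 -> 475 features.

Min-max normalization is fitted on training data only and applied as a
plain affine map (test features may fall outside [0, 1]).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

MIC_RATE_HZ = 8000
ACC_RATE_HZ = 400
WINDOW_S = 1.0
STRIDE_S = 0.25

MIC_COUNTS_MAX = 1023.0
ACC_RANGE_G = 2.0

#: Retained (mic, acc) bin counts per task.
TASK_BINS: Dict[str, Tuple[int, int]] = {
    "intensity": (400, 175),
    "detection": (275, 200),
}

#: Windows within this many samples of nominal length are resampled.
MAX_LENGTH_JITTER = 2


class FeatureError(ValueError):
    pass


class UnrepairedWindowError(FeatureError):
    """Window length or content violates the fixed-length DFT contract."""


@dataclass
class WearableRecording:
    """A continuous two-channel wearable recording starting at t = 0."""

    mic: np.ndarray  # counts, 8 kHz
    acc_z: np.ndarray  # g, 400 Hz
    participant_id: str = ""
    mic_rate_hz: float = MIC_RATE_HZ
    acc_rate_hz: float = ACC_RATE_HZ

    def __post_init__(self) -> None:
        self.mic = np.asarray(self.mic, dtype=float)
        self.acc_z = np.asarray(self.acc_z, dtype=float)

    @property
    def duration_s(self) -> float:
        return self.mic.size / self.mic_rate_hz


@dataclass
class WearableWindow:
    """One 1-s window: 8000 microphone counts and 400 acc z samples."""

    mic: np.ndarray
    acc_z: np.ndarray
    window_start: float = 0.0
    participant_id: str = ""

    def __post_init__(self) -> None:
        self.mic = np.asarray(self.mic, dtype=float)
        self.acc_z = np.asarray(self.acc_z, dtype=float)


@dataclass
class FeatureVector:
    """Concatenated mic + acc single-sided DFT amplitudes for one window."""

    values: np.ndarray
    task: str
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expected = sum(TASK_BINS[self.task])
        if self.values.size != expected:
            raise FeatureError(
                f"{self.task} feature vector must have {expected} entries, "
                f"got {self.values.size}"
            )


@dataclass
class ScalerParams:
    """Per-feature min/max fitted on a training set."""

    minimum: np.ndarray
    maximum: np.ndarray
    fitted_on: str = ""

    def __post_init__(self) -> None:
        self.minimum = np.asarray(self.minimum, dtype=float)
        self.maximum = np.asarray(self.maximum, dtype=float)
        if np.any(self.maximum < self.minimum):
            raise FeatureError("scaler max < min")


def n_windows(duration_s: float, window_s: float = WINDOW_S, stride_s: float = STRIDE_S) -> int:
    """Number of fully contained windows: floor((T - w)/s) + 1."""
    if duration_s < window_s:
        return 0
    return int(np.floor((duration_s - window_s) / stride_s + 1e-9)) + 1


def window_signal(
    recording: WearableRecording,
    window_s: float = WINDOW_S,
    stride_s: float = STRIDE_S,
) -> List[WearableWindow]:
    """Cut a recording into fully contained windows at the given stride."""
    count = n_windows(recording.duration_s, window_s, stride_s)
    mic_len = int(round(window_s * recording.mic_rate_hz))
    acc_len = int(round(window_s * recording.acc_rate_hz))
    out = []
    for i in range(count):
        start = i * stride_s
        m0 = int(round(start * recording.mic_rate_hz))
        a0 = int(round(start * recording.acc_rate_hz))
        out.append(
            WearableWindow(
                mic=recording.mic[m0 : m0 + mic_len],
                acc_z=recording.acc_z[a0 : a0 + acc_len],
                window_start=start,
                participant_id=recording.participant_id,
            )
        )
    return out


def _repair_channel(sig: np.ndarray, nominal: int, name: str) -> np.ndarray:
    valid = ~np.isnan(sig)
    if valid.sum() < 2:
        raise UnrepairedWindowError(f"unrecoverable window: <2 valid {name} samples")
    if abs(sig.size - nominal) > MAX_LENGTH_JITTER:
        raise UnrepairedWindowError(
            f"{name} length {sig.size} deviates from nominal {nominal} "
            f"by more than {MAX_LENGTH_JITTER} samples"
        )
    idx = np.arange(sig.size)
    filled = np.interp(idx, idx[valid], sig[valid])
    if sig.size != nominal:
        # logger jitter: linearly resample onto the nominal grid
        filled = np.interp(
            np.linspace(0.0, sig.size - 1.0, nominal), idx.astype(float), filled
        )
    return filled


def repair_window(window: WearableWindow) -> WearableWindow:
    """Fill gaps and enforce exact 8000/400 channel lengths."""
    return WearableWindow(
        mic=_repair_channel(window.mic, MIC_RATE_HZ, "mic"),
        acc_z=_repair_channel(window.acc_z, ACC_RATE_HZ, "acc_z"),
        window_start=window.window_start,
        participant_id=window.participant_id,
    )


def single_sided_amplitude(signal: np.ndarray, n_bins: int) -> np.ndarray:
    """(2/N) |DFT| at bins 0..n_bins-1 (the 2/N factor includes bin 0)."""
    signal = np.asarray(signal, dtype=float)
    return (2.0 / signal.size) * np.abs(np.fft.rfft(signal)[:n_bins])


def dft_features(window: WearableWindow, task: str) -> FeatureVector:
    """Spectral amplitude features for one repaired window."""
    if task not in TASK_BINS:
        raise FeatureError(f"unknown task {task!r}")
    if window.mic.size != MIC_RATE_HZ or window.acc_z.size != ACC_RATE_HZ:
        raise UnrepairedWindowError(
            "unrepaired window: expected 8000 mic and 400 acc samples, got "
            f"{window.mic.size}/{window.acc_z.size}"
        )
    if np.isnan(window.mic).any() or np.isnan(window.acc_z).any():
        raise UnrepairedWindowError("unrepaired window: NaN samples present")
    k_mic, k_acc = TASK_BINS[task]
    values = np.concatenate(
        [
            single_sided_amplitude(window.mic, k_mic),
            single_sided_amplitude(window.acc_z, k_acc),
        ]
    )
    return FeatureVector(values=values, task=task)


def feature_matrix(windows: Iterable[WearableWindow], task: str) -> np.ndarray:
    """Stack per-window feature vectors into an (n, d) matrix."""
    rows = [dft_features(w, task).values for w in windows]
    if not rows:
        return np.empty((0, sum(TASK_BINS[task])))
    return np.vstack(rows)


def batch_spectra(signals: np.ndarray, n_bins: int) -> np.ndarray:
    """Single-sided amplitudes for a stack of equal-length signals."""
    signals = np.asarray(signals, dtype=float)
    return (2.0 / signals.shape[-1]) * np.abs(
        np.fft.rfft(signals, axis=-1)[..., :n_bins]
    )


def feature_slices(task: str) -> Dict[str, slice]:
    """Column ranges of the mic and acc blocks in a task's feature matrix."""
    k_mic, k_acc = TASK_BINS[task]
    return {"mic": slice(0, k_mic), "acc": slice(k_mic, k_mic + k_acc)}


def fit_scaler(train_features: np.ndarray, fitted_on: str = "") -> ScalerParams:
    """Fit per-feature min-max normalization on training data."""
    X = np.atleast_2d(np.asarray(train_features, dtype=float))
    if X.shape[0] < 1 or X.size == 0:
        raise FeatureError("cannot fit a scaler on an empty training set")
    return ScalerParams(X.min(axis=0), X.max(axis=0), fitted_on=fitted_on)


def apply_scaler(params: ScalerParams, features: np.ndarray) -> np.ndarray:
    """Affine min-max transform; constant training features map to 0."""
    X = np.asarray(features, dtype=float)
    span = params.maximum - params.minimum
    safe = np.where(span > 0, span, 1.0)
    out = (X - params.minimum) / safe
    return np.where(span > 0, out, 0.0)
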