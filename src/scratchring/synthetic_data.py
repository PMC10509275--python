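"""Synthetic scratching data with analytically known ground truth.

Two simulators make every pipeline stage testable without recorded
human data:

* **Tablet streams** -- single-contact scratch trajectories at 150 Hz
  with controllable waveform, frequency, amplitude, force and lift-off
  gaps.  A triangle stroke moves at constant speed, so the chord-based
  velocity estimator's target is exactly 4 A f (amplitude A = half the
  peak-to-peak excursion, f strokes-pairs per second); power ground
  truth is F x 4 A f.  Lift-off emulates contact pressure dropping below
  the sensing threshold at stroke turnarounds: the finger dwells at the
  extremum while unsensed, so interpolation reconstructs a plateau.

* **Wearable recordings** -- band-limited Gaussian noise whose spectral
  envelope encodes activity class and scratch power.  For scratch
  activity the high-band envelope (contact microphone 120-460 Hz,
  accelerometer z 70-180 Hz) scales linearly with power times a
  per-participant gain, reproducing the empirical ordering of spectra
  by power.  Non-scratch activities draw from distinct envelope
  families; two are deliberately confusable in a single modality
  (tapping/clapping mimic scratch in the microphone band, air
  scratching mimics it in the accelerometer band) so that the combined
  model has headroom over single-modality ablations.

All randomness flows from a single seed through `numpy.random.SeedSequence`
with stable per-block keys, so regeneration is reproducible.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Optional, Sequence, Tuple

import numpy as np

from .evaluation import FeatureDataset
from .tablet_labeling import (
    MAX_JUMP_MM,
    TABLET_HEIGHT_MM,
    TABLET_RATE_HZ,
    TABLET_WIDTH_MM,
    TabletStream,
    label_stream,
)
from .wearable_features import (
    ACC_RATE_HZ,
    MIC_RATE_HZ,
    TASK_BINS,
    WearableRecording,
    WearableWindow,
    batch_spectra,
    n_windows,
)

SCRATCH_KINDS = (
    "scratch_hand_fingers",
    "scratch_forearm_wrist",
    "scratch_inside_elbow",
    "scratch_neck",
    "scratch_head",
    "scratch_behind_knees",
    "scratch_ankles",
)
NON_SCRATCH_KINDS = (
    "hand_waving",
    "keyboard_typing",
    "texting_swiping",
    "writing",
    "table_tapping",
    "air_scratching",
    "clapping",
)
ALL_KINDS = SCRATCH_KINDS + NON_SCRATCH_KINDS

#: 9 instructed force x speed combinations of the intensity study.
FORCE_LEVELS = ("low", "medium", "high")
SPEED_LEVELS = ("low", "medium", "high")


class SyntheticDataError(ValueError):
    pass


def _rng(seed: int, *key: int) -> np.random.Generator:
    """Generator keyed by (seed, *key): stable across generation order."""
    return np.random.default_rng(np.random.SeedSequence((int(seed),) + tuple(int(k) for k in key)))


# ---------------------------------------------------------------------------
# tablet streams


@dataclass
class ScratchSpec:
    """One simulated scratching block on the tablet."""

    duration_s: float = 10.0
    frequency_hz: float = 3.0
    amplitude_mm: float = 10.0  # half the peak-to-peak stroke extent
    waveform: str = "triangle"
    force_mean_n: float = 0.5
    force_sd_n: float = 0.02
    lift_fraction: float = 0.0  # fraction of each period with contact lost
    position_noise_mm: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s < 1.0 or self.frequency_hz < 1.0:
            raise SyntheticDataError("need duration >= 1 s and frequency >= 1 Hz")
        if not (0.0 <= self.lift_fraction < 1.0):
            raise SyntheticDataError("lift_fraction must be in [0, 1)")
        if self.waveform not in ("triangle", "sinusoid"):
            raise SyntheticDataError(f"unknown waveform {self.waveform!r}")

    @property
    def truth_velocity(self) -> float:
        """Chord-based mean stroke speed: 4 A f for both waveforms."""
        return 4.0 * self.amplitude_mm * self.frequency_hz

    @property
    def truth_power(self) -> float:
        return self.force_mean_n * self.truth_velocity


def gen_tablet_stream(spec: ScratchSpec) -> Tuple[TabletStream, Dict[str, float]]:
    """Simulate a 150 Hz tablet stream; returns (stream, truth record).

    The y trajectory strokes between +-A around the tablet center.  With
    ``lift_fraction`` > 0, each period spends that fraction dwelling at
    the extremes with contact lost (NaN in x, y, f).
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_s * TABLET_RATE_HZ))
    t = np.arange(n) / TABLET_RATE_HZ
    A, f, l = spec.amplitude_mm, spec.frequency_hz, spec.lift_fraction

    phase = (t * f) % 1.0
    s = (1.0 - l) / 2.0  # phase length of one stroke
    y = np.empty(n)
    lifted = np.zeros(n, dtype=bool)
    down = phase < s
    dwell_lo = (phase >= s) & (phase < 0.5)
    up = (phase >= 0.5) & (phase < 0.5 + s)
    dwell_hi = phase >= 0.5 + s

    def stroke(u: np.ndarray) -> np.ndarray:
        # normalized progress u in [0, 1] from +A to -A
        if spec.waveform == "triangle":
            return A * (1.0 - 2.0 * u)
        return A * np.cos(np.pi * u)

    y[down] = stroke(phase[down] / s)
    y[up] = -stroke((phase[up] - 0.5) / s)
    y[dwell_lo] = -A
    y[dwell_hi] = A
    lifted[dwell_lo | dwell_hi] = True

    stroke_speed = 2.0 * A * f / s  # one stroke covers 2A in s/f seconds
    if stroke_speed / TABLET_RATE_HZ > MAX_JUMP_MM:
        warnings.warn(
            f"stroke speed {stroke_speed:.0f} mm/s moves more than "
            f"{MAX_JUMP_MM} mm per timestep; the position-jump filter will "
            "reject these windows",
            stacklevel=2,
        )

    y = y + TABLET_HEIGHT_MM / 2.0 + rng.normal(0, spec.position_noise_mm, n)
    x = TABLET_WIDTH_MM / 2.0 + rng.normal(0, spec.position_noise_mm, n)
    force = np.maximum(rng.normal(spec.force_mean_n, spec.force_sd_n, n), 0.005)
    y = np.clip(y, 0.0, TABLET_HEIGHT_MM)
    x = np.clip(x, 0.0, TABLET_WIDTH_MM)
    for arr in (x, y, force):
        arr[lifted] = np.nan

    stream = TabletStream(t=t, x=x, y=y, f=force)
    truth = {
        "force_n": spec.force_mean_n,
        "velocity_mm_s": spec.truth_velocity,
        "power_mw": spec.truth_power,
    }
    return stream, truth


# ---------------------------------------------------------------------------
# wearable recordings

#: (band_lo_hz, band_hi_hz, amplitude) envelope components per channel.
#: Scratch band amplitudes scale with gain x power / 600.
_MIC_FLOOR = 1.5  # counts per bin
_ACC_FLOOR = 0.008  # g per bin
_MIC_SCRATCH = (120.0, 460.0, 9.0)
_ACC_SCRATCH = (70.0, 180.0, 0.08)
_ACC_MOTION = (1.0, 6.0, 0.12)  # arm motion accompanying any scratch

#: Non-scratch envelope families: kind -> (mic bands, acc bands).
#: table_tapping and clapping reuse the scratch *microphone* envelope
#: (hard impacts ring the contact microphone like scratching does) and
#: air_scratching reuses the scratch *accelerometer* envelope (the arm
#: oscillates identically without skin contact): each single modality is
#: blind to one pair of activities, so multimodal fusion has measurable
#: headroom over either ablation, as in the recorded study.
_NON_SCRATCH_ENVELOPES: Dict[str, Tuple[list, list]] = {
    "hand_waving": ([], [(0.5, 4.0, 0.30)]),
    "keyboard_typing": ([(30.0, 120.0, 3.0)], [(8.0, 50.0, 0.04)]),
    "texting_swiping": ([(20.0, 80.0, 2.0)], [(4.0, 30.0, 0.03)]),
    "writing": ([(40.0, 150.0, 2.5)], [(5.0, 40.0, 0.035)]),
    "table_tapping": ("mic_scratch_like", [(10.0, 60.0, 0.07)]),
    "clapping": ("mic_scratch_like", [(8.0, 55.0, 0.09)]),
    "air_scratching": ([], "acc_scratch_like"),
}

#: Power-equivalent range (mW) sampled for scratch-like confuser bands.
_CONFUSER_POWER_RANGE = (80.0, 380.0)

#: Per-second multiplicative envelope jitter (lognormal sd), per channel.
#: The microphone is noisier than the accelerometer, mirroring its lower
#: single-modality regression performance.
MIC_ENVELOPE_JITTER = 0.22
ACC_ENVELOPE_JITTER = 0.14


def _band_noise(
    n: int, rate: float, lo: float, hi: float, amplitude: float, rng: np.random.Generator
) -> np.ndarray:
    """Gaussian noise with ~flat single-sided 1-s-window amplitude
    ``amplitude`` inside [lo, hi] Hz and zero outside."""
    if amplitude <= 0:
        return np.zeros(n)
    spec = np.fft.rfft(rng.standard_normal(n))
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    mask = (freqs >= lo) & (freqs <= hi)
    spec *= mask
    x = np.fft.irfft(spec, n=n)
    sd = x.std()
    if sd == 0:
        return np.zeros(n)
    # a 1-s window of white-in-band noise with time-domain sd s has mean
    # single-sided in-band bin amplitude ~ s * sqrt(pi / (2 W)), W = bandwidth
    bandwidth_hz = max(mask.sum() / (n / rate), 1.0)
    target_sd = amplitude * math.sqrt(2.0 * bandwidth_hz / math.pi)
    return x / sd * target_sd


def _smooth_jitter(n: int, rate: float, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Per-second lognormal gain, linearly interpolated across the block."""
    secs = max(int(math.ceil(n / rate)) + 1, 2)
    g = np.exp(rng.normal(0.0, sd, secs))
    return np.interp(np.arange(n) / rate, np.arange(secs), g)


def gen_wearable_recording(
    duration_s: float,
    activity_kind: str,
    power_mw: float = 0.0,
    gain: float = 1.0,
    seed: int = 0,
) -> WearableRecording:
    """Simulate a mic + acc-z recording of one activity block."""
    if activity_kind not in ALL_KINDS:
        raise SyntheticDataError(f"unknown activity kind {activity_kind!r}")
    is_scratch = activity_kind in SCRATCH_KINDS
    if is_scratch and not (0.0 <= power_mw <= 600.0):
        raise SyntheticDataError("scratch power must be within [0, 600] mW")
    rng = np.random.default_rng(seed)
    n_mic = int(round(duration_s * MIC_RATE_HZ))
    n_acc = int(round(duration_s * ACC_RATE_HZ))

    mic = _band_noise(n_mic, MIC_RATE_HZ, 0.0, 4000.0, _MIC_FLOOR, rng)
    acc = _band_noise(n_acc, ACC_RATE_HZ, 0.0, 200.0, _ACC_FLOOR, rng)

    if is_scratch:
        site_factor = 0.85 + 0.3 * (SCRATCH_KINDS.index(activity_kind) / 6.0)
        p = gain * site_factor * power_mw / 600.0
        lo, hi, amp = _MIC_SCRATCH
        comp = _band_noise(n_mic, MIC_RATE_HZ, lo, hi, amp * p, rng)
        mic = mic + comp * _smooth_jitter(n_mic, MIC_RATE_HZ, MIC_ENVELOPE_JITTER, rng)
        lo, hi, amp = _ACC_SCRATCH
        comp = _band_noise(n_acc, ACC_RATE_HZ, lo, hi, amp * p, rng)
        acc = acc + comp * _smooth_jitter(n_acc, ACC_RATE_HZ, ACC_ENVELOPE_JITTER, rng)
        if power_mw > 0:
            lo, hi, amp = _ACC_MOTION
            acc = acc + _band_noise(n_acc, ACC_RATE_HZ, lo, hi, amp * gain, rng)
    else:
        mic_bands, acc_bands = _NON_SCRATCH_ENVELOPES[activity_kind]
        pseudo = rng.uniform(*_CONFUSER_POWER_RANGE) / 600.0 * gain
        if mic_bands == "mic_scratch_like":
            lo, hi, amp = _MIC_SCRATCH
            mic_bands = [(lo, hi, amp * pseudo / gain)]
        if acc_bands == "acc_scratch_like":
            lo, hi, amp = _ACC_SCRATCH
            acc_bands = [(lo, hi, amp * pseudo / gain), _ACC_MOTION]
        for lo, hi, amp in mic_bands:
            comp = _band_noise(n_mic, MIC_RATE_HZ, lo, hi, amp * gain, rng)
            mic = mic + comp * _smooth_jitter(n_mic, MIC_RATE_HZ, MIC_ENVELOPE_JITTER, rng)
        for lo, hi, amp in acc_bands:
            comp = _band_noise(n_acc, ACC_RATE_HZ, lo, hi, amp * gain, rng)
            acc = acc + comp * _smooth_jitter(n_acc, ACC_RATE_HZ, ACC_ENVELOPE_JITTER, rng)

    mic = np.clip(np.round(512.0 + mic), 0.0, 1023.0)
    acc = np.clip(acc, -2.0, 2.0)
    return WearableRecording(mic=mic, acc_z=acc)


def gen_wearable_window(
    power_mw: float, activity_kind: str, gain: float = 1.0, seed: int = 0
) -> WearableWindow:
    """One repaired 1-s window of simulated wearable data."""
    rec = gen_wearable_recording(1.0, activity_kind, power_mw, gain, seed)
    return WearableWindow(mic=rec.mic, acc_z=rec.acc_z)


# ---------------------------------------------------------------------------
# cohorts


@dataclass
class CohortSpec:
    """Study design for a simulated multi-participant cohort.

    Defaults mirror the recorded studies: 9 instructed force x speed
    blocks of 10 s per participant for the intensity study, and
    14 activities of 30 s each for the detection study, windowed at
    1 s / 0.25 s stride.
    """

    n_participants: int = 10
    seed: int = 1
    gain_sd: float = 0.15  # per-participant lognormal wearable gain
    intensity_block_s: float = 10.0
    detection_block_s: float = 30.0
    #: instructed force levels (N) and (amplitude mm, frequency Hz) speeds
    forces_n: Tuple[float, ...] = (0.25, 0.6, 1.2)
    strokes: Tuple[Tuple[float, float], ...] = ((10.0, 2.0), (15.0, 3.0), (20.0, 4.0))
    level_power_map: Dict[int, float] = field(
        default_factory=lambda: {1: 95.0, 2: 130.0, 3: 170.0, 4: 205.0, 5: 260.0}
    )
    position_noise_mm: float = 0.2
    force_sd_n: float = 0.03

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise SyntheticDataError("a cohort needs >= 2 participants")

    def participant_ids(self) -> List[str]:
        return [f"P{i + 1:02d}" for i in range(self.n_participants)]

    def participant_gain(self, p_idx: int) -> float:
        return float(np.exp(_rng(self.seed, 0, p_idx).normal(0.0, self.gain_sd)))


@dataclass
class IntensityBlock:
    participant_id: str
    force_level: str
    speed_level: str
    tablet: TabletStream
    wearable: WearableRecording
    truth_force_n: float
    truth_velocity_mm_s: float
    truth_power_mw: float


@dataclass
class DetectionBlock:
    participant_id: str
    activity_kind: str
    wearable: WearableRecording
    is_scratch: bool
    power_mw: float


def gen_intensity_blocks(spec: CohortSpec) -> Iterator[IntensityBlock]:
    """The intensity study: 9 instructed force x speed blocks per person."""
    for p_idx, pid in enumerate(spec.participant_ids()):
        gain = spec.participant_gain(p_idx)
        for b_idx, (fi, si) in enumerate(
            (fi, si) for fi in range(3) for si in range(3)
        ):
            rng = _rng(spec.seed, 1, p_idx, b_idx)
            force = spec.forces_n[fi] * rng.uniform(0.85, 1.2)
            A, f = spec.strokes[si]
            f = f * rng.uniform(0.9, 1.1)
            lift = float(rng.choice([0.0, 0.2]))
            sspec = ScratchSpec(
                duration_s=spec.intensity_block_s,
                frequency_hz=f,
                amplitude_mm=A,
                waveform="triangle",
                force_mean_n=force,
                force_sd_n=spec.force_sd_n,
                lift_fraction=lift,
                position_noise_mm=spec.position_noise_mm,
                seed=int(rng.integers(2**31)),
            )
            tablet, truth = gen_tablet_stream(sspec)
            tablet.participant_id = pid
            wearable = gen_wearable_recording(
                spec.intensity_block_s,
                "scratch_forearm_wrist",
                power_mw=min(truth["power_mw"], 600.0),
                gain=gain,
                seed=int(rng.integers(2**31)),
            )
            wearable.participant_id = pid
            yield IntensityBlock(
                pid, FORCE_LEVELS[fi], SPEED_LEVELS[si], tablet, wearable,
                truth["force_n"], truth["velocity_mm_s"], truth["power_mw"],
            )


def gen_detection_blocks(spec: CohortSpec) -> Iterator[DetectionBlock]:
    """The detection study: all 14 activities, one block per person each."""
    for p_idx, pid in enumerate(spec.participant_ids()):
        gain = spec.participant_gain(p_idx)
        for k_idx, kind in enumerate(ALL_KINDS):
            rng = _rng(spec.seed, 2, p_idx, k_idx)
            is_scratch = kind in SCRATCH_KINDS
            power = float(rng.uniform(80.0, 380.0)) if is_scratch else 0.0
            rec = gen_wearable_recording(
                spec.detection_block_s, kind, power, gain, int(rng.integers(2**31))
            )
            rec.participant_id = pid
            yield DetectionBlock(pid, kind, rec, is_scratch, power)


def _windows_matrix(rec: WearableRecording, stride_s: float) -> Tuple[np.ndarray, np.ndarray]:
    """All fully contained 1-s windows as (n, 8000) and (n, 400) arrays."""
    count = n_windows(rec.duration_s, 1.0, stride_s)
    mic_step = int(round(stride_s * rec.mic_rate_hz))
    acc_step = int(round(stride_s * rec.acc_rate_hz))
    mic = np.lib.stride_tricks.sliding_window_view(rec.mic, MIC_RATE_HZ)[::mic_step][:count]
    acc = np.lib.stride_tricks.sliding_window_view(rec.acc_z, ACC_RATE_HZ)[::acc_step][:count]
    return mic, acc


def _featurize_recording(rec: WearableRecording, task: str, stride_s: float) -> np.ndarray:
    k_mic, k_acc = TASK_BINS[task]
    mic, acc = _windows_matrix(rec, stride_s)
    return np.hstack([batch_spectra(mic, k_mic), batch_spectra(acc, k_acc)])


def build_intensity_dataset(
    spec: CohortSpec, stride_s: float = 0.25, label_stride_s: float = 0.25
) -> FeatureDataset:
    """Run the full labeling + featurization pipeline over the cohort.

    Tablet streams are labeled with the power algorithm; wearable windows
    at matching starts provide the features.  Windows whose label was
    rejected by the outlier filters are dropped, as in the recorded study.
    """
    X, y, pids, truth = [], [], [], []
    for block in gen_intensity_blocks(spec):
        samples = label_stream(block.tablet, stride_s=label_stride_s)
        feats = _featurize_recording(block.wearable, "intensity", stride_s)
        n = min(len(samples), feats.shape[0])
        for i in range(n):
            if samples[i].valid:
                X.append(feats[i])
                y.append(samples[i].power)
                pids.append(block.participant_id)
                truth.append(block.truth_power_mw)
    return FeatureDataset(
        X=np.array(X), y=np.array(y), participants=np.array(pids),
        task="intensity", truth_power=np.array(truth),
    )


def build_detection_dataset(spec: CohortSpec, stride_s: float = 0.25) -> FeatureDataset:
    """Featurize the detection study: balanced scratch / non-scratch."""
    X, y, pids, kinds = [], [], [], []
    for block in gen_detection_blocks(spec):
        feats = _featurize_recording(block.wearable, "detection", stride_s)
        X.append(feats)
        y.append(np.full(feats.shape[0], float(block.is_scratch)))
        pids.extend([block.participant_id] * feats.shape[0])
        kinds.extend([block.activity_kind] * feats.shape[0])
    return FeatureDataset(
        X=np.vstack(X), y=np.concatenate(y), participants=np.array(pids),
        task="detection", interactions=np.array(kinds),
    )


@dataclass
class ValidationStudy:
    """Simulated validation design: levels 1-5, two sets per participant."""

    levels: np.ndarray  # (5,)
    truth_mw: np.ndarray  # (n_sets, 5) tablet ground truth per set
    regressed_mw: np.ndarray  # (n_sets, 5) simulated model output per set
    set_participants: np.ndarray  # (n_sets,) participant of each set


def gen_validation_study(
    spec: CohortSpec,
    n_participants: int = 14,
    regression_noise_mw: float = 35.0,
    truth_noise_mw: float = 18.0,
) -> ValidationStudy:
    """Instructed-intensity study: each participant scratches twice per level.

    Per-level population means follow the cohort's level -> power map;
    each participant applies their own multiplicative interpretation of
    the 1-5 scale, and the simulated regressor adds independent noise.
    """
    levels = np.array(sorted(spec.level_power_map))
    base = np.array([spec.level_power_map[l] for l in levels])
    truth_rows, reg_rows, set_pids = [], [], []
    for p_idx in range(n_participants):
        rng = _rng(spec.seed, 3, p_idx)
        interp_factor = np.exp(rng.normal(0.0, 0.12))
        for _ in range(2):  # two sets per participant
            truth = base * interp_factor + rng.normal(0, truth_noise_mw, base.size)
            reg = truth + rng.normal(0, regression_noise_mw, base.size)
            truth_rows.append(np.clip(truth, 0, 600))
            reg_rows.append(np.clip(reg, 0, 600))
            set_pids.append(f"V{p_idx + 1:02d}")
    return ValidationStudy(
        levels=levels,
        truth_mw=np.vstack(truth_rows),
        regressed_mw=np.vstack(reg_rows),
        set_participants=np.array(set_pids),
    )
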