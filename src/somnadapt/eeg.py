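"""Polysomnography containers, preprocessing and hypnogram summaries.

A :class:`Recording` holds equally-sampled channels tagged with a modality
(EEG / EOG / EMG).  Preprocessing downsamples to 256 Hz (polyphase
resampling) and applies a zero-phase 4th-order Butterworth bandpass per
modality: EEG 0.3-35 Hz, EOG 0.1-35 Hz, EMG 40-120 Hz.

Sleep staging itself is an input: a :class:`Hypnogram` is a sequence of
30-s-epoch labels (W, S1, S2, S3, S4, REM, MT).  Stage summaries report
absolute epoch counts and percentages relative to total sleep time (TST =
epochs - wake epochs; movement-time epochs stay inside TST but belong to no
stage, so stage percentages can sum below 100%).  SWS is S3 and S4
collapsed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy.signal import butter, resample_poly, sosfiltfilt

__all__ = [
    "STAGES",
    "SLEEP_STAGES",
    "MODALITY_BANDS",
    "Recording",
    "Hypnogram",
    "SleepSummary",
    "infer_modality",
    "preprocess",
    "stage_durations",
    "concordance",
]

STAGES = ("W", "S1", "S2", "S3", "S4", "REM", "MT")
#: stages contributing to stage-wise summaries (everything but wake)
SLEEP_STAGES = ("S1", "S2", "S3", "S4", "REM")
EPOCH_LEN = 30.0  # seconds

MODALITY_BANDS = {"EEG": (0.3, 35.0), "EOG": (0.1, 35.0), "EMG": (40.0, 120.0)}
TARGET_RATE = 256.0
FILTER_ORDER = 4


def infer_modality(label: str) -> str:
    """Map a channel label to EEG/EOG/EMG (10-20 labels count as EEG)."""
    up = label.strip().upper()
    if up.startswith("EOG"):
        return "EOG"
    if up.startswith("EMG"):
        return "EMG"
    return "EEG"


@dataclass
class Recording:
    """Multichannel sampled signal: ``data`` is (n_channels, n_samples)."""

    data: np.ndarray
    channels: list[str]
    rate: float
    modality: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.rate <= 0:
            raise ValueError("sampling rate must be > 0")
        if self.data.shape[0] != len(self.channels):
            raise ValueError("channel count does not match data rows")
        for ch in self.channels:
            self.modality.setdefault(ch, infer_modality(ch))
        unknown = set(self.modality.values()) - set(MODALITY_BANDS)
        if unknown:
            raise ValueError(f"unknown modality {unknown}")

    @property
    def n_samples(self) -> int:
        return int(self.data.shape[1])

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate

    def channel(self, name: str) -> np.ndarray:
        matches = [i for i, ch in enumerate(self.channels) if ch.lower() == name.lower()]
        if not matches:
            raise KeyError(f"channel {name!r} not in recording")
        return self.data[matches[0]]


@dataclass
class Hypnogram:
    """Ordered 30-s-epoch sleep-stage labels."""

    stages: np.ndarray
    epoch_len: float = EPOCH_LEN

    def __post_init__(self):
        self.stages = np.asarray(self.stages, dtype=object)
        if self.stages.size == 0:
            raise ValueError("hypnogram must be non-empty")
        bad = set(self.stages) - set(STAGES)
        if bad:
            raise ValueError(f"unknown stage labels {bad}")
        if self.epoch_len != EPOCH_LEN:
            raise ValueError("epoch length is fixed at 30 s")

    @property
    def n_epochs(self) -> int:
        return int(self.stages.size)

    @property
    def duration(self) -> float:
        return self.n_epochs * self.epoch_len

    def mask(self, stages: tuple[str, ...]) -> np.ndarray:
        """Boolean per-epoch mask for the given stage set."""
        return np.isin(self.stages, stages)

    def sample_mask(self, stages: tuple[str, ...], rate: float, n_samples: int) -> np.ndarray:
        """Per-sample eligibility mask at the given rate, clipped to n_samples."""
        spe = int(round(self.epoch_len * rate))
        mask = np.zeros(n_samples, dtype=bool)
        for e, ok in enumerate(self.mask(stages)):
            if ok:
                mask[e * spe : min((e + 1) * spe, n_samples)] = True
        return mask


@dataclass
class SleepSummary:
    absolute: dict[str, int]  # per-stage epoch counts (plus "SWS" collapsed)
    relative: dict[str, float]  # per-stage % of total sleep time
    tst_epochs: int
    valid: bool  # False when TST = 0 (relative values undefined)


def _band_sos(band: tuple[float, float], rate: float):
    nyq = rate / 2.0
    lo, hi = band
    if hi >= nyq:
        raise ValueError(f"band edge {hi} Hz not below Nyquist {nyq} Hz")
    return butter(FILTER_ORDER, [lo, hi], btype="bandpass", fs=rate, output="sos")


def preprocess(rec: Recording, target_rate: float = TARGET_RATE) -> Recording:
    """Downsample to 256 Hz and bandpass each channel per its modality.

    Resampling uses polyphase filtering (with its built-in anti-alias
    filter); the bandpass is zero-phase (forward-backward), so the output
    has no group delay.
    """
    if rec.rate < target_rate:
        raise ValueError(f"cannot resample {rec.rate} Hz up to {target_rate} Hz")
    if rec.rate == target_rate:
        data = rec.data.copy()
    else:
        frac = Fraction(target_rate / rec.rate).limit_denominator(1000)
        data = resample_poly(rec.data, frac.numerator, frac.denominator, axis=1)
    out = np.empty_like(data)
    for i, ch in enumerate(rec.channels):
        sos = _band_sos(MODALITY_BANDS[rec.modality[ch]], target_rate)
        out[i] = sosfiltfilt(sos, data[i])
    return Recording(out, list(rec.channels), target_rate, dict(rec.modality))


def stage_durations(hyp: Hypnogram) -> SleepSummary:
    """Absolute and TST-relative stage durations, with SWS = S3 + S4."""
    absolute = {s: int(np.sum(hyp.stages == s)) for s in STAGES}
    absolute["SWS"] = absolute["S3"] + absolute["S4"]
    tst = hyp.n_epochs - absolute["W"]
    if tst == 0:
        warnings.warn("total sleep time is zero; relative durations undefined")
        relative = {s: float("nan") for s in (*SLEEP_STAGES, "SWS", "MT")}
        return SleepSummary(absolute, relative, tst_epochs=0, valid=False)
    relative = {s: 100.0 * absolute[s] / tst for s in (*SLEEP_STAGES, "SWS", "MT")}
    return SleepSummary(absolute, relative, tst_epochs=tst, valid=True)


def concordance(h1: Hypnogram, h2: Hypnogram) -> float:
    """Percent epoch-wise agreement between two scorers' hypnograms."""
    if h1.n_epochs != h2.n_epochs:
        raise ValueError("hypnograms differ in length")
    return float(100.0 * np.mean(h1.stages == h2.stages))
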