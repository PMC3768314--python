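"""Sleep-spindle detection by moving-RMS thresholding.

Spindles are brief sigma-band bursts in NREM sleep.  Detection per channel:

1. bandpass the (preprocessed) signal to the spindle band — slow 9-12 Hz or
   fast 12-15 Hz — with a zero-phase 4th-order Butterworth filter;
2. restrict to stage S2-S4 epochs;
3. compute the moving RMS of the band-filtered signal in a 0.2-s centered
   window;
4. mark samples where the RMS exceeds ``threshold_sd`` (1.5-2.5) standard
   deviations of the band-filtered signal, the s.d. taken over the included
   epochs only (a whole-night baseline would be deflated by wake);
5. merge supra-threshold runs separated by less than 0.1 s (threshold
   chatter), then keep events lasting 0.5-3 s.

Events are reported on Fz, Cz and Pz, where spindle activity is most
pronounced; density is events per minute of stage-2-4 sleep, per channel
and pooled (mean over channels).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

from .eeg import Hypnogram, Recording

__all__ = [
    "BANDS",
    "SPINDLE_STAGES",
    "SpindleEvent",
    "moving_rms",
    "detect_spindles",
    "spindle_density",
    "events_to_frame",
]

BANDS = {"slow": (9.0, 12.0), "fast": (12.0, 15.0)}
SPINDLE_STAGES = ("S2", "S3", "S4")
SPINDLE_CHANNELS = ("Fz", "Cz", "Pz")
RMS_WINDOW = 0.2  # seconds
MIN_DURATION = 0.5  # seconds
MAX_DURATION = 3.0  # seconds
MERGE_GAP = 0.1  # seconds


@dataclass(frozen=True)
class SpindleEvent:
    channel: str
    band: str
    onset: float  # seconds from recording start
    duration: float  # seconds

    def __post_init__(self):
        if not (MIN_DURATION <= self.duration <= MAX_DURATION):
            raise ValueError("spindle duration outside the 0.5-3 s gate")


def moving_rms(signal: np.ndarray, rate: float, window: float = RMS_WINDOW) -> np.ndarray:
    """Centered moving RMS; edge windows truncate, output length = input."""
    x = np.asarray(signal, dtype=float)
    if x.size == 0:
        raise ValueError("empty signal")
    if window <= 0:
        raise ValueError("window must be > 0")
    w = max(1, int(round(window * rate)))
    if x.size < w:
        raise ValueError("signal shorter than the RMS window")
    cs = np.concatenate(([0.0], np.cumsum(x * x)))
    i = np.arange(x.size)
    lo = np.clip(i - w // 2, 0, x.size)
    hi = np.clip(i - w // 2 + w, 0, x.size)
    return np.sqrt((cs[hi] - cs[lo]) / (hi - lo))


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """[start, stop) index pairs of the True runs of a boolean mask."""
    d = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    stops = np.flatnonzero(d == -1) + 1
    if mask[0]:
        starts = np.concatenate(([0], starts))
    if mask[-1]:
        stops = np.concatenate((stops, [mask.size]))
    return list(zip(starts.tolist(), stops.tolist()))


def detect_spindles(
    rec: Recording,
    hyp: Hypnogram,
    band: str = "fast",
    threshold_sd: float = 1.5,
    channels: tuple[str, ...] = SPINDLE_CHANNELS,
    merge_gap: float = MERGE_GAP,
) -> list[SpindleEvent]:
    """RMS-threshold spindle detection on stage-2-4 epochs.

    Returns events sorted by (channel order, onset).  Events spanning an
    epoch boundary into a non-eligible epoch are truncated at the boundary
    (detection operates on eligible samples only).
    """
    if band not in BANDS:
        raise ValueError(f"band must be one of {tuple(BANDS)}")
    if not (1.5 <= threshold_sd <= 2.5):
        raise ValueError("threshold_sd must lie in [1.5, 2.5]")
    missing = [c for c in channels if all(c.lower() != ch.lower() for ch in rec.channels)]
    if missing:
        raise ValueError(f"channels missing from recording: {missing}")

    eligible = hyp.sample_mask(SPINDLE_STAGES, rec.rate, rec.n_samples)
    if not eligible.any():
        warnings.warn("no stage-2-4 epochs; no spindles can be detected")
        return []

    sos = butter(4, BANDS[band], btype="bandpass", fs=rec.rate, output="sos")
    gap_samples = int(round(merge_gap * rec.rate))
    events: list[SpindleEvent] = []
    for ch in channels:
        filtered = sosfiltfilt(sos, rec.channel(ch))
        sd = float(filtered[eligible].std())
        rms = moving_rms(filtered, rec.rate)
        above = (rms > threshold_sd * sd) & eligible
        if not above.any():
            continue
        runs = _runs(above)
        merged = [list(runs[0])]
        for start, stop in runs[1:]:
            if start - merged[-1][1] < gap_samples:
                merged[-1][1] = stop
            else:
                merged.append([start, stop])
        for start, stop in merged:
            dur = (stop - start) / rec.rate
            if MIN_DURATION <= dur <= MAX_DURATION:
                events.append(
                    SpindleEvent(channel=ch, band=band, onset=start / rec.rate, duration=dur)
                )
    return events


def events_to_frame(events: list[SpindleEvent], subject: str | None = None) -> pd.DataFrame:
    df = pd.DataFrame(
        dict(
            channel=[e.channel for e in events],
            band=[e.band for e in events],
            onset_s=[e.onset for e in events],
            duration_s=[e.duration for e in events],
        )
    )
    if subject is not None:
        df.insert(0, "subject", subject)
    return df


def spindle_density(
    events: list[SpindleEvent],
    hyp: Hypnogram,
    channels: tuple[str, ...] = SPINDLE_CHANNELS,
    bands: tuple[str, ...] = ("slow", "fast"),
) -> pd.DataFrame:
    """Events per minute of stage-2-4 sleep, per channel x band plus pooled.

    The pooled row is the mean of the per-channel densities.  With zero
    eligible minutes the density is undefined (NaN, with a warning).
    """
    minutes = float(np.sum(hyp.mask(SPINDLE_STAGES)) * hyp.epoch_len / 60.0)
    if minutes == 0:
        warnings.warn("zero minutes of stage-2-4 sleep; density undefined")
    rows = []
    for b in bands:
        per_channel = []
        for ch in channels:
            count = sum(1 for e in events if e.band == b and e.channel == ch)
            dens = count / minutes if minutes > 0 else float("nan")
            per_channel.append(dens)
            rows.append(dict(channel=ch, band=b, count=count, density=dens))
        rows.append(
            dict(
                channel="pooled",
                band=b,
                count=sum(1 for e in events if e.band == b),
                density=float(np.mean(per_channel)),
            )
        )
    return pd.DataFrame(rows)
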