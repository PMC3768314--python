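"""Per-epoch windowed FFT log-power spectra.

Each 30-s sleep epoch is analysed with four overlapping 10-s windows whose
starts are spread uniformly across the epoch (offsets 0, 20/3, 40/3 and
20 s — the unique uniform placement of four 10-s windows in 30 s; at 256 Hz
these round to samples 0, 1707, 3413 and 5120).  The signal is bandpassed
to 0.15-48 Hz first; wake (W) and movement (MT) epochs are excluded; the
FFT magnitudes of all windows of all eligible epochs are averaged per
channel and frequency bin, and the natural log of that mean is the
reported spectrum.  Magnitudes are normalized by the window sample count,
so a unit-amplitude sinusoid at an exact bin frequency contributes 0.5 to
its bin.  A 10-s window gives 0.1-Hz resolution.  No taper is applied by
default (a Hann option exists).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

from .eeg import Hypnogram, Recording

__all__ = [
    "PowerSpectrum",
    "epoch_windows",
    "mean_log_spectrum",
    "band_power",
    "spectra_to_frame",
]

WINDOW_LEN = 10.0  # seconds
N_WINDOWS = 4
EPOCH_LEN = 30.0
SPECTRUM_BAND = (0.15, 48.0)
EXCLUDED_STAGES = ("W", "MT")
DELTA = (0.0, 2.0)  # "less than 2 Hz"
THETA = (3.0, 7.0)


@dataclass
class PowerSpectrum:
    channel: str
    freqs: np.ndarray  # Hz, ascending
    values: np.ndarray  # natural log of mean |FFT|/N per bin
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.freqs.shape != self.values.shape:
            raise ValueError("freqs and values must align")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("frequency bins must ascend")


def window_offsets(rate: float) -> list[int]:
    """Start samples of the four windows: round(i*(30-10)/3 * rate)."""
    step = (EPOCH_LEN - WINDOW_LEN) / (N_WINDOWS - 1)
    return [int(round(i * step * rate)) for i in range(N_WINDOWS)]


def epoch_windows(epoch: np.ndarray, rate: float) -> list[np.ndarray]:
    """Cut a 30-s epoch into its four overlapping 10-s windows."""
    epoch = np.asarray(epoch, dtype=float)
    n_expected = int(round(EPOCH_LEN * rate))
    if epoch.size != n_expected:
        raise ValueError(f"epoch must be exactly {EPOCH_LEN} s ({n_expected} samples)")
    w = int(round(WINDOW_LEN * rate))
    return [epoch[s : s + w] for s in window_offsets(rate)]


def mean_log_spectrum(
    rec: Recording,
    hyp: Hypnogram,
    channels: tuple[str, ...] = ("Fz", "Cz", "Pz"),
    band: tuple[float, float] = SPECTRUM_BAND,
    taper: str | None = None,
) -> dict[str, PowerSpectrum]:
    """Log mean FFT-magnitude spectrum per channel over all sleep epochs."""
    if taper not in (None, "hann"):
        raise ValueError("taper must be None or 'hann'")
    eligible = np.flatnonzero(~hyp.mask(EXCLUDED_STAGES))
    if eligible.size == 0:
        raise ValueError("no eligible (non-wake, non-movement) epochs")
    missing = [c for c in channels if all(c.lower() != ch.lower() for ch in rec.channels)]
    if missing:
        raise ValueError(f"channels missing from recording: {missing}")

    spe = int(round(hyp.epoch_len * rec.rate))
    wlen = int(round(WINDOW_LEN * rec.rate))
    offsets = window_offsets(rec.rate)
    win = np.hanning(wlen) if taper == "hann" else None
    sos = butter(4, band, btype="bandpass", fs=rec.rate, output="sos")
    freqs = np.fft.rfftfreq(wlen, d=1.0 / rec.rate)

    out: dict[str, PowerSpectrum] = {}
    for ch in channels:
        filtered = sosfiltfilt(sos, rec.channel(ch))
        acc = np.zeros(freqs.size)
        count = 0
        for e in eligible:
            seg = filtered[e * spe : (e + 1) * spe]
            if seg.size < spe:
                continue  # hypnogram longer than the recording tail
            for s in offsets:
                w = seg[s : s + wlen]
                if win is not None:
                    w = w * win
                acc += np.abs(np.fft.rfft(w)) / wlen
                count += 1
        if count == 0:
            raise ValueError("no complete eligible epochs in the recording")
        with np.errstate(divide="ignore"):
            values = np.log(acc / count)
        out[ch] = PowerSpectrum(
            channel=ch,
            freqs=freqs,
            values=values,
            meta=dict(
                statistic="natural log of mean |FFT|/N",
                n_windows=count,
                band=band,
                taper=taper,
            ),
        )
    return out


def band_power(spec: PowerSpectrum, lo: float, hi: float) -> float:
    """Mean of the per-bin log values over bins with lo <= f < hi."""
    if lo >= hi:
        raise ValueError("lo must be < hi")
    sel = (spec.freqs >= lo) & (spec.freqs < hi)
    if not sel.any():
        raise ValueError(f"no frequency bins in [{lo}, {hi}) Hz")
    return float(spec.values[sel].mean())


def spectra_to_frame(spectra: dict[str, PowerSpectrum], subject: str | None = None) -> pd.DataFrame:
    rows = []
    for ch, sp in spectra.items():
        df = pd.DataFrame(dict(channel=ch, freq_hz=sp.freqs, log_mean_abs_fft=sp.values))
        rows.append(df)
    df = pd.concat(rows, ignore_index=True)
    if subject is not None:
        df.insert(0, "subject", subject)
    return df
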