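"""Readers and writers for recordings, hypnograms and tidy tables.

Recordings are read from EDF (via mne) or from the package's documented
columnar text format: a small ``#``-prefixed header (format tag, sampling
rate, channel names, per-channel modality) followed by one tab-separated
row per sample.  Channel labels are matched case-insensitively everywhere.

Hypnograms are plain text, either one stage label per line or a
two-column ``epoch<TAB>stage`` table; labels must be W, S1, S2, S3, S4,
REM or MT.
"""

from __future__ import annotations

import warnings
from io import StringIO
from pathlib import Path

import numpy as np
import pandas as pd

from .eeg import STAGES, Hypnogram, Recording, infer_modality

__all__ = [
    "read_recording",
    "write_recording",
    "read_hypnogram",
    "write_hypnogram",
]

_FORMAT_TAG = "somnadapt-recording v1"


def write_recording(rec: Recording, path: str | Path) -> Path:
    """Write a recording in the columnar text format (~7 significant
    digits per sample, comfortably finer than 16-bit quantization)."""
    path = Path(path)
    tab = "\t"
    header = [
        f"# {_FORMAT_TAG}",
        f"# rate: {rec.rate!r}",
        f"# channels: {tab.join(rec.channels)}",
        f"# modality: {tab.join(rec.modality[ch] for ch in rec.channels)}",
    ]
    buf = StringIO()
    pd.DataFrame(rec.data.T, columns=rec.channels).to_csv(
        buf, sep="\t", index=False, header=False, float_format="%.7g"
    )
    path.write_text("\n".join(header) + "\n" + buf.getvalue())
    return path


def _read_columnar(path: Path) -> Recording:
    with open(path) as fh:
        tag = fh.readline().strip()
        if tag != f"# {_FORMAT_TAG}":
            raise ValueError(f"{path}: not a {_FORMAT_TAG} file (header {tag!r})")
        rate = float(fh.readline().split(":", 1)[1])
        channels = fh.readline().split(":", 1)[1].strip().split("\t")
        modality = fh.readline().split(":", 1)[1].strip().split("\t")
        data = pd.read_csv(fh, sep="\t", header=None, dtype=float).to_numpy().T
    if data.shape[0] != len(channels):
        raise ValueError(f"{path}: {data.shape[0]} columns for {len(channels)} channels")
    return Recording(data, channels, rate, dict(zip(channels, modality)))


def _read_edf(path: Path) -> Recording:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    channels = list(raw.ch_names)
    data = raw.get_data()
    return Recording(
        data, channels, float(raw.info["sfreq"]), {ch: infer_modality(ch) for ch in channels}
    )


def read_recording(path: str | Path) -> Recording:
    """Read an EDF (``.edf``) or columnar-text recording."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".edf":
        return _read_edf(path)
    return _read_columnar(path)


def write_hypnogram(hyp: Hypnogram, path: str | Path) -> Path:
    path = Path(path)
    path.write_text("\n".join(str(s) for s in hyp.stages) + "\n")
    return path


def read_hypnogram(path: str | Path) -> Hypnogram:
    """One label per line, or two-column (epoch index, stage)."""
    path = Path(path)
    labels = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        label = parts[-1]
        if label not in STAGES:
            raise ValueError(f"{path}:{lineno}: unknown stage label {label!r}")
        if len(parts) == 2 and not parts[0].isdigit():
            warnings.warn(f"{path}:{lineno}: first column is not an epoch index")
        labels.append(label)
    if not labels:
        raise ValueError(f"{path}: empty hypnogram")
    return Hypnogram(np.array(labels, dtype=object))
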