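"""Spindle detection: moving RMS, burst detection, duration gate,
threshold monotonicity, and equivalence with a brute-force oracle."""

import numpy as np
import pytest

from somnadapt.eeg import Hypnogram, Recording
from somnadapt.spindles import (
    BANDS,
    SPINDLE_STAGES,
    detect_spindles,
    moving_rms,
    spindle_density,
)
from tests.conftest import burst_recording

RATE = 256.0


class TestMovingRms:
    def test_constant_signal(self):
        out = moving_rms(np.full(1000, -3.0), RATE)
        assert np.allclose(out, 3.0)

    def test_sine_rms_is_inverse_sqrt2(self):
        t = np.arange(int(10 * RATE)) / RATE
        out = moving_rms(np.sin(2 * np.pi * 20 * t), RATE)
        core = out[int(RATE) : -int(RATE)]
        assert np.allclose(core, 1 / np.sqrt(2), atol=0.02)

    def test_zeros_and_length(self):
        x = np.zeros(500)
        out = moving_rms(x, RATE)
        assert out.shape == x.shape and np.all(out == 0.0)

    def test_empty_signal_rejected(self):
        with pytest.raises(ValueError):
            moving_rms(np.array([]), RATE)


def brute_force_detect(filtered, eligible, rate, threshold, merge_gap=0.1,
                       min_dur=0.5, max_dur=3.0, window=0.2):
    """Sample-by-sample re-implementation used as an independent oracle."""
    w = int(round(window * rate))
    n = filtered.size
    rms = np.empty(n)
    for i in range(n):
        lo = max(0, i - w // 2)
        hi = min(n, i - w // 2 + w)
        rms[i] = np.sqrt(np.mean(filtered[lo:hi] ** 2))
    above = (rms > threshold) & eligible
    events, start = [], None
    last_stop = None
    raw = []
    for i, a in enumerate(above):
        if a and start is None:
            start = i
        elif not a and start is not None:
            raw.append([start, i])
            start = None
    if start is not None:
        raw.append([start, n])
    merged = []
    for s, e in raw:
        if merged and s - merged[-1][1] < int(round(merge_gap * rate)):
            merged[-1][1] = e
        else:
            merged.append([s, e])
    for s, e in merged:
        dur = (e - s) / rate
        if min_dur <= dur <= max_dur:
            events.append((s / rate, dur))
    return events


def test_single_burst_detected_with_accurate_onset(s2_hypnogram):
    rec = burst_recording(duration=1.0, amplitude=10.0, t0=30.0)
    events = [e for e in detect_spindles(rec, s2_hypnogram, band="fast", threshold_sd=2.5)
              if e.channel == "Fz"]
    assert len(events) == 1
    assert events[0].onset == pytest.approx(30.0, abs=0.1)
    assert 0.5 <= events[0].duration <= 3.0


@pytest.mark.parametrize("duration,amplitude", [(3.5, 10.0), (0.2, 3.0)])
def test_out_of_gate_bursts_yield_no_events(s2_hypnogram, duration, amplitude):
    # a long burst exceeds the 3-s gate; a short weak burst's supra-threshold
    # run stays below 0.5 s — both must be rejected
    rec = burst_recording(duration=duration, amplitude=amplitude)
    events = [e for e in detect_spindles(rec, s2_hypnogram, band="fast", threshold_sd=2.5)
              if e.channel == "Fz"]
    assert events == []


def test_noise_only_events_respect_gate_and_stages():
    rng = np.random.default_rng(4)
    n = int(600 * RATE)  # 10 min
    rec = Recording(rng.normal(0, 1, (3, n)), ["Fz", "Cz", "Pz"], RATE)
    stages = np.array(["S2"] * 10 + ["W"] * 5 + ["S3"] * 5, dtype=object)
    hyp = Hypnogram(stages)
    wake_lo, wake_hi = 10 * 30.0, 15 * 30.0
    for thr in (1.5, 2.5):
        events = detect_spindles(rec, hyp, band="slow", threshold_sd=thr)
        for e in events:
            assert 0.5 <= e.duration <= 3.0
            assert not (wake_lo <= e.onset < wake_hi)
            assert e.onset + e.duration <= wake_lo or e.onset >= wake_hi


def test_raising_threshold_never_increases_count():
    from somnadapt.eeg import preprocess
    from somnadapt.synthetic import NightProfile, simulate_night

    prof = NightProfile(stages=["S2"] * 20, seed=7)
    rec, hyp, _ = simulate_night(prof)
    rec = preprocess(rec)
    counts = [len(detect_spindles(rec, hyp, band="fast", threshold_sd=t))
              for t in (1.5, 1.8, 2.1, 2.5)]
    assert counts == sorted(counts, reverse=True)


def test_equivalence_with_brute_force_oracle(s2_hypnogram):
    from scipy.signal import butter, sosfiltfilt

    rec = burst_recording(duration=1.2, amplitude=8.0, seed=3)
    events = [e for e in detect_spindles(rec, s2_hypnogram, band="fast", threshold_sd=1.5)
              if e.channel == "Fz"]
    sos = butter(4, BANDS["fast"], btype="bandpass", fs=RATE, output="sos")
    filtered = sosfiltfilt(sos, rec.channel("Fz"))
    eligible = s2_hypnogram.sample_mask(SPINDLE_STAGES, RATE, rec.n_samples)
    oracle = brute_force_detect(filtered, eligible, RATE,
                                threshold=1.5 * filtered[eligible].std())
    assert len(events) == len(oracle)
    for ev, (onset, dur) in zip(events, oracle):
        assert ev.onset == pytest.approx(onset, abs=1e-9)
        assert ev.duration == pytest.approx(dur, abs=1e-9)


def test_threshold_outside_range_rejected(s2_hypnogram):
    rec = burst_recording(duration=1.0)
    with pytest.raises(ValueError):
        detect_spindles(rec, s2_hypnogram, band="fast", threshold_sd=3.0)
    with pytest.raises(ValueError):
        detect_spindles(rec, s2_hypnogram, band="sigma")


def test_no_eligible_epochs_warns_and_returns_empty():
    rec = burst_recording(duration=1.0)
    hyp = Hypnogram(np.array(["W", "REM"], dtype=object))
    with pytest.warns(UserWarning, match="no stage-2-4"):
        assert detect_spindles(rec, hyp, band="fast") == []


class TestDensity:
    def make_hyp(self, minutes):
        return Hypnogram(np.array(["S2"] * (minutes * 2), dtype=object))

    def test_zero_events(self):
        df = spindle_density([], self.make_hyp(20))
        assert (df["density"] == 0).all()

    def test_rate_arithmetic(self):
        from somnadapt.spindles import SpindleEvent

        events = [SpindleEvent("Fz", "fast", onset=10.0 * i, duration=1.0) for i in range(10)]
        df = spindle_density(events, self.make_hyp(20))
        fz = df[(df.channel == "Fz") & (df.band == "fast")]["density"].iloc[0]
        assert fz == pytest.approx(0.5)
        doubled = spindle_density(events * 2, self.make_hyp(20))
        fz2 = doubled[(doubled.channel == "Fz") & (doubled.band == "fast")]["density"].iloc[0]
        assert fz2 == pytest.approx(1.0)

    def test_zero_denominator_flagged(self):
        hyp = Hypnogram(np.array(["W"] * 4, dtype=object))
        with pytest.warns(UserWarning, match="zero minutes"):
            df = spindle_density([], hyp)
        assert df["density"].isna().all()
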