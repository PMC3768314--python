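import numpy as np
import pytest

from somnadapt.eeg import Hypnogram, Recording
from somnadapt.synthetic import synthetic_face

RATE = 256.0


@pytest.fixture(scope="session")
def face():
    return synthetic_face(seed=0)


@pytest.fixture()
def s2_hypnogram():
    """Two 30-s epochs of stage 2 (covers a 60-s test signal)."""
    return Hypnogram(np.array(["S2", "S2"], dtype=object))


def burst_recording(duration, amplitude=10.0, t0=30.0, carrier=13.0, seed=0,
                    total=60.0, envelope="rect", rate=RATE):
    """60 s of unit white noise on Fz/Cz/Pz with one sigma burst on Fz."""
    rng = np.random.default_rng(seed)
    n = int(total * rate)
    x = rng.normal(0, 1, n)
    m = int(round(duration * rate))
    i0 = int(round(t0 * rate))
    env = np.hanning(m) if envelope == "hann" else np.ones(m)
    x[i0 : i0 + m] += amplitude * env * np.sin(2 * np.pi * carrier * np.arange(m) / rate)
    data = np.vstack([x, rng.normal(0, 1, n), rng.normal(0, 1, n)])
    return Recording(data, ["Fz", "Cz", "Pz"], rate)
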