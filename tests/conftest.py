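import numpy as np
import pytest

from provoc import AudioSignal, make_tone

RATE = 22050


@pytest.fixture
def rate():
    return RATE


@pytest.fixture
def rng():
    return np.random.default_rng(20190404)


@pytest.fixture
def tone440(rate):
    return make_tone(440.0, 1.0, rate)


@pytest.fixture
def noise_signal(rate, rng):
    return AudioSignal(0.3 * rng.standard_normal(rate), rate)


def peak_frequency(signal) -> float:
    """Location (Hz) of the largest full-signal FFT magnitude."""
    mags = np.abs(np.fft.rfft(signal.samples))
    return float(np.argmax(mags) * signal.rate / len(signal.samples))


def correlation(a, b) -> float:
    n = min(len(a.samples), len(b.samples))
    return float(np.corrcoef(a.samples[:n], b.samples[:n])[0, 1])


def rms(x) -> float:
    return float(np.sqrt(np.mean(np.square(x))))
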