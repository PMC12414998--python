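import numpy as np
import pytest

from loombias.hrtf import ContrastSpec, FrequencyAxis, MagnitudeSpectrumSet


@pytest.fixture
def axis():
    # linear FFT-style grid covering 86 Hz .. 22 kHz
    return FrequencyAxis(np.linspace(86.13, 22050.0, 256))


@pytest.fixture
def band():
    return ContrastSpec(C=1.0, band_lo=1000.0, band_hi=16000.0)


@pytest.fixture
def spectrum_set(axis):
    """Four directions x two ears of smooth random dB spectra."""
    rng = np.random.default_rng(7)
    dirs = np.array([[0.0, 0.0], [0.0, 90.0], [0.0, 180.0], [30.0, 45.0]])
    f = axis.frequencies
    mags = np.empty((4, 2, len(axis)))
    for i in range(4):
        for e in range(2):
            # sum of a few smooth log-frequency ripples, +-10 dB scale
            amp = rng.uniform(2, 5, 3)
            ph = rng.uniform(0, 2 * np.pi, 3)
            per = rng.uniform(1.5, 4.0, 3)
            mags[i, e] = sum(
                a * np.sin(2 * np.pi * np.log2(f / 1000.0) / p + q)
                for a, p, q in zip(amp, per, ph)
            )
    return MagnitudeSpectrumSet(mags, dirs, axis)
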