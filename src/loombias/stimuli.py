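"""Stimulus synthesis for the looming-bias and localization paradigms.

Two stimulus families are used: Gaussian white-noise bursts (directional
localization) and Schroeder-phase harmonic tone complexes (looming bias and
externalization; fundamentals 100-140 Hz, band 1-16 kHz, phase curvature
0.5). Spatialization applies minimum-phase filters built from (possibly
contrast-manipulated) HRTF magnitude spectra. A looming/receding trial is a
transition between two spatializations of the same source signal: the
"flattened" and "shaped" stimuli are created by a seeded-jitter onset
(600 +/- 50 ms) and a 10 ms raised-cosine crossfade, which keeps intensity
constant for highly correlated endpoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

from .hrtf import MagnitudeSpectrumSet

__all__ = [
    "ToneComplexSpec",
    "TransitionSpec",
    "Stimulus",
    "noise_burst",
    "harmonic_complex",
    "apply_hrtf",
    "make_transition",
    "rms_equalize",
    "write_wav",
]


@dataclass(frozen=True)
class ToneComplexSpec:
    """Harmonic complex: fundamental, passband, Schroeder phase curvature."""

    f0: float
    band_lo: float = 1000.0
    band_hi: float = 16000.0
    phase_curvature: float = 0.5
    duration: float = 0.6
    fs: float = 44100.0

    def __post_init__(self):
        if self.f0 <= 0 or self.band_lo < self.f0:
            raise ValueError("need 0 < f0 <= band_lo")
        if not 0.0 <= abs(self.phase_curvature) <= 1.0:
            raise ValueError("|phase_curvature| must be in [0, 1]")


@dataclass(frozen=True)
class TransitionSpec:
    """Nominal transition onset, uniform jitter half-width, crossfade length (s)."""

    onset_nominal: float = 0.6
    jitter: float = 0.05
    crossfade: float = 0.01

    def __post_init__(self):
        if self.onset_nominal - self.jitter <= 0:
            raise ValueError("onset_nominal - jitter must be > 0")
        if self.crossfade <= 0:
            raise ValueError("crossfade must be > 0")


@dataclass
class Stimulus:
    """Two-channel (or mono) waveform with sampling rate and annotations."""

    samples: np.ndarray  # (n_channels, n_samples)
    fs: float
    annotations: dict = field(default_factory=dict)

    def __post_init__(self):
        s = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if s.shape[0] > s.shape[1]:
            raise ValueError("samples must be (n_channels, n_samples)")
        self.samples = s

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def rms(self) -> float:
        return float(np.sqrt(np.mean(self.samples**2)))


def _raised_cosine_ramp(n: int) -> np.ndarray:
    # 0 at sample 0, 1 at sample n (inclusive endpoint handled by caller slicing)
    return 0.5 * (1.0 - np.cos(np.pi * np.arange(n) / n))


def noise_burst(
    duration: float = 0.5, ramp: float = 0.01, fs: float = 44100.0, seed: int | None = None
) -> Stimulus:
    """Gaussian white-noise burst with raised-cosine on/off ramps."""
    if not 2 * ramp < duration:
        raise ValueError("need 2*ramp < duration")
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    x = rng.standard_normal(n)
    nr = int(round(ramp * fs))
    if nr > 0:
        env = np.ones(n)
        env[:nr] = _raised_cosine_ramp(nr)
        env[-nr:] = _raised_cosine_ramp(nr)[::-1]
        x *= env
    x /= np.max(np.abs(x))
    return Stimulus(x[None, :], fs, {"kind": "noise_burst", "seed": seed})


def harmonic_complex(spec: ToneComplexSpec) -> Stimulus:
    """Equal-amplitude harmonic complex with Schroeder-type phases.

    Components are the harmonics n*f0 inside [band_lo, band_hi], with phases
    phi_n = curvature * pi * n * (n + 1) / N (N = number of components),
    spreading energy in time and limiting the crest factor. Peak-normalized.
    """
    n_lo = int(np.ceil(spec.band_lo / spec.f0 - 1e-9))
    n_hi = int(np.floor(spec.band_hi / spec.f0 + 1e-9))
    if n_hi < n_lo:
        raise ValueError("no harmonic of f0 falls inside the band")
    harmonics = np.arange(n_lo, n_hi + 1)
    N = harmonics.size
    t = np.arange(int(round(spec.duration * spec.fs))) / spec.fs
    phases = spec.phase_curvature * np.pi * harmonics * (harmonics + 1) / N
    x = np.sum(
        np.sin(2 * np.pi * spec.f0 * harmonics[:, None] * t[None, :] + phases[:, None]),
        axis=0,
    )
    x /= np.max(np.abs(x))
    return Stimulus(
        x[None, :],
        spec.fs,
        {"kind": "harmonic_complex", "f0": spec.f0, "n_components": int(N)},
    )


def _minimum_phase_fir(mag_db: np.ndarray, n_fft: int) -> np.ndarray:
    """Minimum-phase FIR from a one-sided dB magnitude (rfft grid, n_fft//2+1 bins).

    Homomorphic construction: fold the real cepstrum of log|H| and
    exponentiate back.
    """
    logmag = mag_db * (np.log(10.0) / 20.0)
    full = np.concatenate([logmag, logmag[-2:0:-1]])
    cep = np.fft.ifft(full).real
    fold = np.zeros_like(cep)
    fold[0] = cep[0]
    fold[1 : n_fft // 2] = 2.0 * cep[1 : n_fft // 2]
    fold[n_fft // 2] = cep[n_fft // 2]
    h = np.fft.ifft(np.exp(np.fft.fft(fold))).real
    return h


def apply_hrtf(
    stim: Stimulus,
    specs: MagnitudeSpectrumSet,
    direction: tuple[float, float],
    n_fft: int = 512,
    itd_samples: int = 0,
    normalize: bool = True,
) -> Stimulus:
    """Spatialize a stimulus with minimum-phase filters for one direction.

    The direction's per-ear magnitude spectra are interpolated onto the rfft
    grid of ``n_fft`` bins, rendered as minimum-phase FIRs and convolved with
    the (mono or per-ear) input. ``itd_samples`` delays the left (positive)
    or right (negative) ear to restore a broadband interaural time
    difference, which magnitude-only manipulation discards.
    """
    idx = specs.direction_index(*direction)
    fs = stim.fs
    grid = np.fft.rfftfreq(n_fft, d=1.0 / fs)
    out = []
    for ear in (0, 1):
        mag = np.interp(
            grid,
            specs.axis.frequencies,
            specs.magnitudes[idx, ear],
            left=specs.magnitudes[idx, ear, 0],
            right=specs.magnitudes[idx, ear, -1],
        )
        h = _minimum_phase_fir(mag, n_fft)
        x = stim.samples[min(ear, stim.samples.shape[0] - 1)]
        y = fftconvolve(x, h)[: stim.n_samples]
        out.append(y)
    y = np.vstack(out)
    if itd_samples != 0:
        ear = 0 if itd_samples > 0 else 1
        d = abs(int(itd_samples))
        y[ear] = np.concatenate([np.zeros(d), y[ear, :-d]]) if d < y.shape[1] else 0.0
    scale = 1.0
    if normalize:
        peak = np.max(np.abs(y))
        if peak > 1.0:
            scale = 1.0 / peak
            y = y * scale
    ann = dict(stim.annotations)
    ann.update({"direction": tuple(direction), "peak_scale": scale})
    return Stimulus(y, fs, ann)


def make_transition(
    stimA: Stimulus, stimB: Stimulus, tspec: TransitionSpec, seed: int | None = None
) -> Stimulus:
    """Crossfade from A into B with a jittered onset and raised-cosine faders.

    The realized onset is drawn uniformly from onset_nominal +/- jitter
    (seeded) and recorded in the annotations; fade-out and fade-in weights
    are complementary at every sample, so correlated endpoints keep constant
    intensity through the transition.
    """
    if stimA.fs != stimB.fs or stimA.n_samples != stimB.n_samples:
        raise ValueError("stimuli must share sampling rate and length")
    rng = np.random.default_rng(seed)
    onset = tspec.onset_nominal + rng.uniform(-tspec.jitter, tspec.jitter)
    fs = stimA.fs
    i0 = int(round(onset * fs))
    nf = int(round(tspec.crossfade * fs))
    i1 = min(i0 + nf, stimA.n_samples)
    nf = i1 - i0
    if i0 >= stimA.n_samples or nf <= 0:
        raise ValueError("transition onset lies beyond the stimulus")
    w_in = _raised_cosine_ramp(nf)
    y = stimA.samples.copy()
    y[:, i0:i1] = (1.0 - w_in) * stimA.samples[:, i0:i1] + w_in * stimB.samples[:, i0:i1]
    y[:, i1:] = stimB.samples[:, i1:]
    ann = {
        "transition_onset": onset,
        "crossfade": tspec.crossfade,
        "from": stimA.annotations,
        "to": stimB.annotations,
    }
    return Stimulus(y, fs, ann)


def rms_equalize(stims: list[Stimulus], target_db: float = -20.0) -> list[Stimulus]:
    """Scale each stimulus to a common RMS level (dB re full scale).

    Both channels of a stimulus share one scale factor, preserving the
    interaural level relation within each stimulus.
    """
    target = 10 ** (target_db / 20.0)
    out = []
    for s in stims:
        r = s.rms()
        if r <= 0:
            raise ValueError("cannot equalize a silent stimulus")
        ann = dict(s.annotations)
        ann["rms_scale"] = target / r
        out.append(Stimulus(s.samples * (target / r), s.fs, ann))
    return out


def write_wav(stim: Stimulus, path) -> None:
    """Write a stimulus as a float32 WAV file (channels as columns)."""
    from scipy.io import wavfile

    wavfile.write(path, int(stim.fs), stim.samples.T.astype(np.float32))
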