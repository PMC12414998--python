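"""Spectral-contrast manipulation of HRTF magnitude spectra.

Head-related transfer functions (HRTFs) encode direction-dependent spectral
filtering by the pinna, head and torso. The manipulation implemented here
interpolates/extrapolates each magnitude spectrum about its ERB-weighted
in-band mean with a scalar spectral contrast factor ``C``:

    M_c(f) = C * M_1(f) + (1 - C) * (1/N_f) * sum_k w'(k) * M_1(k)

where the sum runs over the N_f frequency bins inside the manipulation band
(default 1-16 kHz) and ``w'`` is a frequency weighting proportional to the
derivative of the ERB-rate scale (i.e. inversely proportional to the
equivalent rectangular bandwidth), normalized to mean 1 over the in-band
bins. ``C = 1`` leaves the native cues untouched, ``C = 0`` flattens the
in-band spectrum to a constant ("flat" cues, no spectral spatial
information), and ``C = -1`` inverts it about the weighted mean ("novel" /
impossible-ear cues). The manipulation operates on dB magnitudes; inversion
in linear amplitude could produce non-physical negative magnitudes.

Before applying the contrast, measured spectra are smoothed with a
gammatone-shaped kernel whose equivalent rectangular width scales with the
local ERB, emulating auditory frequency resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "FrequencyAxis",
    "MagnitudeSpectrumSet",
    "ErbWeighting",
    "ContrastSpec",
    "erb",
    "erb_weights",
    "smooth_spectrum",
    "spectral_contrast",
    "make_cue_sets",
]

EARS = ("left", "right")


def erb(f):
    """Equivalent rectangular bandwidth (Hz) at frequency ``f`` (Hz).

    Glasberg & Moore parameterization: ERB(f) = 24.7 * (4.37 f/1000 + 1).
    """
    f = np.asarray(f, dtype=float)
    return 24.7 * (4.37 * f / 1000.0 + 1.0)


@dataclass(frozen=True)
class FrequencyAxis:
    """Strictly increasing, positive frequency grid in Hz."""

    frequencies: np.ndarray

    def __post_init__(self):
        f = np.asarray(self.frequencies, dtype=float)
        if f.ndim != 1 or f.size < 2:
            raise ValueError("frequency axis needs >= 2 bins")
        if not np.all(np.isfinite(f)) or np.any(f <= 0):
            raise ValueError("frequencies must be finite and > 0")
        if np.any(np.diff(f) <= 0):
            raise ValueError("frequency axis must be strictly increasing")
        object.__setattr__(self, "frequencies", f)

    def __len__(self):
        return self.frequencies.size

    def band_mask(self, lo: float, hi: float) -> np.ndarray:
        return (self.frequencies >= lo) & (self.frequencies <= hi)


@dataclass
class MagnitudeSpectrumSet:
    """Per-direction, per-ear magnitude spectra in dB on a shared axis.

    ``magnitudes`` has shape (n_directions, 2, n_frequencies); ear order is
    (left, right). ``directions`` holds interaural coordinates
    (lateral deg, polar deg) per row.
    """

    magnitudes: np.ndarray
    directions: np.ndarray
    axis: FrequencyAxis

    def __post_init__(self):
        m = np.asarray(self.magnitudes, dtype=float)
        d = np.asarray(self.directions, dtype=float)
        if m.ndim != 3 or m.shape[1] != 2:
            raise ValueError("magnitudes must have shape (n_dir, 2, n_freq)")
        if m.shape[2] != len(self.axis):
            raise ValueError("magnitudes and axis disagree on bin count")
        if d.shape != (m.shape[0], 2):
            raise ValueError("directions must have shape (n_dir, 2)")
        if not np.all(np.isfinite(m)):
            raise ValueError("magnitudes must be finite")
        self.magnitudes = m
        self.directions = d

    @property
    def n_directions(self) -> int:
        return self.magnitudes.shape[0]

    def direction_index(self, lateral: float, polar: float, atol: float = 0.5) -> int:
        d = self.directions
        hit = np.nonzero(
            (np.abs(d[:, 0] - lateral) <= atol) & (np.abs(d[:, 1] - polar) <= atol)
        )[0]
        if hit.size == 0:
            avail = ", ".join(f"({a:g}, {b:g})" for a, b in d)
            raise KeyError(
                f"direction (lat={lateral}, pol={polar}) not in set; available: {avail}"
            )
        return int(hit[0])

    def copy(self) -> "MagnitudeSpectrumSet":
        return MagnitudeSpectrumSet(
            self.magnitudes.copy(), self.directions.copy(), self.axis
        )


@dataclass(frozen=True)
class ContrastSpec:
    """Spectral contrast factor and manipulation band (Hz)."""

    C: float
    band_lo: float = 1000.0
    band_hi: float = 16000.0

    def __post_init__(self):
        if not np.isfinite(self.C):
            raise ValueError("contrast factor must be finite")
        if not (0 < self.band_lo < self.band_hi):
            raise ValueError("need 0 < band_lo < band_hi")


@dataclass(frozen=True)
class ErbWeighting:
    """ERB-rate-derivative weights on the in-band bins of an axis.

    ``weights`` is dense over the full axis with zeros outside the band;
    ``mask`` marks in-band bins. In-band weights are positive with mean 1.
    """

    weights: np.ndarray
    mask: np.ndarray
    axis: FrequencyAxis = field(repr=False)


def erb_weights(axis: FrequencyAxis, band: ContrastSpec) -> ErbWeighting:
    """Frequency weighting w'(f) proportional to d(ERB-rate)/df = 1/ERB(f).

    Evaluated on the axis bins inside [band_lo, band_hi] and normalized so the
    in-band mean is 1; bins outside the band get weight 0.
    """
    mask = axis.band_mask(band.band_lo, band.band_hi)
    n = int(mask.sum())
    if n < 2:
        raise ValueError(
            f"band [{band.band_lo}, {band.band_hi}] Hz covers {n} axis bins; need >= 2"
        )
    w = np.zeros(len(axis))
    raw = 1.0 / erb(axis.frequencies[mask])
    w[mask] = raw / raw.mean()
    return ErbWeighting(weights=w, mask=mask, axis=axis)


def _gammatone_kernel(axis: FrequencyAxis, bandwidth_factor: float) -> np.ndarray:
    """Row-stochastic smoothing matrix with 4th-order gammatone magnitude rows.

    Row i is |H(f; fc=f_i)| = [1 + ((f-fc)/b)^2]^(-2) sampled on the axis, with
    b set so the kernel's equivalent rectangular width equals
    bandwidth_factor * ERB(fc) (for this Lorentzian-squared shape
    ERW = b*pi/2, hence b = 2*ERW/pi). Rows are normalized to sum 1 so
    constants are preserved.
    """
    f = axis.frequencies
    erw = bandwidth_factor * erb(f)
    b = 2.0 * erw / np.pi
    x = (f[None, :] - f[:, None]) / b[:, None]
    K = (1.0 + x * x) ** -2
    return K / K.sum(axis=1, keepdims=True)


def smooth_spectrum(
    specs: MagnitudeSpectrumSet, bandwidth_factor: float = 1.0
) -> MagnitudeSpectrumSet:
    """ERB-scaled gammatone smoothing of every spectrum in the set (dB domain)."""
    if not bandwidth_factor > 0:
        raise ValueError("bandwidth_factor must be > 0")
    K = _gammatone_kernel(specs.axis, bandwidth_factor)
    sm = specs.magnitudes @ K.T
    return MagnitudeSpectrumSet(sm, specs.directions.copy(), specs.axis)


def spectral_contrast(
    specs: MagnitudeSpectrumSet, spec: ContrastSpec, w: ErbWeighting | None = None
) -> MagnitudeSpectrumSet:
    """Apply the contrast manipulation inside the band; out-of-band unchanged.

    The ERB-weighted in-band mean of each spectrum is invariant under any C.
    """
    if w is None:
        w = erb_weights(specs.axis, spec)
    if w.axis is not specs.axis and not np.array_equal(
        w.axis.frequencies, specs.axis.frequencies
    ):
        raise ValueError("weights were computed on a different frequency axis")
    mask = w.mask
    ww = w.weights[mask]
    m_in = specs.magnitudes[:, :, mask]
    wmean = (m_in * ww).mean(axis=2, keepdims=True)  # (1/N_f) sum w'(k) M1(k)
    out = specs.magnitudes.copy()
    out[:, :, mask] = spec.C * m_in + (1.0 - spec.C) * wmean
    return MagnitudeSpectrumSet(out, specs.directions.copy(), specs.axis)


def make_cue_sets(
    native: MagnitudeSpectrumSet,
    band: ContrastSpec | None = None,
    bandwidth_factor: float | None = None,
) -> dict[str, MagnitudeSpectrumSet]:
    """Produce the native (C=1), flat (C=0) and novel (C=-1) cue sets.

    If ``bandwidth_factor`` is given, spectra are gammatone-smoothed first
    (measurement pipeline order: smooth, then contrast); otherwise the input
    is taken as already smoothed. The flat set carries one constant per
    (direction, ear) spectrum — the direction-dependent weighted mean — so it
    retains broadband level differences but no spectral shape.
    """
    if band is None:
        band = ContrastSpec(C=1.0)
    base = native if bandwidth_factor is None else smooth_spectrum(native, bandwidth_factor)
    w = erb_weights(base.axis, band)
    return {
        "native": spectral_contrast(base, replace(band, C=1.0), w),
        "flat": spectral_contrast(base, replace(band, C=0.0), w),
        "novel": spectral_contrast(base, replace(band, C=-1.0), w),
    }
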