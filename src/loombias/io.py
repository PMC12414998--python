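"""File interfaces: delimited-text spectrum tables and read-only SOFA import.

SOFA (AES69) HRTF containers are netCDF4 and therefore HDF5 underneath, so
the SimpleFreeFieldHRIR convention can be read with h5py alone. Writing is
not supported; manipulated spectra round-trip through plain CSV tables with
columns (lateral, polar, frequency, left_db, right_db).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .hrtf import FrequencyAxis, MagnitudeSpectrumSet

__all__ = [
    "read_spectrum_table",
    "write_spectrum_table",
    "read_sofa",
    "geodetic_to_interaural",
]

_COLUMNS = ["lateral", "polar", "frequency", "left_db", "right_db"]


def write_spectrum_table(specs: MagnitudeSpectrumSet, path) -> None:
    """Write a magnitude-spectrum set as a long-format CSV table."""
    f = specs.axis.frequencies
    rows = []
    for i, (lat, pol) in enumerate(specs.directions):
        rows.append(
            pd.DataFrame(
                {
                    "lateral": lat,
                    "polar": pol,
                    "frequency": f,
                    "left_db": specs.magnitudes[i, 0],
                    "right_db": specs.magnitudes[i, 1],
                }
            )
        )
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def read_spectrum_table(path) -> MagnitudeSpectrumSet:
    """Read a long-format CSV spectrum table written by :func:`write_spectrum_table`."""
    df = pd.read_csv(path)
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"spectrum table missing columns: {missing}")
    dirs = df[["lateral", "polar"]].drop_duplicates().to_numpy()
    freqs = np.sort(df["frequency"].unique())
    axis = FrequencyAxis(freqs)
    mags = np.empty((len(dirs), 2, len(freqs)))
    for i, (lat, pol) in enumerate(dirs):
        sub = df[(df["lateral"] == lat) & (df["polar"] == pol)].sort_values("frequency")
        if len(sub) != len(freqs):
            raise ValueError("every direction must share the same frequency grid")
        mags[i, 0] = sub["left_db"].to_numpy()
        mags[i, 1] = sub["right_db"].to_numpy()
    return MagnitudeSpectrumSet(mags, dirs, axis)


def geodetic_to_interaural(azimuth_deg, elevation_deg):
    """Convert geodetic (azimuth, elevation) to interaural (lateral, polar) degrees.

    Azimuth counts counterclockwise from the front, elevation up from the
    horizontal plane. Lateral is in [-90, 90] (positive left under this
    convention is positive azimuth; flip outside if needed), polar in
    [-90, 270) around the interaural axis with front 0, above 90, back 180.
    """
    az = np.deg2rad(np.asarray(azimuth_deg, dtype=float))
    el = np.deg2rad(np.asarray(elevation_deg, dtype=float))
    lat = np.arcsin(np.clip(np.sin(az) * np.cos(el), -1.0, 1.0))
    pol = np.arctan2(np.sin(el), np.cos(az) * np.cos(el))
    pol = np.rad2deg(pol)
    pol = np.mod(pol + 90.0, 360.0) - 90.0
    return np.rad2deg(lat), pol


def read_sofa(path, n_fft: int = 512, floor_db: float = -100.0) -> MagnitudeSpectrumSet:
    """Read a SimpleFreeFieldHRIR SOFA file into dB magnitude spectra.

    Impulse responses are transformed with an ``n_fft``-point real FFT
    (default 512); the DC bin is dropped so the axis stays strictly positive.
    Source positions (spherical degrees) are converted to interaural
    coordinates. Requires h5py; the file is opened as plain HDF5.
    """
    import h5py

    with h5py.File(path, "r") as f:
        ir = np.asarray(f["Data.IR"])  # (M, R, N)
        fs = float(np.ravel(f["Data.SamplingRate"])[0])
        pos = np.asarray(f["SourcePosition"])  # (M, 3): azi, ele, r
    if ir.ndim != 3 or ir.shape[1] != 2:
        raise ValueError("expected binaural Data.IR with shape (M, 2, N)")
    spec = np.fft.rfft(ir, n=n_fft, axis=-1)
    mag = 20.0 * np.log10(np.maximum(np.abs(spec), 10 ** (floor_db / 20.0)))
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / fs)
    lat, pol = geodetic_to_interaural(pos[:, 0], pos[:, 1])
    dirs = np.column_stack([lat, pol])
    axis = FrequencyAxis(freqs[1:])
    return MagnitudeSpectrumSet(mag[:, :, 1:], dirs, axis)
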