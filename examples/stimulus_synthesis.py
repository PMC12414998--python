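"""Synthesize a looming-bias trial: a Schroeder-phase harmonic complex,
spatialized through two cue sets and crossfaded from one to the other.

A "looming" percept arises when the spectrum transitions from flattened
cues to the listener's shaped (native) cues; the crossfade onset is
jittered around 600 ms and the fade is a 10 ms raised cosine.
"""

import tempfile
from pathlib import Path

import numpy as np

from loombias import (
    ContrastSpec,
    FrequencyAxis,
    MagnitudeSpectrumSet,
    ToneComplexSpec,
    TransitionSpec,
    apply_hrtf,
    harmonic_complex,
    make_cue_sets,
    make_transition,
    rms_equalize,
    write_wav,
)

# source: 100 Hz harmonic complex, 1-16 kHz, phase curvature 0.5, 1.2 s
source = harmonic_complex(ToneComplexSpec(f0=100.0, duration=1.2))
print(f"source: {source.annotations['n_components']} components, RMS {source.rms():.3f}")

# toy directional spectra and their flattened counterpart
rng = np.random.default_rng(1)
axis = FrequencyAxis(np.linspace(86.13, 22050.0, 257))
f = axis.frequencies
mags = rng.normal(0, 1, (1, 2, 1)) + 5.0 * np.sin(
    2 * np.pi * np.log2(f / 1000.0)[None, None, :] / 2.0
)
specs = MagnitudeSpectrumSet(mags, np.array([[0.0, 45.0]]), axis)
cues = make_cue_sets(specs, ContrastSpec(C=1.0))

shaped = apply_hrtf(source, cues["native"], (0.0, 45.0))
flattened = apply_hrtf(source, cues["flat"], (0.0, 45.0))

looming = make_transition(flattened, shaped, TransitionSpec(), seed=7)
receding = make_transition(shaped, flattened, TransitionSpec(), seed=7)
looming, receding = rms_equalize([looming, receding], target_db=-20.0)

for name, stim in (("looming", looming), ("receding", receding)):
    print(
        f"{name:>9}: onset {stim.annotations['transition_onset']:.3f} s, "
        f"RMS {20 * np.log10(stim.rms()):.1f} dBFS, {stim.duration:.2f} s"
    )

out = Path(tempfile.mkdtemp()) / "looming.wav"
write_wav(looming, out)
print(f"wrote {out}")
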