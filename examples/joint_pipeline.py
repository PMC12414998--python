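"""End-to-end joint pipeline on ground-truth data:
epochs -> cluster test -> per-trial cluster scores -> EEG-informed LBA fit.

The synthetic bundle links the single-trial ERP amplitudes that drive the
cluster to the drift rates that drive behavior, so the fitted EEG slope
should recover the negative generating link.
"""

import numpy as np

from loombias import cluster_permutation, cluster_score, fit_hierarchical, neighbors_from_distance
from loombias.synth import CONDITIONS, SyntheticConfig, generate_joint_bundle

cfg = SyntheticConfig(n_subjects=10, n_channels=16, n_erp_trials=40, eeg_noise_sd=5.0)
bundle = generate_joint_bundle(cfg, seed=20)
ep = bundle.epochs

clusters = cluster_permutation(
    ep.condition_average("native-flattened"),
    ep.condition_average("native-shaped"),
    neighbors_from_distance(ep.layout, 0.05),
    ep.times,
    n_perm=1000,
    seed=21,
    window=(0.0, 0.3),
)
top = clusters[0]
print(
    f"top cluster: {top.polarity}, mass {top.mass:.1f}, p = {top.p_value:.4f}, "
    f"{top.tmin * 1000:.0f}-{top.tmax * 1000:.0f} ms"
)

scores = np.empty((cfg.n_subjects, len(CONDITIONS), cfg.n_erp_trials))
for s in range(cfg.n_subjects):
    for ci in range(len(CONDITIONS)):
        scores[s, ci] = cluster_score(ep.data[s, ci], ep.times, top)

trials = bundle.behavior.copy()
trials["eeg"] = scores.ravel()
post = fit_hierarchical(
    trials, formula="match + eeg", n_chains=2, n_samples=200, n_burn=300, seed=22
)
p_neg = float((post.eeg_slope_samples(scale="standardized") < 0).mean())
print(f"fitted EEG slope sign: P(beta < 0) = {p_neg:.3f} (generated with beta < 0)")
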