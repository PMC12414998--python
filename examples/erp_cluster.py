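"""Cluster-based permutation test on synthetic ERP epochs.

Condition-average ERPs are contrasted with a paired spatiotemporal cluster
test: per-sample t values above the cluster-forming threshold are grouped
into connected clusters, and the cluster-mass null is built from
within-participant condition swaps (sign flips of the difference maps).
"""

from loombias import baseline_correct, cluster_permutation, neighbors_from_distance
from loombias.synth import SyntheticConfig, gen_erp_epochs

cfg = SyntheticConfig(n_subjects=14, n_channels=32, n_erp_trials=40, erp_effect_uv=0.6)
epochs = gen_erp_epochs(cfg, seed=11)
epochs.data = baseline_correct(epochs.data, epochs.times)

condA = epochs.condition_average("native-flattened")
condB = epochs.condition_average("native-shaped")
adjacency = neighbors_from_distance(epochs.layout, 0.05)

clusters = cluster_permutation(
    condA, condB, adjacency, epochs.times, n_perm=2000, seed=12, window=(0.0, 0.3)
)
print(f"{len(clusters)} cluster(s) in 0-300 ms; those with p < 0.2:")
for c in (c for c in clusters if c.p_value < 0.2):
    chs = ", ".join(epochs.layout.names[i] for i in c.channels)
    print(
        f"  {c.polarity:>8}  mass {c.mass:9.2f}  p = {c.p_value:.4f}  "
        f"{c.tmin * 1000:.0f}-{c.tmax * 1000:.0f} ms  channels: {chs}"
    )
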