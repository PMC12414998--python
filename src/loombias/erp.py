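"""ERP statistics: baseline correction, trial equalization, and
nonparametric spatiotemporal cluster-based permutation tests.

The inference chain mirrors the standard event-related-potential workflow
for paired condition contrasts. Per (channel, time) sample a dependent-
samples t statistic is computed across participants; samples exceeding the
two-tailed cluster-forming threshold are grouped into spatiotemporally
connected clusters (neighboring channel at the same time, or adjacent time
on the same channel; positive and negative clusters never merge). Each
cluster's mass is the sum of its t values. The Monte-Carlo null is built by
randomly swapping the two conditions within participants (equivalently,
flipping the sign of each participant's difference map) and collecting the
maximum cluster mass per polarity; one-sided p-values against the
matching-polarity null are doubled (capped at 1) to account for two-tailed
testing. p-values use the (b + 1) / (n_perm + 1) convention so they are
never exactly zero.

Cluster scores — per-trial mean amplitudes over the cluster's time extent
and every channel that contributed to it at any point — summarize the
cluster for downstream single-trial modelling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

__all__ = [
    "ChannelLayout",
    "EpochsArray",
    "ClusterResult",
    "baseline_correct",
    "equalize_trials",
    "neighbors_from_distance",
    "suggest_distance_threshold",
    "cluster_permutation",
    "cluster_score",
]


@dataclass(frozen=True)
class ChannelLayout:
    """Channel names with 3-D positions (consistent arbitrary units)."""

    names: tuple
    positions: np.ndarray

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float)
        if len(set(self.names)) != len(self.names):
            raise ValueError("channel names must be unique")
        if pos.shape != (len(self.names), 3) or not np.all(np.isfinite(pos)):
            raise ValueError("positions must be finite with shape (n_channels, 3)")
        object.__setattr__(self, "names", tuple(self.names))
        object.__setattr__(self, "positions", pos)

    @classmethod
    def from_text(cls, path) -> "ChannelLayout":
        """Read a plain-text layout: one `name x y z` row per channel."""
        names, rows = [], []
        for line in Path(path).read_text().splitlines():
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            names.append(parts[0])
            rows.append([float(v) for v in parts[1:4]])
        return cls(tuple(names), np.asarray(rows))

    def __len__(self):
        return len(self.names)


@dataclass
class EpochsArray:
    """Epoched EEG: (participant, condition, trial, channel, time) in microvolts."""

    data: np.ndarray
    times: np.ndarray
    layout: ChannelLayout
    conditions: tuple

    def __post_init__(self):
        d = np.asarray(self.data, dtype=float)
        if d.ndim != 5:
            raise ValueError("data must be 5-D (participant, condition, trial, channel, time)")
        if d.shape[1] != len(self.conditions):
            raise ValueError("condition axis does not match condition labels")
        if d.shape[3] != len(self.layout) or d.shape[4] != len(self.times):
            raise ValueError("channel/time axes do not match layout/times")
        self.data = d
        self.times = np.asarray(self.times, dtype=float)
        self.conditions = tuple(self.conditions)

    def condition_average(self, condition) -> np.ndarray:
        """Per-participant trial-average ERP, shape (participant, channel, time)."""
        i = self.conditions.index(condition)
        return self.data[:, i].mean(axis=1)

    def save(self, directory) -> None:
        """Write the array (.npy) with a JSON sidecar describing the axes."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.save(directory / "epochs.npy", self.data)
        meta = {
            "dims": ["participant", "condition", "trial", "channel", "time"],
            "shape": list(self.data.shape),
            "times": self.times.tolist(),
            "conditions": list(self.conditions),
            "channel_names": list(self.layout.names),
            "channel_positions": self.layout.positions.tolist(),
        }
        (directory / "epochs.json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, directory) -> "EpochsArray":
        directory = Path(directory)
        meta = json.loads((directory / "epochs.json").read_text())
        data = np.load(directory / "epochs.npy")
        layout = ChannelLayout(
            tuple(meta["channel_names"]), np.asarray(meta["channel_positions"])
        )
        return cls(data, np.asarray(meta["times"]), layout, tuple(meta["conditions"]))


def baseline_correct(data: np.ndarray, times: np.ndarray, window=(-0.1, 0.0)) -> np.ndarray:
    """Subtract the mean over the baseline window along the last (time) axis.

    Applied per trial and channel; any leading axes are preserved.
    """
    times = np.asarray(times, dtype=float)
    mask = (times >= window[0]) & (times <= window[1])
    if not mask.any():
        raise ValueError(f"baseline window {window} contains no samples")
    return data - data[..., mask].mean(axis=-1, keepdims=True)


def equalize_trials(counts) -> list[np.ndarray]:
    """Blind trial equalization: retain min(counts) trials per condition.

    For a condition with ``n`` trials and ``r = n - min(counts)`` removals,
    the removed session positions (0-based) are floor((i + 0.5) * n / r),
    i = 0..r-1 — as evenly spaced over the session as possible. Returns the
    retained 0-based session positions per condition, deterministically.
    """
    counts = list(counts)
    if any(c < 1 for c in counts):
        raise ValueError("all condition counts must be >= 1")
    m = min(counts)
    retained = []
    for n in counts:
        r = n - m
        if r == 0:
            retained.append(np.arange(n))
            continue
        removed = np.floor((np.arange(r) + 0.5) * n / r).astype(int)
        keep = np.setdiff1d(np.arange(n), removed)
        retained.append(keep)
    return retained


def neighbors_from_distance(layout: ChannelLayout, threshold: float) -> np.ndarray:
    """Boolean adjacency: channels are neighbors iff Euclidean distance < threshold."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    pos = layout.positions
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    adj = d < threshold
    np.fill_diagonal(adj, False)
    return adj


def suggest_distance_threshold(layout: ChannelLayout, target_mean_neighbors: float = 7.0) -> float:
    """Distance threshold whose adjacency has about the target mean degree."""
    pos = layout.positions
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    vals = np.sort(np.unique(d[d > 0]))
    degrees = [((d < v).sum() - 0) / len(layout) for v in vals]
    best = int(np.argmin(np.abs(np.asarray(degrees) - target_mean_neighbors)))
    return float(vals[best])


@dataclass
class ClusterResult:
    """One spatiotemporal cluster with its mass statistic and Monte-Carlo p."""

    mass: float
    p_value: float
    polarity: str  # "positive" | "negative"
    members: np.ndarray  # (k, 2) array of (channel index, window time index)
    channels: np.ndarray  # sorted contributing channel indices
    time_indices: np.ndarray  # sorted window time indices touched
    tmin: float
    tmax: float
    window_times: np.ndarray = field(repr=False)


def _neighbor_pairs(adjacency: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    i, j = np.nonzero(np.triu(adjacency, 1))
    return i, j


def _label_clusters(mask: np.ndarray, pi: np.ndarray, pj: np.ndarray):
    """Connected components of True cells of mask (n_ch, n_t).

    Edges: same channel adjacent time; neighbor channels same time. Returns
    (flat cell indices, root label per cell).
    """
    n_ch, n_t = mask.shape
    cells = np.flatnonzero(mask.ravel())
    if cells.size == 0:
        return cells, cells
    # map flat index -> compact id
    comp = -np.ones(n_ch * n_t, dtype=np.int64)
    comp[cells] = np.arange(cells.size)
    # temporal edges
    te = mask[:, :-1] & mask[:, 1:]
    tc, tt = np.nonzero(te)
    ea = tc * n_t + tt
    eb = ea + 1
    # spatial edges
    if pi.size:
        se = mask[pi, :] & mask[pj, :]
        sp, st = np.nonzero(se)
        ea = np.concatenate([ea, pi[sp] * n_t + st])
        eb = np.concatenate([eb, pj[sp] * n_t + st])
    parent = np.arange(cells.size)

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for a, b in zip(comp[ea], comp[eb]):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra
    roots = np.array([find(k) for k in range(cells.size)])
    return cells, roots


def _max_cluster_masses(tmap: np.ndarray, thr: float, pi, pj) -> tuple[float, float]:
    """(max positive cluster mass, max |negative cluster mass|) of a t-map."""
    out = []
    for sign in (1.0, -1.0):
        mask = sign * tmap > thr
        cells, roots = _label_clusters(mask, pi, pj)
        if cells.size == 0:
            out.append(0.0)
            continue
        masses = np.bincount(roots, weights=sign * tmap.ravel()[cells])
        out.append(float(masses.max()))
    return out[0], out[1]


def _paired_t(diff_flat: np.ndarray) -> np.ndarray:
    n = diff_flat.shape[0]
    m = diff_flat.mean(axis=0)
    sd = diff_flat.std(axis=0, ddof=1)
    return m / np.maximum(sd, 1e-300) * np.sqrt(n)


def cluster_permutation(
    condA: np.ndarray,
    condB: np.ndarray,
    adjacency: np.ndarray,
    times: np.ndarray,
    n_perm: int = 10000,
    alpha: float = 0.05,
    cluster_alpha: float = 0.05,
    window: tuple = (0.0, 0.3),
    seed: int | None = None,
    chunk: int = 2000,
) -> list[ClusterResult]:
    """Cluster-based permutation test of a paired condition contrast.

    ``condA``/``condB`` are per-participant condition averages with shape
    (participant, channel, time). The analysis is restricted to ``window``
    on the time axis. ``cluster_alpha`` sets the two-tailed sample-level
    cluster-forming threshold (t critical value at participant df). Returns
    all detected clusters (either polarity) sorted by p-value; p-values are
    two-tailed ("prop"-corrected, i.e. one-sided Monte-Carlo p times 2,
    capped at 1). ``alpha`` is recorded for interpretation only.
    """
    condA = np.asarray(condA, float)
    condB = np.asarray(condB, float)
    if condA.shape != condB.shape or condA.ndim != 3:
        raise ValueError("condA/condB must both be (participant, channel, time)")
    n_subj = condA.shape[0]
    if n_subj < 2:
        raise ValueError("need >= 2 participants for a paired test")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    times = np.asarray(times, float)
    wmask = (times >= window[0]) & (times <= window[1])
    if not wmask.any():
        raise ValueError(f"analysis window {window} contains no samples")
    wt = times[wmask]
    D = (condA - condB)[:, :, wmask]
    n_ch, n_t = D.shape[1], D.shape[2]
    thr = float(stats.t.ppf(1.0 - cluster_alpha / 2.0, df=n_subj - 1))
    pi, pj = _neighbor_pairs(np.asarray(adjacency, bool))

    Dflat = D.reshape(n_subj, -1)
    t_obs = _paired_t(Dflat).reshape(n_ch, n_t)

    # observed clusters per polarity
    observed = []
    for sign, polarity in ((1.0, "positive"), (-1.0, "negative")):
        mask = sign * t_obs > thr
        cells, roots = _label_clusters(mask, pi, pj)
        if cells.size == 0:
            continue
        for r in np.unique(roots):
            sel = cells[roots == r]
            ch_idx = sel // n_t
            ti_idx = sel % n_t
            mass = float(t_obs.ravel()[sel].sum())
            observed.append(
                ClusterResult(
                    mass=mass,
                    p_value=np.nan,
                    polarity=polarity,
                    members=np.column_stack([ch_idx, ti_idx]),
                    channels=np.unique(ch_idx),
                    time_indices=np.unique(ti_idx),
                    tmin=float(wt[ti_idx.min()]),
                    tmax=float(wt[ti_idx.max()]),
                    window_times=wt,
                )
            )
    if not observed:
        return []

    # permutation null: within-participant condition swaps == sign flips of D
    rng = np.random.default_rng(seed)
    ss = (Dflat**2).sum(axis=0)
    null_pos = np.empty(n_perm)
    null_neg = np.empty(n_perm)
    done = 0
    while done < n_perm:
        c = min(chunk, n_perm - done)
        signs = rng.integers(0, 2, size=(c, n_subj)) * 2 - 1
        M = signs @ Dflat / n_subj
        var = (ss - n_subj * M**2) / (n_subj - 1)
        T = M / np.sqrt(np.maximum(var, 1e-300) / n_subj)
        for k in range(c):
            null_pos[done + k], null_neg[done + k] = _max_cluster_masses(
                T[k].reshape(n_ch, n_t), thr, pi, pj
            )
        done += c

    for cl in observed:
        null = null_pos if cl.polarity == "positive" else null_neg
        b = int((null >= abs(cl.mass)).sum())
        p_one = (b + 1) / (n_perm + 1)
        cl.p_value = min(1.0, 2.0 * p_one)
    observed.sort(key=lambda c: c.p_value)
    return observed


def cluster_score(
    trial_data: np.ndarray, times: np.ndarray, cluster: ClusterResult
) -> np.ndarray:
    """Per-trial mean amplitude over the cluster's rectangular extent.

    ``trial_data`` is (trial, channel, time). The score averages over the
    full [tmin, tmax] cluster epoch and every channel that contributed to
    the cluster at any point (not the ragged member set).
    """
    if cluster.channels.size == 0:
        raise ValueError("cluster has no members")
    times = np.asarray(times, float)
    tmask = (times >= cluster.tmin) & (times <= cluster.tmax)
    if not tmask.any():
        raise ValueError("cluster time extent not covered by the epochs' time axis")
    sub = trial_data[:, cluster.channels][:, :, tmask]
    return sub.mean(axis=(1, 2))
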