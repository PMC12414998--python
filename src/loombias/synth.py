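"""Ground-truth synthetic data for every pipeline stage.

The generator emulates the statistical structure the analysis assumes, at
the scale of the experiment it mirrors: 14 subjects, 8 blocks of 100
looming-bias trials (50 flattened / 50 shaped per block, blocks alternating
native/novel spectral cues starting with native), four source positions
(FU 45, FD 135, BU 225, BD 270 degrees polar), behavior simulated from the
hierarchical LBA forward model, single-trial EEG cluster amplitudes linearly
linked to drift rates (negative link by default), multichannel ERP epochs
with a known spatiotemporal effect whose polarity reverses between native
and novel cues, and localization responses with gain/bias/scatter plus
quadrant confusions biased toward the rear.

All randomness flows from one master seed through named substreams, so the
full bundle regenerates bit-identically and stages can be regenerated
independently.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .erp import ChannelLayout, EpochsArray
from .lba import LBAParams, simulate_lba
from .localization import wrap_polar

__all__ = [
    "SyntheticConfig",
    "SyntheticBundle",
    "POSITIONS",
    "synthetic_cap",
    "default_target_grid",
    "gen_subject_params",
    "gen_trial_skeleton",
    "gen_eeg_amplitudes",
    "gen_behavior",
    "gen_erp_epochs",
    "gen_localization_responses",
    "generate_bundle",
    "generate_joint_bundle",
]

# position label -> (polar deg, vertical, horizontal)
POSITIONS = {
    "FU": (45.0, "up", "front"),
    "FD": (135.0, "down", "front"),
    "BU": (225.0, "up", "back"),
    "BD": (270.0, "down", "back"),
}

CONDITIONS = ("native-flattened", "native-shaped", "novel-flattened", "novel-shaped")

# sign of the condition-mean cluster amplitude: native cues show the more
# negative amplitude for flattened stimuli, novel cues for shaped stimuli
_AMP_SIGN = {
    ("native", "flattened"): -1.0,
    ("native", "shaped"): 1.0,
    ("novel", "flattened"): 1.0,
    ("novel", "shaped"): -1.0,
}


@dataclass
class SyntheticConfig:
    """Full generative ground truth for the synthetic experiment."""

    # experiment scale
    n_subjects: int = 14
    n_blocks: int = 8
    trials_per_block: int = 100
    # group-level LBA parameters (natural scale) and between-subject SDs
    # (SDs act on log scale for A, B, t0)
    A: float = 0.5
    B: float = 1.0
    t0: float = 0.25
    sd_A: float = 0.15
    sd_B: float = 0.15
    sd_t0: float = 0.1
    s_v: float = 1.0
    # drift-rate coefficients (1/s) and their between-subject SDs
    drift_intercept: float = 2.0
    drift_match: float = 0.36  # accumulator-stimulus congruency advantage
    drift_direction: float = 0.1  # flattened vs shaped offset
    drift_cue: float = 0.1  # native vs novel offset
    sd_drift: float = 0.15
    # EEG single-trial link
    beta_eeg: float = -0.017  # 1/(uV s)
    sd_beta_eeg: float = 0.005
    eeg_contrast: float = 2.0  # uV between condition means
    eeg_noise_sd: float = 10.0  # uV single-trial amplitude SD
    # ERP epochs
    n_channels: int = 32
    n_erp_trials: int = 50  # per condition per subject
    erp_window: tuple = (0.08, 0.17)
    erp_effect_channels: int = 5
    erp_effect_uv: float = 0.5
    erp_noise_sd: float = 1.0
    erp_spatial_decay: float = 0.06  # m, exponential noise correlation length
    erp_fs: float = 100.0
    erp_tmin: float = -0.1
    erp_tmax: float = 1.5
    # localization response model
    loc_gain: float = 0.9
    loc_bias_lat: float = 0.0
    loc_bias_pol: float = 0.0
    loc_scatter_lat: float = 8.0
    loc_scatter_pol: float = 25.0
    loc_confusion_rate: float = 0.05
    loc_confusion_center: float = 180.0  # rear bias of confused responses
    loc_confusion_scatter: float = 20.0
    loc_trials: int = 300

    def validate(self):
        for name in ("sd_A", "sd_B", "sd_t0", "sd_drift", "eeg_noise_sd", "erp_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.loc_confusion_rate <= 1:
            raise ValueError("loc_confusion_rate must be in [0, 1]")
        return self


@dataclass
class SyntheticBundle:
    """Cross-referenced synthetic tables plus the generating ground truth."""

    behavior: pd.DataFrame
    eeg_amplitudes: pd.DataFrame
    epochs: EpochsArray | None
    localization: pd.DataFrame
    ground_truth: dict
    seed: int

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.behavior.to_csv(directory / "behavior.csv", index=False)
        self.eeg_amplitudes.to_csv(directory / "eeg_amplitudes.csv", index=False)
        self.localization.to_csv(directory / "localization.csv", index=False)
        gt = dict(self.ground_truth)
        gt["seed"] = self.seed
        (directory / "ground_truth.json").write_text(json.dumps(gt, default=_jsonable))
        if self.epochs is not None:
            self.epochs.save(directory / "epochs")


def _jsonable(x):
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    raise TypeError(f"not JSON-serializable: {type(x)}")


def _streams(seed: int, n: int):
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def synthetic_cap(n_channels: int = 32, radius: float = 0.1) -> ChannelLayout:
    """Quasi-uniform electrode layout on the upper hemisphere (Fibonacci)."""
    k = np.arange(n_channels)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    z = 0.05 + 0.95 * (k + 0.5) / n_channels  # upper hemisphere only
    r = np.sqrt(1.0 - z**2)
    theta = golden * k
    pos = radius * np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    names = tuple(f"E{i + 1}" for i in range(n_channels))
    return ChannelLayout(names, pos)


def default_target_grid() -> pd.DataFrame:
    """Fixture target grid sampling the median and coronal planes."""
    rows = []
    for pol in np.arange(-30.0, 211.0, 30.0):
        for lat in (-20.0, 0.0, 20.0):
            rows.append({"target_lat": lat, "target_pol": pol})
    for lat in np.arange(-80.0, 81.0, 20.0):
        rows.append({"target_lat": lat, "target_pol": 0.0})
    return pd.DataFrame(rows).drop_duplicates(ignore_index=True)


def gen_subject_params(config: SyntheticConfig, seed) -> list[dict]:
    """Draw per-subject LBA parameters and drift coefficients.

    Positivity of A, B, t0 is kept by drawing on the log scale. Returns one
    dictionary per subject with keys A, B, t0, s_v, drift coefficients and
    beta_eeg.
    """
    config.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = []
    for _ in range(config.n_subjects):
        out.append(
            {
                "A": float(np.exp(np.log(config.A) + config.sd_A * rng.standard_normal())),
                "B": float(np.exp(np.log(config.B) + config.sd_B * rng.standard_normal())),
                "t0": float(np.exp(np.log(config.t0) + config.sd_t0 * rng.standard_normal())),
                "s_v": config.s_v,
                "drift_intercept": config.drift_intercept
                + config.sd_drift * rng.standard_normal(),
                "drift_match": config.drift_match + config.sd_drift * rng.standard_normal(),
                "drift_direction": config.drift_direction
                + config.sd_drift * rng.standard_normal(),
                "drift_cue": config.drift_cue + config.sd_drift * rng.standard_normal(),
                "beta_eeg": config.beta_eeg + config.sd_beta_eeg * rng.standard_normal(),
            }
        )
    return out


def gen_trial_skeleton(config: SyntheticConfig, seed) -> pd.DataFrame:
    """Factorial trial table without responses.

    Blocks alternate native/novel cues starting with native; within each
    block half the trials are flattened and half shaped, in randomized
    order; positions are drawn uniformly from the four used in the study.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    labels = list(POSITIONS)
    for s in range(config.n_subjects):
        for b in range(config.n_blocks):
            cue = "native" if b % 2 == 0 else "novel"
            half = config.trials_per_block // 2
            dirs = np.array(["flattened"] * half + ["shaped"] * (config.trials_per_block - half))
            rng.shuffle(dirs)
            pos = rng.choice(labels, size=config.trials_per_block)
            for i in range(config.trials_per_block):
                pol, vert, horiz = POSITIONS[pos[i]]
                rows.append(
                    {
                        "subject": s,
                        "block": b,
                        "trial": b * config.trials_per_block + i,
                        "cue": cue,
                        "direction": dirs[i],
                        "position": pos[i],
                        "vertical": vert,
                        "horizontal": horiz,
                    }
                )
    return pd.DataFrame(rows)


def gen_eeg_amplitudes(skeleton: pd.DataFrame, config: SyntheticConfig, seed) -> pd.DataFrame:
    """Single-trial cluster amplitudes: condition mean + Gaussian noise.

    The condition means follow the observed polarity pattern (native cues:
    flattened more negative than shaped; reversed for novel cues) with a
    total between-condition contrast of ``eeg_contrast`` microvolts.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sign = np.array(
        [_AMP_SIGN[(c, d)] for c, d in zip(skeleton["cue"], skeleton["direction"])]
    )
    mean = sign * config.eeg_contrast / 2.0
    amp = mean + config.eeg_noise_sd * rng.standard_normal(len(skeleton))
    out = skeleton[["subject", "block", "trial", "cue", "direction"]].copy()
    out["eeg_amp"] = amp
    return out


def _drift_means(sub: pd.DataFrame, p: dict, amp: np.ndarray, config: SyntheticConfig):
    """Per-trial drift means for (looming, receding) accumulators."""
    flattened = (sub["direction"] == "flattened").to_numpy()
    native = (sub["cue"] == "native").to_numpy()
    base = (
        p["drift_intercept"]
        + p["drift_direction"] * flattened
        + p["drift_cue"] * native
        + p["beta_eeg"] * amp
    )
    v = np.empty((len(sub), 2))
    # accumulator 0 = looming: matches flattened stimuli
    v[:, 0] = base + p["drift_match"] * flattened
    v[:, 1] = base + p["drift_match"] * (~flattened)
    return v


def gen_behavior(
    skeleton: pd.DataFrame,
    subject_params: list[dict],
    config: SyntheticConfig,
    seed,
    eeg_amp: np.ndarray | None = None,
) -> pd.DataFrame:
    """Simulate choices and RTs from the LBA forward model per trial.

    When ``eeg_amp`` is given (one amplitude per skeleton row), the
    generative drift includes the subject's beta_eeg * amplitude term, so
    behavior and the amplitude table are dependent exactly as the joint
    model assumes.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    amp_all = np.zeros(len(skeleton)) if eeg_amp is None else np.asarray(eeg_amp, float)
    out = skeleton.copy()
    out["eeg_amp"] = amp_all
    out["choice"] = ""
    out["rt"] = np.nan
    for s, p in enumerate(subject_params):
        mask = (skeleton["subject"] == s).to_numpy()
        sub = skeleton[mask]
        v = _drift_means(sub, p, amp_all[mask], config)
        params = LBAParams(A=p["A"], B=p["B"], t0=p["t0"], v=[0.0, 0.0], s_v=p["s_v"])
        winner, rt = simulate_lba(params, seed=rng, v=v)
        out.loc[mask, "choice"] = np.where(winner == 0, "looming", "receding")
        out.loc[mask, "rt"] = rt
    return out


def gen_erp_epochs(
    config: SyntheticConfig,
    seed,
    layout: ChannelLayout | None = None,
    trial_amplitudes: np.ndarray | None = None,
) -> EpochsArray:
    """Multichannel ERP epochs with a known spatiotemporal effect.

    Per subject, condition and trial: spatially correlated Gaussian noise
    (exponential decay of channel covariance with distance) plus a
    condition-signed effect of ``erp_effect_uv`` microvolts inside the
    effect window on a set of adjacent channels. ``trial_amplitudes``
    (subject, condition, trial) overrides the deterministic condition
    effect with per-trial amplitudes, which links the epochs to behavior in
    the joint pipeline. Time axis [-0.1, 1.5] s at 100 Hz by default.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if layout is None:
        layout = synthetic_cap(config.n_channels)
    n_ch = len(layout)
    times = np.arange(
        round(config.erp_tmin * config.erp_fs), round(config.erp_tmax * config.erp_fs) + 1
    ) / config.erp_fs
    n_t = times.size
    d = np.linalg.norm(layout.positions[:, None] - layout.positions[None, :], axis=-1)
    cov = np.exp(-d / config.erp_spatial_decay)
    L = np.linalg.cholesky(cov + 1e-9 * np.eye(n_ch))
    # effect channels: the erp_effect_channels closest to the first electrode
    order = np.argsort(d[0])
    eff_ch = np.sort(order[: config.erp_effect_channels])
    wmask = (times >= config.erp_window[0]) & (times <= config.erp_window[1])
    profile = np.zeros((n_ch, n_t))
    profile[np.ix_(eff_ch, np.flatnonzero(wmask))] = 1.0

    shape = (config.n_subjects, len(CONDITIONS), config.n_erp_trials, n_ch, n_t)
    noise = rng.standard_normal(shape) * config.erp_noise_sd
    data = np.einsum("ij,scajt->scait", L, noise)
    if trial_amplitudes is None:
        for ci, cond in enumerate(CONDITIONS):
            cue, direction = cond.split("-")
            amp = _AMP_SIGN[(cue, direction)] * config.erp_effect_uv / 2.0
            data[:, ci] += amp * profile
    else:
        ta = np.asarray(trial_amplitudes, float)
        data += ta[..., None, None] * profile
    return EpochsArray(data, times, layout, CONDITIONS)


def gen_localization_responses(
    targets: pd.DataFrame, config: SyntheticConfig, seed, n_trials: int | None = None
) -> pd.DataFrame:
    """Localization responses with gain, bias, scatter and quadrant confusions.

    response = gain * target + bias + Gaussian scatter per dimension; with
    probability ``loc_confusion_rate`` the polar response is redrawn near the
    confusion center (default 180 deg, the rear bias seen with degraded
    spectral cues). Lateral responses are clipped to [-90, 90], polar
    responses wrapped into [-90, 270).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = n_trials if n_trials is not None else config.loc_trials
    idx = rng.integers(0, len(targets), n)
    tl = targets["target_lat"].to_numpy(float)[idx]
    tp = targets["target_pol"].to_numpy(float)[idx]
    rl = config.loc_gain * tl + config.loc_bias_lat + config.loc_scatter_lat * rng.standard_normal(n)
    rp = config.loc_gain * tp + config.loc_bias_pol + config.loc_scatter_pol * rng.standard_normal(n)
    confused = rng.uniform(size=n) < config.loc_confusion_rate
    rp = np.where(
        confused,
        config.loc_confusion_center + config.loc_confusion_scatter * rng.standard_normal(n),
        rp,
    )
    return pd.DataFrame(
        {
            "target_lat": tl,
            "target_pol": wrap_polar(tp),
            "resp_lat": np.clip(rl, -90.0, 90.0),
            "resp_pol": wrap_polar(rp),
            "confused": confused,
        }
    )


def generate_bundle(config: SyntheticConfig | None = None, seed: int = 0) -> SyntheticBundle:
    """Generate the full cross-referenced synthetic dataset from one seed."""
    config = (config or SyntheticConfig()).validate()
    r_params, r_skel, r_amp, r_beh, r_erp, r_loc = _streams(seed, 6)
    params = gen_subject_params(config, r_params)
    skeleton = gen_trial_skeleton(config, r_skel)
    amps = gen_eeg_amplitudes(skeleton, config, r_amp)
    behavior = gen_behavior(skeleton, params, config, r_beh, eeg_amp=amps["eeg_amp"].to_numpy())
    epochs = gen_erp_epochs(config, r_erp)
    targets = default_target_grid()
    localization = gen_localization_responses(targets, config, r_loc)
    gt = {"config": asdict(config), "subject_params": params}
    return SyntheticBundle(behavior, amps, epochs, localization, gt, seed)


def generate_joint_bundle(
    config: SyntheticConfig | None = None, seed: int = 0
) -> SyntheticBundle:
    """Bundle whose ERP epochs carry the same single-trial amplitudes that
    drive behavior, enabling the full joint pipeline (cluster test ->
    cluster scores -> EEG-informed LBA fit) on ground-truth data.

    The behavioral design is restricted to ``n_erp_trials`` trials per
    condition cell per subject so each behavior trial has exactly one epoch.
    """
    config = (config or SyntheticConfig()).validate()
    r_params, r_amp, r_beh, r_erp = _streams(seed, 4)
    params = gen_subject_params(config, r_params)
    # balanced skeleton: n_erp_trials per (cue, direction) cell
    rows = []
    for s in range(config.n_subjects):
        for ci, cond in enumerate(CONDITIONS):
            cue, direction = cond.split("-")
            for k in range(config.n_erp_trials):
                rows.append(
                    {
                        "subject": s,
                        "block": ci,
                        "trial": ci * config.n_erp_trials + k,
                        "cue": cue,
                        "direction": direction,
                        "position": "FU",
                        "vertical": "up",
                        "horizontal": "front",
                        "condition": cond,
                        "cond_trial": k,
                    }
                )
    skeleton = pd.DataFrame(rows)
    amps = gen_eeg_amplitudes(skeleton, config, r_amp)
    behavior = gen_behavior(skeleton, params, config, r_beh, eeg_amp=amps["eeg_amp"].to_numpy())
    ta = (
        amps["eeg_amp"]
        .to_numpy()
        .reshape(config.n_subjects, len(CONDITIONS), config.n_erp_trials)
    )
    epochs = gen_erp_epochs(config, r_erp, trial_amplitudes=ta)
    gt = {"config": asdict(config), "subject_params": params}
    return SyntheticBundle(behavior, amps, epochs, pd.DataFrame(), gt, seed)
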