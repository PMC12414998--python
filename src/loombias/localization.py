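"""Sound-localization scoring in interaural coordinates and chance references.

Directions are (lateral, polar) pairs: lateral in [-90, 90] degrees from
left to right, polar in [-90, 270) degrees around the interaural axis
(below -90, front 0, above 90, back 180). Three aggregate error measures
are used: the lateral error (mean absolute lateral difference), the
quadrant error rate (percentage of trials whose circular polar error
exceeds 90 degrees — front/back or up/down confusions) and the local polar
error (mean polar error over the remaining, non-confused trials).

Because polar-dimension performance can be poor, observed errors are
normalized by a chance reference obtained from a virtual experiment with
fully randomized responses over the response range: the ratio
observed/chance is ~1 at chance performance and 0 for perfect responses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "wrap_polar",
    "polar_error",
    "ErrorSummary",
    "score_trials",
    "score_by_participant",
    "uniform_response_sampler",
    "chance_simulation",
    "ChanceReference",
]


def wrap_polar(angle):
    """Wrap polar angles (deg) into the canonical range [-90, 270)."""
    return np.mod(np.asarray(angle, dtype=float) + 90.0, 360.0) - 90.0


def polar_error(target_polar, response_polar):
    """Absolute circular difference of polar angles, in [0, 180] degrees."""
    d = np.mod(np.asarray(response_polar, float) - np.asarray(target_polar, float), 360.0)
    return np.where(d > 180.0, 360.0 - d, d)


@dataclass(frozen=True)
class ErrorSummary:
    """Aggregate localization error measures.

    ``local_polar_error`` is NaN when every trial is a quadrant error (the
    local measure is then undefined).
    """

    lateral_error: float
    local_polar_error: float
    quadrant_error_rate: float  # percent
    n_trials: int
    n_local_trials: int


def _validate(df: pd.DataFrame) -> pd.DataFrame:
    need = ["target_lat", "target_pol", "resp_lat", "resp_pol"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")
    if len(df) == 0:
        raise ValueError("trial table is empty")
    for c in ("target_lat", "resp_lat"):
        if np.any(np.abs(df[c].to_numpy(float)) > 90.0 + 1e-9):
            raise ValueError(f"{c} outside [-90, 90]")
    return df


def score_trials(trials: pd.DataFrame, local_threshold: float = 90.0) -> ErrorSummary:
    """Score a trial table with columns target_lat/target_pol/resp_lat/resp_pol.

    Polar errors above ``local_threshold`` (default 90 deg) count as quadrant
    errors and are excluded from the local polar error.
    """
    df = _validate(trials)
    lat_err = np.abs(df["resp_lat"].to_numpy(float) - df["target_lat"].to_numpy(float))
    pol_err = polar_error(df["target_pol"].to_numpy(float), df["resp_pol"].to_numpy(float))
    local = pol_err <= local_threshold
    n = len(df)
    n_local = int(local.sum())
    return ErrorSummary(
        lateral_error=float(lat_err.mean()),
        local_polar_error=float(pol_err[local].mean()) if n_local else float("nan"),
        quadrant_error_rate=100.0 * (n - n_local) / n,
        n_trials=n,
        n_local_trials=n_local,
    )


def score_by_participant(
    trials: pd.DataFrame, by=("participant",), local_threshold: float = 90.0
) -> pd.DataFrame:
    """Score per group (default per participant) and return one row per group.

    Matches repeated-measures usage: aggregate within participant first, then
    across participants.
    """
    rows = []
    for key, sub in trials.groupby(list(by)):
        s = score_trials(sub, local_threshold)
        key = key if isinstance(key, tuple) else (key,)
        rows.append(
            dict(zip(by, key))
            | {
                "lateral_error": s.lateral_error,
                "local_polar_error": s.local_polar_error,
                "quadrant_error_rate": s.quadrant_error_rate,
                "n_trials": s.n_trials,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ChanceReference:
    """Chance-level error measures and observed/chance ratios (when supplied)."""

    lateral_error: float
    local_polar_error: float
    quadrant_error_rate: float
    ratios: dict | None = None


def uniform_response_sampler(targets: pd.DataFrame):
    """Uniform sampler over the rectangle spanned by the target range.

    Lateral responses are uniform on [min, max] of the target laterals;
    polar responses uniform on [min, max] of the target polars (canonical
    range). This realizes an equal response distribution inside the target
    range.
    """
    lat = targets["target_lat"].to_numpy(float)
    pol = wrap_polar(targets["target_pol"].to_numpy(float))
    lat_lo, lat_hi = float(lat.min()), float(lat.max())
    pol_lo, pol_hi = float(pol.min()), float(pol.max())

    def sample(target_lat, target_pol, rng: np.random.Generator):
        n = len(target_lat)
        return (
            rng.uniform(lat_lo, lat_hi, n),
            rng.uniform(pol_lo, pol_hi, n),
        )

    return sample


def chance_simulation(
    targets: pd.DataFrame,
    sampler=None,
    n_sim: int = 100,
    seed: int | None = None,
    observed: ErrorSummary | None = None,
    local_threshold: float = 90.0,
) -> ChanceReference:
    """Virtual localization experiment with fully randomized responses.

    Each of the ``n_sim`` replicates resamples the actual target list (with
    replacement) and draws one random response per trial from
    ``sampler(target_lat, target_pol, rng)`` (default: uniform inside the
    target range, ignoring the targets); replicate scores are averaged.
    If ``observed`` is given, observed/chance ratios are attached.
    """
    if len(targets) == 0:
        raise ValueError("target list is empty")
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    if sampler is None:
        sampler = uniform_response_sampler(targets)
    rng = np.random.default_rng(seed)
    tl = targets["target_lat"].to_numpy(float)
    tp = targets["target_pol"].to_numpy(float)
    n = len(targets)
    lat_e = np.empty(n_sim)
    pol_e = np.empty(n_sim)
    qe = np.empty(n_sim)
    for i in range(n_sim):
        idx = rng.integers(0, n, n)
        rl, rp = sampler(tl[idx], tp[idx], rng)
        s = score_trials(
            pd.DataFrame(
                {"target_lat": tl[idx], "target_pol": tp[idx], "resp_lat": rl, "resp_pol": rp}
            ),
            local_threshold,
        )
        lat_e[i], pol_e[i], qe[i] = s.lateral_error, s.local_polar_error, s.quadrant_error_rate
    ref = dict(
        lateral_error=float(lat_e.mean()),
        local_polar_error=float(np.nanmean(pol_e)),
        quadrant_error_rate=float(qe.mean()),
    )
    ratios = None
    if observed is not None:
        ratios = {
            "lateral_error": observed.lateral_error / ref["lateral_error"],
            "local_polar_error": observed.local_polar_error / ref["local_polar_error"],
            "quadrant_error_rate": observed.quadrant_error_rate / ref["quadrant_error_rate"],
        }
    return ChanceReference(**ref, ratios=ratios)
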