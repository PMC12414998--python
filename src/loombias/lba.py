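"""Linear ballistic accumulator (LBA) decision model with hierarchical
Bayesian estimation and a single-trial EEG drift regressor.

Model
-----
Each response option has one accumulator. On a trial, accumulator ``i``
starts at a point drawn uniformly from [0, A], accumulates evidence
linearly at a drift rate drawn (across trials) from a normal distribution
with mean ``v_i`` and SD ``s_v``, and responds when it reaches threshold
``b = A + B`` (``B > 0`` keeps the threshold above the start-point range).
The first accumulator to reach threshold determines the choice; the
response time is the passage time plus a non-decision time ``t0``. Drifts
are truncated at zero by default, so every race terminates and the joint
(choice, RT) "defective" densities integrate to exactly one across
choices.

Drift rates are parameterized by the experimental design through a linear
model over the trial factors — stimulus-response match, motion direction,
spectral cue, vertical and horizontal position — optionally extended by a
continuous single-trial EEG cluster amplitude:

    v ~ match * direction * cue + vertical * horizontal + eeg

Hierarchical estimation samples subject-level parameters (log A, log B,
log t0, drift coefficients) and group-level means and SDs with an adaptive
random-walk Metropolis-within-Gibbs sampler (conjugate Gibbs updates for
the group level). Convergence is monitored with the split Gelman-Rubin
R-hat; model comparison uses the Bayesian Predictive Information Criterion
(BPIC = mean deviance + 2 * p_D) and a BIC-difference Bayes-factor
approximation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from patsy import build_design_matrices, dmatrix
from scipy import stats
from scipy.special import ndtr

_SQRT2PI = np.sqrt(2.0 * np.pi)


def _phi(z):
    return np.exp(-0.5 * z * z) / _SQRT2PI

__all__ = [
    "LBAParams",
    "LBADesign",
    "LBAPosterior",
    "LBAPriors",
    "ContrastReport",
    "lba_node_pdf_cdf",
    "defective_density",
    "defective_loglik",
    "simulate_lba",
    "build_design",
    "loglik",
    "fit_hierarchical",
    "gelman_rubin",
    "split_rhat",
    "bpic",
    "bf_from_bic",
    "contrast_delta",
    "contraction",
]

ACCUMULATORS = ("looming", "receding")
_TINY_A = 1e-8


@dataclass
class LBAParams:
    """Single-subject LBA parameters; threshold is b = A + B."""

    A: float
    B: float
    t0: float
    v: np.ndarray
    s_v: float = 1.0

    def __post_init__(self):
        if self.A < 0 or self.B <= 0 or self.t0 < 0 or self.s_v <= 0:
            raise ValueError("require A >= 0, B > 0, t0 >= 0, s_v > 0")
        self.v = np.atleast_1d(np.asarray(self.v, dtype=float))

    @property
    def b(self) -> float:
        return self.A + self.B


def lba_node_pdf_cdf(t, A, b, v, s_v, truncated: bool = True):
    """Density and CDF of one accumulator's first-passage time.

    Start point uniform on [0, A], threshold ``b``, drift normal with mean
    ``v`` and SD ``s_v`` (truncated to positive drifts when ``truncated``;
    then the CDF tends to 1). Vectorized over all arguments; t <= 0 yields
    (0, 0).
    """
    t = np.asarray(t, dtype=float)
    A = np.asarray(A, dtype=float)
    b = np.asarray(b, dtype=float)
    v = np.asarray(v, dtype=float)
    s_v = np.asarray(s_v, dtype=float)
    if np.any(b <= 0) or np.any(A < 0) or np.any(s_v <= 0):
        raise ValueError("require b > 0, A >= 0, s_v > 0")
    t, A, b, v, s_v = np.broadcast_arrays(t, A, b, v, s_v)
    pos = t > 0
    ts = np.where(pos, t, 1.0)  # avoid division by zero off-support

    small_A = A < _TINY_A
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        # general-A closed forms
        Asafe = np.where(small_A, 1.0, A)
        z1 = (b - Asafe - ts * v) / (ts * s_v)
        z2 = (b - ts * v) / (ts * s_v)
        cdf_g = (
            1.0
            + (b - Asafe - ts * v) / Asafe * ndtr(z1)
            - (b - ts * v) / Asafe * ndtr(z2)
            + ts * s_v / Asafe * (_phi(z1) - _phi(z2))
        )
        pdf_g = (
            -v * ndtr(z1)
            + s_v * _phi(z1)
            + v * ndtr(z2)
            - s_v * _phi(z2)
        ) / Asafe
        # A -> 0 limit: passage time b / drift
        zz = (v - b / ts) / s_v
        cdf_0 = ndtr(zz)
        pdf_0 = _phi(zz) * b / (ts**2 * s_v)

        cdf = np.where(small_A, cdf_0, cdf_g)
        pdf = np.where(small_A, pdf_0, pdf_g)
        if truncated:
            p_pos = ndtr(v / s_v)
            cdf = cdf / p_pos
            pdf = pdf / p_pos

    pdf = np.where(pos, np.clip(pdf, 0.0, None), 0.0)
    cdf = np.where(pos, np.clip(cdf, 0.0, 1.0), 0.0)
    return pdf, cdf


def defective_density(choice: int, rt, params: LBAParams, truncated: bool = True):
    """Joint (choice, RT) density: f_winner * prod_losers (1 - F_loser).

    ``choice`` indexes the winning accumulator; RTs at or below t0 have
    density 0. Summed/integrated over choices and RT this equals 1 under the
    truncated-drift convention.
    """
    rt = np.asarray(rt, dtype=float)
    t = rt - params.t0
    dens = np.ones_like(t)
    for i, vi in enumerate(params.v):
        f, F = lba_node_pdf_cdf(t, params.A, params.b, vi, params.s_v, truncated)
        dens = dens * (f if i == choice else (1.0 - F))
    return np.where(t > 0, dens, 0.0)


def defective_loglik(rt, choice, v, A, b, t0, s_v=1.0, truncated: bool = True):
    """Sum of log defective densities for trial-wise drift means.

    ``rt``/``choice`` are (n,) arrays, ``v`` is (n, n_acc) with one drift
    mean per accumulator per trial. Any rt <= t0 makes the result -inf.
    """
    rt = np.asarray(rt, dtype=float)
    choice = np.asarray(choice, dtype=int)
    v = np.asarray(v, dtype=float)
    t = rt - t0
    if np.any(t <= 0):
        return -np.inf
    f, F = lba_node_pdf_cdf(t[:, None], A, b, v, s_v, truncated)
    n = rt.size
    fw = f[np.arange(n), choice]
    surv = 1.0 - F
    surv[np.arange(n), choice] = 1.0
    with np.errstate(divide="ignore"):
        ll = np.log(fw) + np.log(surv).sum(axis=1)
    return float(ll.sum())


def simulate_lba(
    params: LBAParams,
    n: int | None = None,
    seed=None,
    v: np.ndarray | None = None,
    truncated: bool = True,
):
    """Forward-simulate choices and RTs from the race model.

    Either ``n`` trials with the drift means in ``params.v``, or trial-wise
    drift means ``v`` of shape (n, n_acc). Reproducible under ``seed`` (an
    int or a Generator).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if v is None:
        if n is None:
            raise ValueError("give either n or trial-wise v")
        v = np.broadcast_to(params.v, (n, params.v.size))
    v = np.asarray(v, dtype=float)
    n, n_acc = v.shape
    if truncated:
        a = (0.0 - v) / params.s_v
        drifts = stats.truncnorm.rvs(
            a, np.inf, loc=v, scale=params.s_v, size=(n, n_acc), random_state=rng
        )
    else:
        drifts = v + params.s_v * rng.standard_normal((n, n_acc))
        drifts = np.where(drifts <= 0, np.nan, drifts)
    starts = rng.uniform(0.0, params.A, size=(n, n_acc)) if params.A > 0 else np.zeros((n, n_acc))
    with np.errstate(invalid="ignore", divide="ignore"):
        times = (params.b - starts) / drifts
    times = np.where(np.isfinite(times), times, np.inf)
    winner = np.argmin(times, axis=1)
    rt = params.t0 + times[np.arange(n), winner]
    return winner, rt


@dataclass
class LBADesign:
    """Expanded drift-rate design: per-trial, per-accumulator model matrix."""

    formula: str
    X: np.ndarray  # (n_trials, n_acc, p)
    column_names: list
    design_info: object = field(repr=False)
    accumulators: tuple = ACCUMULATORS
    has_eeg: bool = False

    @property
    def n_coef(self) -> int:
        return self.X.shape[2]

    def drift_means(self, beta: np.ndarray) -> np.ndarray:
        """v = X beta, shape (n_trials, n_acc)."""
        return self.X @ np.asarray(beta, dtype=float)

    def cell_vector(self, cell: dict) -> np.ndarray:
        """Design row for one condition cell (eeg defaults to 0)."""
        row = dict(cell)
        if self.has_eeg:
            row.setdefault("eeg", 0.0)
        try:
            (mat,) = build_design_matrices([self.design_info], pd.DataFrame([row]))
        except Exception as exc:  # patsy raises several types for unknown levels
            raise KeyError(f"cannot resolve cell {cell!r} under the design: {exc}") from exc
        return np.asarray(mat)[0]


def _accumulator_frame(trials: pd.DataFrame, accumulator: str) -> pd.DataFrame:
    frame = pd.DataFrame(index=trials.index)
    if "direction" in trials:
        d = trials["direction"].astype(str)
        congruent = (d == "flattened") == (accumulator == "looming")
        frame["match"] = np.where(congruent, "match", "nonmatch")
    for col in ("direction", "cue", "vertical", "horizontal"):
        if col in trials:
            frame[col] = trials[col].astype(str)
    if "eeg" in trials:
        frame["eeg"] = trials["eeg"].astype(float)
    elif "eeg_amp" in trials:
        frame["eeg"] = trials["eeg_amp"].astype(float)
    frame["accumulator"] = accumulator
    return frame


def build_design(
    trials: pd.DataFrame,
    formula: str = "match*direction*cue + vertical*horizontal + eeg",
    accumulators: tuple = ACCUMULATORS,
) -> LBADesign:
    """Expand a drift-rate formula into a per-trial, per-accumulator matrix.

    The ``match`` factor codes accumulator-stimulus congruency (a flattened
    stimulus matches the looming accumulator, a shaped stimulus the receding
    one), so the matrix differs between the two accumulators of each trial.
    A leading ``v ~`` on the formula is accepted and stripped. A ``eeg``
    term pulls the continuous single-trial amplitude from the ``eeg`` (or
    ``eeg_amp``) column.
    """
    rhs = formula.split("~", 1)[-1].strip()
    frames = [_accumulator_frame(trials, a) for a in accumulators]
    stacked = pd.concat(frames, ignore_index=True)
    mat = dmatrix(rhs, stacked, return_type="matrix")
    X = np.asarray(mat)
    names = list(mat.design_info.column_names)
    p = X.shape[1]
    if np.linalg.matrix_rank(X) < p:
        raise ValueError(
            f"rank-deficient design ({np.linalg.matrix_rank(X)} < {p}); columns: {names}"
        )
    n_trials = len(trials)
    X = X.reshape(len(accumulators), n_trials, p).transpose(1, 0, 2)
    return LBADesign(
        formula=rhs,
        X=X,
        column_names=names,
        design_info=mat.design_info,
        accumulators=tuple(accumulators),
        has_eeg="eeg" in rhs.replace(" ", "").split("+") or "eeg" in names,
    )


def loglik(trials: pd.DataFrame, design: LBADesign, params: dict, truncated: bool = True):
    """Log-likelihood of a subject's trials under a parameter dictionary.

    ``params`` holds scalars A, B, t0 (and optionally s_v) plus the drift
    coefficient vector ``beta`` matching the design columns.
    """
    rt = trials["rt"].to_numpy(float)
    choice_idx = _choice_index(trials, design)
    v = design.drift_means(params["beta"])
    return defective_loglik(
        rt,
        choice_idx,
        v,
        params["A"],
        params["A"] + params["B"],
        params["t0"],
        params.get("s_v", 1.0),
        truncated,
    )


def _choice_index(trials: pd.DataFrame, design: LBADesign) -> np.ndarray:
    ch = trials["choice"]
    if ch.dtype.kind in "iu":
        return ch.to_numpy(int)
    lookup = {a: i for i, a in enumerate(design.accumulators)}
    return ch.map(lookup).to_numpy(int)


# ---------------------------------------------------------------------------
# hierarchical estimation


@dataclass
class LBAPriors:
    """Weakly informative hierarchical priors.

    Group means are normal(m0, s0^2) per parameter (on the sampling scale:
    log A, log B, log t0, raw drift coefficients); group variances are
    inverse-gamma(a0, b0).
    """

    m0: np.ndarray
    s0: np.ndarray
    a0: float = 2.0
    b0: float = 0.1

    @classmethod
    def default(cls, n_beta: int) -> "LBAPriors":
        m0 = np.concatenate([[np.log(0.5), np.log(1.0), np.log(0.2)], np.zeros(n_beta)])
        s0 = np.concatenate([[1.0, 1.0, 1.0], np.full(n_beta, 3.0)])
        return cls(m0=m0, s0=s0)


@dataclass
class LBAPosterior:
    """Posterior samples from the hierarchical sampler.

    Arrays are indexed (chain, sample, ...): ``subject`` additionally by
    (subject, parameter) and the group arrays by parameter. ``param_names``
    orders the parameter axis as [log_A, log_B, log_t0, beta...].
    """

    subject: np.ndarray
    group_mean: np.ndarray
    group_sd: np.ndarray
    loglik: np.ndarray
    param_names: list
    design: LBADesign | None = None
    priors: LBAPriors | None = None
    seed: int | None = None
    eeg_sd_by_subject: dict | None = None
    _data: object = field(default=None, repr=False)

    @property
    def n_chains(self) -> int:
        return self.subject.shape[0]

    def group_mean_samples(self, name: str) -> np.ndarray:
        return self.group_mean[:, :, self.param_names.index(name)]

    def beta_group_samples(self) -> np.ndarray:
        """Group-level drift-coefficient samples, (chain, sample, n_beta)."""
        return self.group_mean[:, :, 3:]

    def eeg_slope_samples(self, scale: str = "raw") -> np.ndarray:
        """Posterior samples of the EEG-amplitude drift slope.

        ``scale="standardized"`` returns the group-mean coefficient of the
        within-subject z-scored amplitude (dimensionless per unit SD);
        ``scale="raw"`` converts back to 1/(microvolt*second) by dividing
        each subject's coefficient by that subject's amplitude SD and
        averaging over subjects per posterior draw.
        """
        try:
            k = self.param_names.index("beta:eeg")
        except ValueError as exc:
            raise ValueError("model has no eeg term") from exc
        if scale == "standardized" or not self.eeg_sd_by_subject:
            return self.group_mean[:, :, k]
        sds = np.asarray(list(self.eeg_sd_by_subject.values()))
        return (self.subject[:, :, :, k] / sds).mean(axis=2)

    def posterior_mean_params(self):
        """Per-subject posterior-mean parameter vectors, (n_subjects, p)."""
        return self.subject.mean(axis=(0, 1))

    def total_loglik_at_mean(self) -> float:
        if self._data is None:
            raise ValueError("posterior holds no data reference")
        theta = self.posterior_mean_params()
        return _total_loglik(theta, *self._data)

    def bpic(self) -> float:
        return bpic(self.loglik.ravel(), self.total_loglik_at_mean())

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savez(
            directory / "posterior.npz",
            subject=self.subject,
            group_mean=self.group_mean,
            group_sd=self.group_sd,
            loglik=self.loglik,
        )
        meta = {
            "param_names": self.param_names,
            "formula": self.design.formula if self.design else None,
            "seed": self.seed,
        }
        (directory / "posterior.json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, directory) -> "LBAPosterior":
        directory = Path(directory)
        arrs = np.load(directory / "posterior.npz")
        meta = json.loads((directory / "posterior.json").read_text())
        return cls(
            subject=arrs["subject"],
            group_mean=arrs["group_mean"],
            group_sd=arrs["group_sd"],
            loglik=arrs["loglik"],
            param_names=meta["param_names"],
            seed=meta["seed"],
        )


def _unpack(theta: np.ndarray) -> dict:
    return {
        "A": float(np.exp(theta[0])),
        "B": float(np.exp(theta[1])),
        "t0": float(np.exp(theta[2])),
        "beta": theta[3:],
    }


def _subject_loglik(theta, rt, choice, X, s_v, truncated):
    p = _unpack(theta)
    v = X @ p["beta"]
    return defective_loglik(rt, choice, v, p["A"], p["A"] + p["B"], p["t0"], s_v, truncated)


def _total_loglik(theta_by_subject, datasets, s_v, truncated):
    total = 0.0
    for theta, (rt, choice, X) in zip(theta_by_subject, datasets):
        total += _subject_loglik(theta, rt, choice, X, s_v, truncated)
    return total


def fit_hierarchical(
    trials: pd.DataFrame,
    formula: str = "match*direction*cue + vertical*horizontal + eeg",
    priors: LBAPriors | None = None,
    n_chains: int = 3,
    n_samples: int = 500,
    n_burn: int | None = None,
    thin: int = 1,
    seed: int | None = None,
    s_v: float = 1.0,
    truncated: bool = True,
    prior_only: bool = False,
    design: LBADesign | None = None,
    rhat_threshold: float = 1.1,
    standardize_eeg: bool = True,
) -> LBAPosterior:
    """Hierarchical Bayesian LBA fit by adaptive Metropolis-within-Gibbs.

    ``trials`` must contain a ``subject`` column plus the factor/response
    columns used by the formula. Subject parameter blocks (structural
    [log A, log B, log t0] and drift coefficients) are updated with adaptive
    random-walk Metropolis steps (scales tuned toward ~30% acceptance during
    burn-in); group means and variances use conjugate Gibbs updates. Draws
    are reproducible under ``seed``. A convergence warning (split R-hat
    above ``rhat_threshold`` for any group-level parameter) is attached to
    the returned posterior as ``converged``/``max_rhat`` attributes rather
    than raised.
    """
    if n_chains < 2:
        raise ValueError("need >= 2 chains for convergence diagnostics")
    subjects = sorted(trials["subject"].unique())
    if len(subjects) < 2:
        raise ValueError("hierarchical fit needs >= 2 subjects")
    eeg_sds = None
    eeg_col = "eeg" if "eeg" in trials.columns else ("eeg_amp" if "eeg_amp" in trials.columns else None)
    wants_eeg = "eeg" in formula.replace(" ", "")
    if design is None and standardize_eeg and wants_eeg and eeg_col is not None:
        # z-score the EEG covariate within subject for well-conditioned
        # sampling; the raw-scale slope is recovered afterwards
        trials = trials.copy()
        eeg_sds = {}
        for s in subjects:
            m = trials["subject"] == s
            vals = trials.loc[m, eeg_col].to_numpy(float)
            sd = vals.std(ddof=1)
            if sd <= 0:
                raise ValueError(f"subject {s} has constant EEG amplitudes")
            trials.loc[m, eeg_col] = (vals - vals.mean()) / sd
            eeg_sds[s] = float(sd)
    if design is None:
        design = build_design(trials, formula)
    n_beta = design.n_coef
    P = 3 + n_beta
    if priors is None:
        priors = LBAPriors.default(n_beta)
    if n_burn is None:
        n_burn = n_samples

    # per-subject data slices (rows of the stacked design matrix)
    datasets = []
    min_rt = []
    for s in subjects:
        mask = (trials["subject"] == s).to_numpy()
        sub = trials[mask]
        rt = sub["rt"].to_numpy(float)
        choice = _choice_index(sub, design)
        X = design.X[mask]
        datasets.append((rt, choice, X))
        min_rt.append(rt.min())
    S = len(subjects)

    if prior_only:
        def sub_ll(theta, k):
            return 0.0
    else:
        def sub_ll(theta, k):
            rt, choice, X = datasets[k]
            return _subject_loglik(theta, rt, choice, X, s_v, truncated)

    ss = np.random.SeedSequence(seed)
    chain_seeds = ss.spawn(n_chains)

    n_keep = n_samples
    subj_out = np.empty((n_chains, n_keep, S, P))
    mu_out = np.empty((n_chains, n_keep, P))
    sd_out = np.empty((n_chains, n_keep, P))
    ll_out = np.empty((n_chains, n_keep))

    blocks = [np.arange(3), np.arange(3, P)]

    for c in range(n_chains):
        rng = np.random.default_rng(chain_seeds[c])
        theta = np.empty((S, P))
        for k in range(S):
            theta[k, 0] = np.log(0.3)
            theta[k, 1] = np.log(0.8)
            theta[k, 2] = np.log(max(0.5 * min_rt[k], 1e-3))
            theta[k, 3:] = 0.0
            if n_beta:
                theta[k, 3] = 2.0  # intercept: positive mean drift
            theta[k] += 0.05 * rng.standard_normal(P)
        mu = theta.mean(axis=0)
        sig2 = np.full(P, 0.2)
        curr_ll = np.array([sub_ll(theta[k], k) for k in range(S)])
        # fall back for -inf inits: shrink t0
        for k in range(S):
            tries = 0
            while not np.isfinite(curr_ll[k]) and tries < 20:
                theta[k, 2] -= 0.5
                curr_ll[k] = sub_ll(theta[k], k)
                tries += 1
        step = np.full(S, 0.08)  # scalar proposal scale per subject
        prop_chol = [np.eye(P) for _ in range(S)]
        cov_installed = np.zeros(S, dtype=bool)
        acc = np.zeros(S)
        tried = np.zeros(S)
        history = np.empty((n_burn, S, P)) if n_burn else None

        total_iter = n_burn + n_keep * thin
        kept = 0
        for it in range(total_iter):
            if prior_only:
                # flat likelihood: the posterior is the prior itself, so
                # draw the whole hierarchy i.i.d. from it
                mu = priors.m0 + priors.s0 * rng.standard_normal(P)
                sig2 = priors.b0 / rng.gamma(priors.a0, 1.0, size=P)
                theta = mu + np.sqrt(sig2) * rng.standard_normal((S, P))
                curr_ll[:] = 0.0
            for k in range(0 if prior_only else S):
                prop = theta[k] + step[k] * (prop_chol[k] @ rng.standard_normal(P))
                new_ll = sub_ll(prop, k)
                if np.isfinite(new_ll):
                    lp_new = new_ll - 0.5 * np.sum((prop - mu) ** 2 / sig2)
                    lp_old = curr_ll[k] - 0.5 * np.sum((theta[k] - mu) ** 2 / sig2)
                    if np.log(rng.uniform()) < lp_new - lp_old:
                        theta[k] = prop
                        curr_ll[k] = new_ll
                        acc[k] += 1
                tried[k] += 1
            if it < n_burn:
                history[it] = theta
                # adapt scalar scale toward ~25% acceptance and, once enough
                # draws exist, shape the proposal with the empirical covariance
                if (it + 1) % 25 == 0:
                    rate = acc / np.maximum(tried, 1)
                    step *= np.exp(rate - 0.25)
                    step = np.clip(step, 1e-4, 2.0)
                    acc[:] = 0
                    tried[:] = 0
                    if it + 1 >= 150:
                        lo = max(0, it + 1 - 500)
                        for k in range(S):
                            cov = np.cov(history[lo : it + 1, k].T)
                            try:
                                prop_chol[k] = np.linalg.cholesky(cov + 1e-8 * np.eye(P))
                                if not cov_installed[k]:
                                    step[k] = 2.38 / np.sqrt(P)
                                    cov_installed[k] = True
                            except np.linalg.LinAlgError:
                                pass
            # conjugate group updates
            prec = S / sig2 + 1.0 / priors.s0**2
            mean = (theta.sum(axis=0) / sig2 + priors.m0 / priors.s0**2) / prec
            mu = mean + rng.standard_normal(P) / np.sqrt(prec)
            a_post = priors.a0 + 0.5 * S
            b_post = priors.b0 + 0.5 * ((theta - mu) ** 2).sum(axis=0)
            sig2 = b_post / rng.gamma(a_post, 1.0, size=P)
            if it >= n_burn and (it - n_burn) % thin == 0 and kept < n_keep:
                subj_out[c, kept] = theta
                mu_out[c, kept] = mu
                sd_out[c, kept] = np.sqrt(sig2)
                ll_out[c, kept] = curr_ll.sum()
                kept += 1

    names = ["log_A", "log_B", "log_t0"] + [f"beta:{n}" for n in design.column_names]
    post = LBAPosterior(
        subject=subj_out,
        group_mean=mu_out,
        group_sd=sd_out,
        loglik=ll_out,
        param_names=names,
        design=design,
        priors=priors,
        seed=seed,
        eeg_sd_by_subject=eeg_sds,
        _data=(datasets, s_v, truncated) if not prior_only else None,
    )
    rhats = gelman_rubin(post)
    post.max_rhat = max(rhats.values())
    post.converged = post.max_rhat < rhat_threshold
    post.rhats = rhats
    return post


# ---------------------------------------------------------------------------
# diagnostics and model comparison


def split_rhat(x: np.ndarray) -> float:
    """Split Gelman-Rubin R-hat for one parameter, chains as rows (C, N)."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need >= 2 chains")
    n = x.shape[1] // 2
    if n < 5:
        raise ValueError("need >= 10 samples per chain")
    halves = np.concatenate([x[:, :n], x[:, n : 2 * n]], axis=0)
    W = halves.var(axis=1, ddof=1).mean()
    if W <= 0:
        return 1.0
    B = n * halves.mean(axis=1).var(ddof=1)
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W))


def gelman_rubin(posterior: LBAPosterior) -> dict:
    """Split R-hat per monitored group-level parameter (means and SDs)."""
    out = {}
    for i, name in enumerate(posterior.param_names):
        out[f"mu:{name}"] = split_rhat(posterior.group_mean[:, :, i])
        out[f"sd:{name}"] = split_rhat(posterior.group_sd[:, :, i])
    return out


def bpic(loglik_samples: np.ndarray, loglik_at_posterior_mean: float) -> float:
    """Bayesian Predictive Information Criterion: D-bar + 2 p_D.

    D-bar is the posterior mean deviance (-2 log L); p_D = D-bar - D(theta-bar)
    with the deviance evaluated at the posterior mean parameters. Lower is
    better.
    """
    ll = np.asarray(loglik_samples, dtype=float)
    if ll.size == 0 or not np.all(np.isfinite(ll)):
        raise ValueError("per-sample log-likelihoods missing or non-finite")
    d_bar = float(-2.0 * ll.mean())
    d_hat = -2.0 * float(loglik_at_posterior_mean)
    p_d = d_bar - d_hat
    return d_bar + 2.0 * p_d


def bf_from_bic(bic_null: float, bic_alt: float):
    """BIC-difference Bayes factor: BF = exp((BIC0 - BIC1)/2), with the
    posterior probability BF / (1 + BF) of the alternative."""
    if not (np.isfinite(bic_null) and np.isfinite(bic_alt)):
        raise ValueError("BIC values must be finite")
    bf = float(np.exp((bic_null - bic_alt) / 2.0))
    return bf, bf / (1.0 + bf)


@dataclass(frozen=True)
class ContrastReport:
    """Posterior drift-rate contrast Delta between two condition cells."""

    delta_mean: float
    ci_low: float
    ci_high: float
    p_positive: float
    p_negative: float
    samples: np.ndarray = field(repr=False)


def contrast_delta(
    posterior: LBAPosterior, cellA: dict, cellB: dict, ci: float = 0.95
) -> ContrastReport:
    """Group-level drift difference Delta = v(cellA) - v(cellB).

    Per posterior sample the group-mean drift coefficients are projected
    onto the two cells' design rows. Reports the posterior mean, the
    equal-tailed credible interval and the one-tailed posterior masses
    P(Delta > 0) / P(Delta < 0) (strict inequalities, so a self-contrast
    reports both as 0).
    """
    if posterior.design is None:
        raise ValueError("posterior carries no design; refit or attach one")
    xa = posterior.design.cell_vector(cellA)
    xb = posterior.design.cell_vector(cellB)
    beta = posterior.beta_group_samples().reshape(-1, posterior.design.n_coef)
    delta = beta @ (xa - xb)
    lo, hi = np.quantile(delta, [(1 - ci) / 2, 1 - (1 - ci) / 2])
    return ContrastReport(
        delta_mean=float(delta.mean()),
        ci_low=float(lo),
        ci_high=float(hi),
        p_positive=float((delta > 0).mean()),
        p_negative=float((delta < 0).mean()),
        samples=delta,
    )


def contraction(posterior: LBAPosterior) -> dict:
    """Prior-to-posterior contraction per group-mean parameter.

    1 - var(posterior)/var(prior); ~0 means the data did not inform the
    parameter (e.g. in a prior-only fit), ~1 means strong updating.
    """
    if posterior.priors is None:
        raise ValueError("posterior carries no prior specification")
    out = {}
    for i, name in enumerate(posterior.param_names):
        post_var = posterior.group_mean[:, :, i].ravel().var(ddof=1)
        out[f"mu:{name}"] = 1.0 - post_var / posterior.priors.s0[i] ** 2
    return out
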