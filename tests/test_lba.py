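import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import integrate

from loombias.lba import (
    LBAParams,
    LBAPosterior,
    LBAPriors,
    bf_from_bic,
    bpic,
    build_design,
    contrast_delta,
    contraction,
    defective_density,
    defective_loglik,
    fit_hierarchical,
    gelman_rubin,
    lba_node_pdf_cdf,
    loglik,
    simulate_lba,
    split_rhat,
)


def factorial_trials(n_per_cell=2, seed=0, subjects=("s1",)):
    """Fully crossed condition table with filled-in rt/choice/eeg columns."""
    rng = np.random.default_rng(seed)
    rows = []
    for subject in subjects:
        for d, c, ver, hor in itertools.product(
            ("flattened", "shaped"), ("native", "novel"), ("up", "down"), ("front", "back")
        ):
            for _ in range(n_per_cell):
                rows.append(
                    {
                        "subject": subject,
                        "direction": d,
                        "cue": c,
                        "vertical": ver,
                        "horizontal": hor,
                        "eeg": rng.normal(0, 5),
                        "rt": rng.uniform(0.4, 1.5),
                        "choice": rng.choice(["looming", "receding"]),
                    }
                )
    return pd.DataFrame(rows)


class TestNodeDistribution:
    GRID = [(0.0, 0.5, 1.0), (0.5, 1.0, 2.0), (1.0, 2.0, 3.0)]

    @pytest.mark.parametrize("A,b_minus_A,v", GRID)
    def test_pdf_integrates_to_one(self, A, b_minus_A, v):
        b = A + b_minus_A
        total, err = integrate.quad(
            lambda t: lba_node_pdf_cdf(t, A, b, v, 1.0)[0], 0, np.inf, limit=200
        )
        assert total == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("A,b_minus_A,v", GRID)
    def test_pdf_is_derivative_of_cdf(self, A, b_minus_A, v):
        b = A + b_minus_A
        t = np.linspace(0.05, 6.0, 200)
        h = 1e-6
        _, Fp = lba_node_pdf_cdf(t + h, A, b, v, 1.0)
        _, Fm = lba_node_pdf_cdf(t - h, A, b, v, 1.0)
        f, _ = lba_node_pdf_cdf(t, A, b, v, 1.0)
        np.testing.assert_allclose(f, (Fp - Fm) / (2 * h), atol=1e-4, rtol=1e-4)

    def test_truncated_cdf_tends_to_one(self):
        # the first-passage tail decays like 1/t (drifts near zero), so the
        # CDF approaches 1 with O(1/t) error
        t = np.array([1e2, 1e3, 1e4, 1e5])
        _, F = lba_node_pdf_cdf(t, 0.5, 1.5, 0.5, 1.0, truncated=True)
        assert np.all(np.diff(F) > 0)
        np.testing.assert_allclose(1.0 - F, (1.0 - F[0]) * t[0] / t, rtol=1e-2)
        assert F[-1] > 1.0 - 1e-4

    def test_untruncated_cdf_limited_by_positive_drift_mass(self):
        from scipy.special import ndtr

        _, F = lba_node_pdf_cdf(1e6, 0.5, 1.5, 0.5, 1.0, truncated=False)
        assert F == pytest.approx(ndtr(0.5), abs=1e-6)

    def test_nonpositive_times_give_zero(self):
        f, F = lba_node_pdf_cdf(np.array([-1.0, 0.0, 0.5]), 0.5, 1.5, 2.0, 1.0)
        assert f[0] == f[1] == 0.0 and F[0] == F[1] == 0.0
        assert f[2] > 0

    def test_zero_A_limit_matches_small_A(self):
        t = np.linspace(0.1, 4.0, 50)
        f0, F0 = lba_node_pdf_cdf(t, 0.0, 1.0, 1.5, 1.0)
        fe, Fe = lba_node_pdf_cdf(t, 1e-6, 1.0, 1.5, 1.0)
        np.testing.assert_allclose(f0, fe, rtol=1e-3, atol=1e-6)
        np.testing.assert_allclose(F0, Fe, rtol=1e-3, atol=1e-6)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            lba_node_pdf_cdf(1.0, -0.1, 1.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            lba_node_pdf_cdf(1.0, 0.5, 0.0, 1.0, 1.0)

    def test_simulation_matches_cdf(self):
        params = LBAParams(A=0.5, B=1.0, t0=0.0, v=[1.5])
        _, rt = simulate_lba(params, n=40000, seed=0)
        grid = np.linspace(0.1, 5.0, 60)
        _, F = lba_node_pdf_cdf(grid, 0.5, 1.5, 1.5, 1.0)
        emp = np.searchsorted(np.sort(rt), grid) / rt.size
        assert np.max(np.abs(emp - F)) < 0.01


class TestDefectiveDensity:
    def test_symmetric_race_splits_evenly(self):
        params = LBAParams(A=0.4, B=0.9, t0=0.2, v=[1.2, 1.2])
        probs = [
            integrate.quad(
                lambda t: float(defective_density(c, t, params)), params.t0, np.inf, limit=200
            )[0]
            for c in (0, 1)
        ]
        assert probs[0] == pytest.approx(probs[1], abs=1e-8)
        assert sum(probs) == pytest.approx(1.0, abs=1e-6)

    def test_normalizes_and_matches_simulation(self):
        params = LBAParams(A=0.5, B=1.0, t0=0.25, v=[2.0, 1.0])
        probs = [
            integrate.quad(
                lambda t: float(defective_density(c, t, params)), params.t0, np.inf, limit=200
            )[0]
            for c in (0, 1)
        ]
        assert sum(probs) == pytest.approx(1.0, abs=1e-6)
        winner, _ = simulate_lba(params, n=40000, seed=1)
        assert probs[0] == pytest.approx((winner == 0).mean(), abs=0.01)

    def test_zero_below_t0(self):
        params = LBAParams(A=0.5, B=1.0, t0=0.25, v=[2.0, 1.0])
        assert defective_density(0, np.array([0.1, 0.25]), params).max() == 0.0

    def test_loglik_matches_density_and_scales_with_duplication(self):
        params = LBAParams(A=0.5, B=1.0, t0=0.25, v=[2.0, 1.0])
        rng = np.random.default_rng(2)
        choice, rt = simulate_lba(params, n=10, seed=3)
        v = np.broadcast_to(params.v, (10, 2))
        ll = defective_loglik(rt, choice, v, params.A, params.b, params.t0)
        manual = sum(
            np.log(float(defective_density(c, r, params))) for c, r in zip(choice, rt)
        )
        assert ll == pytest.approx(manual, rel=1e-10)
        ll3 = defective_loglik(
            np.tile(rt, 3), np.tile(choice, 3), np.tile(v, (3, 1)), params.A, params.b, params.t0
        )
        assert ll3 == pytest.approx(3 * ll, rel=1e-10)

    def test_rt_at_or_below_t0_gives_minus_inf(self):
        v = np.ones((2, 2))
        assert defective_loglik([0.2, 0.8], [0, 1], v, 0.5, 1.5, 0.25) == -np.inf


class TestSimulate:
    def test_deterministic_under_seed(self):
        params = LBAParams(A=0.5, B=1.0, t0=0.2, v=[2.0, 1.0])
        w1, r1 = simulate_lba(params, n=100, seed=7)
        w2, r2 = simulate_lba(params, n=100, seed=7)
        np.testing.assert_array_equal(w1, w2)
        np.testing.assert_array_equal(r1, r2)

    def test_degenerate_limit_is_deterministic_passage(self):
        params = LBAParams(A=0.0, B=1.0, t0=0.3, v=[2.0], s_v=1e-9)
        _, rt = simulate_lba(params, n=50, seed=8)
        np.testing.assert_allclose(rt, 0.3 + 1.0 / 2.0, atol=1e-6)

    def test_higher_drift_wins_more_and_is_faster(self):
        fast = LBAParams(A=0.5, B=1.0, t0=0.2, v=[3.0, 1.0])
        winner, rt = simulate_lba(fast, n=5000, seed=9)
        assert (winner == 0).mean() > 0.8
        slow = LBAParams(A=0.5, B=1.0, t0=0.2, v=[1.0, 1.0])
        _, rt_slow = simulate_lba(slow, n=5000, seed=9)
        assert rt.mean() < rt_slow.mean()

    def test_trialwise_drifts(self):
        params = LBAParams(A=0.2, B=1.0, t0=0.2, v=[1.0, 1.0], s_v=1e-9)
        v = np.array([[5.0, 0.5], [0.5, 5.0]] * 50)
        winner, _ = simulate_lba(params, v=v, seed=10)
        np.testing.assert_array_equal(winner, np.array([0, 1] * 50))


class TestDesign:
    def test_full_formula_has_twelve_columns(self):
        trials = factorial_trials()
        design = build_design(trials, "match*direction*cue + vertical*horizontal + eeg")
        assert design.n_coef == 12
        assert design.X.shape == (len(trials), 2, 12)
        assert design.has_eeg

    def test_match_codes_congruency(self):
        trials = factorial_trials(n_per_cell=1)
        design = build_design(trials, "match")
        assert design.n_coef == 2
        flattened = trials["direction"] == "flattened"
        # column 1 is the nonmatch indicator; looming accumulator matches flattened
        nonmatch_looming = design.X[:, 0, 1]
        np.testing.assert_array_equal(nonmatch_looming, (~flattened).astype(float))
        nonmatch_receding = design.X[:, 1, 1]
        np.testing.assert_array_equal(nonmatch_receding, flattened.astype(float))

    def test_drift_means_shape_and_values(self):
        trials = factorial_trials(n_per_cell=1)
        design = build_design(trials, "match")
        v = design.drift_means(np.array([2.0, -0.5]))
        assert v.shape == (len(trials), 2)
        assert set(np.round(v.ravel(), 9)) == {2.0, 1.5}

    def test_rank_deficiency_detected(self):
        trials = factorial_trials()
        trials["cue"] = trials["direction"].map(
            {"flattened": "native", "shaped": "novel"}
        )  # perfectly confounded factors
        with pytest.raises(ValueError, match="rank-deficient"):
            build_design(trials, "direction + cue")

    def test_cell_vector_round_trip(self):
        trials = factorial_trials()
        design = build_design(trials, "match + eeg")
        x = design.cell_vector({"match": "nonmatch"})
        np.testing.assert_allclose(x, [1.0, 1.0, 0.0])  # eeg defaults to 0
        with pytest.raises(KeyError):
            design.cell_vector({"match": "no-such-level"})

    def test_formula_lhs_stripped(self):
        trials = factorial_trials()
        d1 = build_design(trials, "v ~ match")
        d2 = build_design(trials, "match")
        np.testing.assert_array_equal(d1.X, d2.X)

    def test_loglik_nested_null_equality(self):
        # with the eeg coefficient at 0 the eeg model reduces to the null model
        trials = factorial_trials(n_per_cell=4)
        d_eeg = build_design(trials, "match + eeg")
        d_null = build_design(trials, "match")
        p_eeg = {"A": 0.5, "B": 1.0, "t0": 0.2, "beta": np.array([2.0, -0.5, 0.0])}
        p_null = {"A": 0.5, "B": 1.0, "t0": 0.2, "beta": np.array([2.0, -0.5])}
        assert loglik(trials, d_eeg, p_eeg) == pytest.approx(
            loglik(trials, d_null, p_null), rel=1e-12
        )


class TestDiagnostics:
    def test_split_rhat_constant_chains(self):
        assert split_rhat(np.full((3, 40), 1.7)) == 1.0

    def test_split_rhat_iid_near_one(self):
        rng = np.random.default_rng(11)
        x = rng.normal(0, 1, (4, 1000))
        assert split_rhat(x) < 1.05

    def test_split_rhat_disjoint_chains_large(self):
        rng = np.random.default_rng(12)
        x = rng.normal(0, 0.1, (2, 200))
        x[1] += 10.0
        assert split_rhat(x) > 2.0

    def test_split_rhat_input_validation(self):
        with pytest.raises(ValueError):
            split_rhat(np.zeros(10))
        with pytest.raises(ValueError):
            split_rhat(np.zeros((1, 100)))
        with pytest.raises(ValueError):
            split_rhat(np.zeros((2, 4)))

    def test_bpic_degenerate_point_mass(self):
        ll = np.full(100, -50.0)
        # pD = 0 when the posterior is a point mass at the mean
        assert bpic(ll, -50.0) == pytest.approx(100.0)

    def test_bpic_closed_form_and_order_invariance(self):
        rng = np.random.default_rng(13)
        ll = -50.0 + rng.normal(0, 2, 500)
        at_mean = -48.0
        b1 = bpic(ll, at_mean)
        b2 = bpic(ll[::-1], at_mean)
        assert b1 == pytest.approx(b2)
        # D-bar + 2 pD = 3 D-bar - 2 D(theta-bar)
        d_bar = -2.0 * ll.mean()
        assert b1 == pytest.approx(3 * d_bar - 2 * (-2.0 * at_mean))
        with pytest.raises(ValueError):
            bpic(np.array([]), -50.0)
        with pytest.raises(ValueError):
            bpic(np.array([np.nan]), -50.0)

    def test_bf_from_bic_closed_forms(self):
        bf, p = bf_from_bic(100.0, 100.0)
        assert bf == pytest.approx(1.0) and p == pytest.approx(0.5)
        bf, p = bf_from_bic(102.0, 100.0)
        assert bf == pytest.approx(np.e)
        assert p == pytest.approx(np.e / (1 + np.e))
        bf_ab, _ = bf_from_bic(95.0, 100.0)
        bf_ba, _ = bf_from_bic(100.0, 95.0)
        assert bf_ab * bf_ba == pytest.approx(1.0)
        with pytest.raises(ValueError):
            bf_from_bic(np.inf, 0.0)


def manual_posterior(beta_samples, design):
    """LBAPosterior with prescribed group-level beta draws (1 chain)."""
    beta_samples = np.asarray(beta_samples, float)
    n, p = beta_samples.shape
    group_mean = np.zeros((1, n, 3 + p))
    group_mean[0, :, 3:] = beta_samples
    names = ["log_A", "log_B", "log_t0"] + [f"beta:{c}" for c in design.column_names]
    return LBAPosterior(
        subject=np.zeros((1, n, 1, 3 + p)),
        group_mean=group_mean,
        group_sd=np.ones((1, n, 3 + p)),
        loglik=np.zeros((1, n)),
        param_names=names,
        design=design,
        priors=LBAPriors.default(p),
    )


class TestContrast:
    @pytest.fixture
    def design(self):
        return build_design(factorial_trials(), "match")

    def test_self_contrast_is_null(self, design):
        post = manual_posterior(np.random.default_rng(14).normal(0, 1, (200, 2)), design)
        rep = contrast_delta(post, {"match": "match"}, {"match": "match"})
        assert rep.delta_mean == 0.0
        assert rep.p_positive == 0.0 and rep.p_negative == 0.0

    def test_known_samples_give_known_summary(self, design):
        # Delta = v(match) - v(nonmatch) = -beta[nonmatch]; feed samples {1,2,3}
        beta = np.column_stack([np.zeros(3), -np.array([1.0, 2.0, 3.0])])
        post = manual_posterior(beta, design)
        rep = contrast_delta(post, {"match": "match"}, {"match": "nonmatch"}, ci=0.5)
        assert rep.delta_mean == pytest.approx(2.0)
        assert rep.p_positive == 1.0 and rep.p_negative == 0.0
        np.testing.assert_allclose(np.sort(rep.samples), [1.0, 2.0, 3.0])
        assert rep.ci_low == pytest.approx(np.quantile([1, 2, 3], 0.25))
        assert rep.ci_high == pytest.approx(np.quantile([1, 2, 3], 0.75))

    def test_missing_design_rejected(self, design):
        post = manual_posterior(np.zeros((10, 2)), design)
        post.design = None
        with pytest.raises(ValueError):
            contrast_delta(post, {"match": "match"}, {"match": "nonmatch"})


def small_dataset(seed=0, n_subjects=3, n_trials=150):
    """Simulated two-condition dataset with a known match effect."""
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subjects):
        direction = rng.permutation(["flattened", "shaped"] * (n_trials // 2))
        v = np.empty((n_trials, 2))
        flattened = direction == "flattened"
        v[:, 0] = np.where(flattened, 2.5, 1.8)
        v[:, 1] = np.where(flattened, 1.8, 2.5)
        params = LBAParams(A=0.5, B=1.0, t0=0.25, v=[1.0, 1.0])
        choice, rt = simulate_lba(params, v=v, seed=rng)
        rows.append(
            pd.DataFrame(
                {
                    "subject": f"s{s}",
                    "direction": direction,
                    "rt": rt,
                    "choice": np.asarray(["looming", "receding"])[choice],
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


class TestFitHierarchical:
    def test_fit_is_deterministic_and_recovers_sign(self):
        trials = small_dataset()
        kwargs = dict(
            formula="match", n_chains=2, n_samples=60, n_burn=150, seed=42
        )
        post1 = fit_hierarchical(trials, **kwargs)
        post2 = fit_hierarchical(trials, **kwargs)
        np.testing.assert_array_equal(post1.group_mean, post2.group_mean)
        np.testing.assert_array_equal(post1.subject, post2.subject)
        # true nonmatch deficit: contrast match - nonmatch clearly positive
        rep = contrast_delta(post1, {"match": "match"}, {"match": "nonmatch"})
        assert rep.delta_mean > 0
        assert rep.p_positive > 0.9

    def test_prior_only_shows_no_contraction(self):
        trials = small_dataset()
        post = fit_hierarchical(
            trials,
            formula="match",
            n_chains=2,
            n_samples=500,
            n_burn=500,
            seed=1,
            prior_only=True,
        )
        con = contraction(post)
        for name, c in con.items():
            assert abs(c) < 0.2, name

    def test_save_load_round_trip(self, tmp_path):
        trials = small_dataset(n_subjects=2, n_trials=60)
        post = fit_hierarchical(
            trials, formula="match", n_chains=2, n_samples=30, n_burn=60, seed=2
        )
        post.save(tmp_path / "post")
        back = LBAPosterior.load(tmp_path / "post")
        np.testing.assert_array_equal(back.group_mean, post.group_mean)
        assert back.param_names == post.param_names
        # diagnostics still computable from the reloaded arrays
        assert set(gelman_rubin(back)) == set(gelman_rubin(post))

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            fit_hierarchical(small_dataset(), formula="match", n_chains=1)
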