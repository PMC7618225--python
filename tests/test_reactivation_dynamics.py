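import numpy as np
import pytest

from ripplelamina import reactivation_dynamics as rd
from ripplelamina.population_activity import population_vectors, zscore_rows


class TestRecentPriorTransform:
    def test_identity_when_unchanged(self):
        rng = np.random.default_rng(0)
        A = rng.normal(size=(6, 6))
        A = A @ A.T + 6 * np.eye(6)
        W, Wp, flagged = rd.recent_prior_transform(A, A)
        assert np.allclose(W, np.eye(6), atol=1e-8)
        assert np.allclose(Wp, np.eye(6), atol=1e-8)
        assert not flagged

    def test_scaling(self):
        rng = np.random.default_rng(1)
        A = rng.normal(size=(5, 5))
        A = A @ A.T + 5 * np.eye(5)
        W, _, _ = rd.recent_prior_transform(A, 2.0 * A)
        assert np.allclose(W, 2.0 * np.eye(5), atol=1e-8)

    def test_transform_inverts_exactly_when_well_conditioned(self):
        rng = np.random.default_rng(2)
        A_pre = rng.normal(size=(7, 7)) + 7 * np.eye(7)
        A_theta = rng.normal(size=(7, 7)) + 7 * np.eye(7)
        W, _, flagged = rd.recent_prior_transform(A_pre, A_theta)
        assert not flagged
        assert np.allclose(W @ A_pre, A_theta, atol=1e-8)

    def test_singular_matrix_regularised_and_flagged(self):
        A_pre = np.ones((4, 4))  # rank 1
        A_theta = np.eye(4)
        W, _, flagged = rd.recent_prior_transform(A_pre, A_theta)
        assert flagged
        assert np.all(np.isfinite(W))

    def test_wake_gained_motif_dominates_spectrum(self):
        rng = np.random.default_rng(3)
        n = 12
        base = rng.normal(size=(n, n)) * 0.05
        A_pre = base @ base.T + np.eye(n)
        motif = np.zeros(n)
        motif[3:7] = 0.5
        A_theta = A_pre + 4.0 * np.outer(motif, motif)
        W, _, _ = rd.recent_prior_transform(A_pre, A_theta)
        Ws = (W + W.T) / 2
        vals, vecs = np.linalg.eigh(Ws)
        top = vecs[:, np.argmax(vals)]
        cos = abs(top @ motif / np.linalg.norm(motif))
        assert cos > 0.8


class TestBalanceScore:
    def test_identity_matrix_gives_squared_norm(self):
        v = np.array([1.0, 2.0, -1.0])
        assert rd.balance_score(np.eye(3), v[:, None])[0] == pytest.approx(6.0)

    def test_quadratic_scaling(self):
        rng = np.random.default_rng(4)
        W = rng.normal(size=(5, 5))
        v = rng.normal(size=(5, 1))
        assert rd.balance_score(W, 2 * v)[0] == pytest.approx(
            4 * rd.balance_score(W, v)[0]
        )

    def test_wake_aligned_vectors_score_higher(self):
        rng = np.random.default_rng(5)
        n = 10
        A_pre = np.eye(n)
        wake = np.zeros(n)
        wake[:4] = 1.0
        A_theta = np.eye(n) + 2.0 * np.outer(wake, wake) / 4
        W, _, _ = rd.recent_prior_transform(A_pre, A_theta)
        v_wake = np.tile(wake[:, None], (1, 30)) + 0.1 * rng.normal(size=(n, 30))
        prior = np.zeros(n)
        prior[5:9] = 1.0
        v_prior = np.tile(prior[:, None], (1, 30)) + 0.1 * rng.normal(size=(n, 30))
        assert rd.balance_score(W, v_wake).mean() > rd.balance_score(W, v_prior).mean()

    def test_region_pair_mask(self):
        regions = np.array(["CA3", "CA3", "CA1", "CA1"])
        mask = rd.region_pair_mask(regions, "CA3", "CA1")
        assert mask[0, 2] == mask[2, 0] == 1.0
        assert mask[0, 1] == mask[2, 3] == 0.0

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rd.balance_score(np.eye(3), np.ones((4, 7)))


class TestDriftTimecourse:
    def test_bins_cover_10_to_70_in_six_windows(self):
        out = rd.drift_timecourse({"LM": [15.0]}, {"LM": [1.0]})
        centres = out["LM"].bin_centres_min
        assert centres.size == 6
        assert centres[0] == 15.0 and centres[-1] == 65.0

    def test_constant_input_all_zero_after_normalisation(self):
        rng = np.random.default_rng(6)
        t = rng.uniform(10, 70, 400)
        out = rd.drift_timecourse({"LM": t, "Rad": t}, {"LM": np.full(400, 3.3), "Rad": np.full(400, 3.3)})
        assert np.allclose(out["LM"].values, 0.0)
        assert np.allclose(out["Rad"].values, 0.0)
        assert out["LM"].offset == pytest.approx(3.3)

    def test_first_ten_minutes_excluded(self):
        out = rd.drift_timecourse({"LM": [5.0, 15.0]}, {"LM": [100.0, 1.0]})
        assert out["LM"].values[0] + out["LM"].offset == pytest.approx(1.0)

    def test_exponential_decay_monotone(self):
        t = np.linspace(10.5, 69.5, 600)
        v = np.exp(-t / 13.0)
        out = rd.drift_timecourse({"LM": t}, {"LM": v})
        assert np.all(np.diff(out["LM"].values) < 0)


class TestFitFlatVsExponential:
    def test_flat_noise_selects_flat_in_most_seeds(self):
        wins = 0
        t = np.tile(np.arange(15.0, 70.0, 10.0), 8)
        for seed in range(20):
            rng = np.random.default_rng(seed)
            y = rng.normal(0, 0.3, t.size)
            fit = rd.fit_flat_vs_exponential(t, y, n_boot=0)
            wins += fit.model == "flat"
        assert wins >= 19

    def test_planted_decay_recovered_with_ci(self):
        rng = np.random.default_rng(7)
        sessions = np.repeat(np.arange(10), 6)
        t = np.tile(np.arange(15.0, 70.0, 10.0), 10)
        y = 1.0 * np.exp(-t / 13.0) + 0.0 + rng.normal(0, 0.05, t.size)
        fit = rd.fit_flat_vs_exponential(t, y, session_ids=sessions, n_boot=200, seed=0)
        assert fit.model == "exponential"
        assert fit.bic_exp < fit.bic_flat
        lo, hi = fit.tau_ci
        assert lo <= 13.0 <= hi

    def test_tau_invariant_to_additive_offset(self):
        rng = np.random.default_rng(8)
        t = np.tile(np.arange(15.0, 70.0, 10.0), 10)
        y = np.exp(-t / 13.0) + rng.normal(0, 0.02, t.size)
        f1 = rd.fit_flat_vs_exponential(t, y, n_boot=0)
        f2 = rd.fit_flat_vs_exponential(t, y + 5.0, n_boot=0)
        assert f1.params["tau_min"] == pytest.approx(f2.params["tau_min"], rel=0.05)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            rd.fit_flat_vs_exponential([1, 2, 3], [1, 2, 3])


class TestStability:
    def test_equal_accuracies_give_one(self):
        assert rd.stability_score(0.6, 0.6) == 1.0

    def test_worked_example(self):
        assert rd.stability_score(0.8, 0.3) == pytest.approx(0.5)

    def test_monotone_in_post_accuracy(self):
        post = np.linspace(0.0, 0.8, 9)
        s = rd.stability_score(0.8, post)
        assert np.all(np.diff(s) > 0)


def _motif_session(
    n_units=20, n_theta=400, n_pre=300, n_post=300, re_express="post", seed=0
):
    """Theta-cycle motif re-expressed in pre and/or post ripples."""
    rng = np.random.default_rng(seed)
    motif = list(range(5))

    def counts(n_ev, with_motif):
        X = rng.poisson(1.0, (n_units, n_ev))
        if with_motif:
            active = rng.random(n_ev) < 0.45
            X[np.ix_(motif, np.flatnonzero(active))] += rng.poisson(
                2.5, (len(motif), active.sum())
            )
        return X

    theta = counts(n_theta, True)
    pre = counts(n_pre, re_express in ("pre", "both"))
    post = counts(n_post, re_express in ("post", "both"))
    tetrodes = np.arange(n_units) % 5
    return theta, pre, post, tetrodes


class TestGlmReactivation:
    def test_post_only_re_expression_significant(self):
        theta, pre, post, tet = _motif_session(re_express="post", seed=9)
        out = rd.glm_reactivation(theta, pre, post, tet, n_draws=20, seed=0)
        assert out["test"].p < 0.05
        ok = np.isfinite(out["acc_pre"])
        assert np.all((out["acc_pre"][ok] >= -1) & (out["acc_pre"][ok] <= 1))

    def test_pre_only_not_significant(self):
        theta, pre, post, tet = _motif_session(re_express="pre", seed=10)
        out = rd.glm_reactivation(theta, pre, post, tet, n_draws=20, seed=1)
        assert out["test"].p > 0.05

    def test_independent_ripples_null(self):
        theta, pre, post, tet = _motif_session(re_express="none", seed=11)
        out = rd.glm_reactivation(theta, pre, post, tet, n_draws=20, seed=2)
        ok = np.isfinite(out["acc_pre"]) & np.isfinite(out["acc_post"])
        assert abs(np.mean(out["acc_post"][ok] - out["acc_pre"][ok])) < 0.05

    def test_sublayer_filter_skips_small_groups(self):
        theta, pre, post, tet = _motif_session(seed=12)
        sub = np.array(["deep"] * 17 + ["superficial"] * 3)
        out = rd.glm_reactivation(
            theta, pre, post, tet, sublayers=sub, sublayer_filter=True,
            n_draws=10, seed=3,
        )
        assert np.isnan(out["acc_pre"][17:]).all()  # too few superficial peers


class TestPresleepReactivationDecay:
    def test_decaying_expression_yields_declining_series(self):
        rng = np.random.default_rng(13)
        n_units, motif = 20, list(range(6))
        pre = rng.poisson(1.0, (n_units, 400))
        active = rng.random(400) < 0.5
        pre[np.ix_(motif, np.flatnonzero(active))] += rng.poisson(2.5, (6, active.sum()))
        t_post = np.sort(rng.uniform(10.0, 70.0, 600))
        post = rng.poisson(1.0, (n_units, 600))
        p_expr = np.exp(-t_post / 13.0)
        expr = rng.random(600) < p_expr
        post[np.ix_(motif, np.flatnonzero(expr))] += rng.poisson(2.5, (6, expr.sum()))
        centres, strength, per_unit = rd.presleep_reactivation_decay(
            pre, post, t_post, n_shuffles=20, seed=0
        )
        assert strength[0] > strength[-1]
        fit = rd.fit_flat_vs_exponential(centres, strength, n_boot=0)
        assert fit.model == "exponential"

    def test_chance_normalisation_zero_for_shuffled_ids(self):
        rng = np.random.default_rng(14)
        pre = rng.poisson(1.5, (12, 300))
        t_post = np.sort(rng.uniform(10.0, 70.0, 300))
        post = rng.poisson(1.5, (12, 300))
        _, strength, _ = rd.presleep_reactivation_decay(
            pre, post, t_post, n_shuffles=20, seed=1
        )
        assert np.nanmean(np.abs(strength)) < 0.05


class TestWakeReactivationPartial:
    def test_wake_motif_in_post_gives_positive_beta(self):
        theta, pre, post, _ = _motif_session(re_express="post", n_post=900, seed=15)
        rng = np.random.default_rng(0)
        t_post = np.sort(rng.uniform(10.0, 70.0, 900))
        centres, betas = rd.wake_reactivation_partial(pre, theta, post, t_post)
        assert np.nanmean(betas) > 0.1

    def test_pre_replay_partialled_out(self):
        """Post events replay only pre-sleep structure: wake beta ~ 0."""
        rng = np.random.default_rng(16)
        n_units, motif_pre, motif_wake = 20, list(range(5)), list(range(8, 13))

        def counts(n_ev, members):
            X = rng.poisson(1.0, (n_units, n_ev))
            active = rng.random(n_ev) < 0.45
            X[np.ix_(members, np.flatnonzero(active))] += rng.poisson(
                2.5, (len(members), active.sum())
            )
            return X

        pre = counts(400, motif_pre)
        theta = counts(400, motif_pre + motif_wake)  # wake has both
        post = counts(900, motif_pre)  # post replays pre only
        t_post = np.sort(rng.uniform(10.0, 70.0, 900))
        _, betas = rd.wake_reactivation_partial(pre, theta, post, t_post)
        assert abs(np.nanmean(betas)) < 0.12

    def test_constant_re_expression_stable_series(self):
        theta, pre, post, _ = _motif_session(re_express="post", n_post=1200, seed=17)
        rng = np.random.default_rng(1)
        t_post = np.sort(rng.uniform(10.0, 70.0, 1200))
        centres, betas = rd.wake_reactivation_partial(pre, theta, post, t_post)
        fit = rd.fit_flat_vs_exponential(centres, betas, n_boot=0)
        assert fit.model == "flat"


class TestFeatureAttribution:
    def make_series(self, drift=True, seed=0):
        rng = np.random.default_rng(seed)
        n = 60
        t = np.tile(np.arange(15.0, 70.0, 10.0), 10)
        balance = (np.exp(-t / 13.0) if drift else np.zeros(t.size)) + rng.normal(
            0, 0.05, t.size
        )
        occ = rng.normal(30.0, 2.0, t.size)  # constant occurrence frequency
        spars = rng.normal(0.3, 0.02, t.size)  # constant sparsity
        return balance, t, occ, spars

    def test_drift_attributed_to_log_time_only(self):
        balance, t, occ, spars = self.make_series(drift=True, seed=18)
        out = rd.feature_attribution(balance, t, occ, spars, n_shuffles=300, seed=0)
        assert out["features"]["log_time"]["p"] < 0.05
        assert out["features"]["occurrence_freq"]["p"] > 0.05
        assert out["features"]["sparsity"]["p"] > 0.05
        assert out["features"]["log_time"]["gain"] > 0.2

    def test_irrelevant_feature_gains_near_zero(self):
        balance, t, occ, spars = self.make_series(drift=True, seed=19)
        out = rd.feature_attribution(balance, t, occ, spars, n_shuffles=200, seed=1)
        assert abs(out["features"]["occurrence_freq"]["gain"]) < 0.1
        assert abs(out["features"]["sparsity"]["gain"]) < 0.1

    def test_shuffled_balance_no_accuracy(self):
        balance, t, occ, spars = self.make_series(drift=False, seed=20)
        out = rd.feature_attribution(balance, t, occ, spars, n_shuffles=100, seed=2)
        assert out["accuracy"] < 0.35


class TestSublayerDecay:
    def make_per_unit(self, deep_decays=True, seed=0):
        rng = np.random.default_rng(seed)
        centres = np.arange(15.0, 70.0, 10.0)
        n_deep, n_sup = 10, 10
        S = np.empty((n_deep + n_sup, centres.size))
        for u in range(n_deep + n_sup):
            if u < n_deep and deep_decays:
                S[u] = 0.5 * np.exp(-centres / 13.0) + rng.normal(0, 0.02, centres.size)
            else:
                S[u] = 0.2 + rng.normal(0, 0.02, centres.size)
        labels = np.array(["deep"] * n_deep + ["superficial"] * n_sup)
        return S, centres, labels

    def test_decay_in_deep_only(self):
        S, centres, labels = self.make_per_unit(deep_decays=True, seed=21)
        out = rd.sublayer_decay_compare(S, centres, labels, n_boot=300, seed=0)
        assert out["deep"]["z"] < out["superficial"]["z"]
        assert out["deep"]["z"] < -2

    def test_no_decay_both_within_band(self):
        S, centres, labels = self.make_per_unit(deep_decays=False, seed=22)
        out = rd.sublayer_decay_compare(S, centres, labels, n_boot=300, seed=1)
        assert abs(out["deep"]["z"]) < 2.5
        assert abs(out["superficial"]["z"]) < 2.5

    def test_small_sublayer_excluded(self):
        S, centres, labels = self.make_per_unit(seed=23)
        labels = labels.copy()
        labels[:18] = "deep"
        labels[18:] = "superficial"
        out = rd.sublayer_decay_compare(S, centres, labels, n_boot=50, min_units=5, seed=2)
        assert np.isnan(out["superficial"]["z"])

    def test_circular_shift_preserves_autocorrelation(self):
        rng = np.random.default_rng(24)
        y = rng.normal(size=64)
        spec = np.abs(np.fft.rfft(y)) ** 2
        spec_shift = np.abs(np.fft.rfft(np.roll(y, 17))) ** 2
        assert np.allclose(spec, spec_shift, atol=1e-8)
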