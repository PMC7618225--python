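import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from ripplelamina import coactivity_graphs as cg


class TestPopulationConditioned:
    def test_matches_two_regressor_ols_oracle(self):
        """Closed-form OLS on [x_i, P] reproduces the edge weight."""
        rng = np.random.default_rng(0)
        n = 5000
        shared = rng.normal(size=n)
        x0 = shared + 0.3 * rng.normal(size=n)
        x1 = shared + 0.3 * rng.normal(size=n)
        X = np.vstack([x0, x1, rng.normal(size=(4, n))])
        g = cg.population_conditioned_coactivity(X, zscore=False)
        # oracle: directed beta for (0 -> 1) and (1 -> 0), then symmetrised
        total = X.sum(axis=0)
        betas = []
        for i, j in ((0, 1), (1, 0)):
            D = np.column_stack([X[i], total - X[i] - X[j], np.ones(n)])
            betas.append(np.linalg.lstsq(D, X[j], rcond=None)[0][0])
        assert g.weights[0, 1] == pytest.approx(np.mean(betas), abs=1e-9)
        assert g.weights[0, 1] > 0.5

    def test_independent_units_near_zero(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(6, 10_000))
        g = cg.population_conditioned_coactivity(X, zscore=False)
        off = g.weights[~np.eye(6, dtype=bool)]
        assert np.abs(off).max() < 0.05

    def test_symmetric_with_zero_diagonal(self, spike_pvs):
        g = cg.population_conditioned_coactivity(spike_pvs[("post-sleep", "Rad")])
        assert np.array_equal(g.weights, g.weights.T)
        assert np.all(np.diag(g.weights) == 0)

    def test_constant_unit_flagged_nan(self):
        rng = np.random.default_rng(2)
        X = rng.poisson(1.0, (5, 200)).astype(float)
        X[3] = 2.0
        g = cg.population_conditioned_coactivity(X)
        assert np.isnan(g.weights[3, 0]) and np.isnan(g.weights[0, 3])

    def test_planted_coactivity_difference_recovered_in_strength(self):
        """Stronger planted pairwise coactivity yields larger node strength."""
        rng = np.random.default_rng(14)
        n_units, n_ev = 20, 1500

        def correlated(rho):
            shared = rng.normal(size=n_ev)
            return np.sqrt(rho) * shared + np.sqrt(1 - rho) * rng.normal(
                size=(n_units, n_ev)
            )

        g_hi = cg.population_conditioned_coactivity(correlated(0.3), zscore=False)
        g_lo = cg.population_conditioned_coactivity(correlated(0.05), zscore=False)
        s_hi = cg.node_strength(g_hi)
        s_lo = cg.node_strength(g_lo)
        assert np.mean(s_hi - s_lo) > 0
        assert np.mean(s_hi > s_lo) > 0.9  # paired over units


class TestFullyConditioned:
    def test_large_penalty_shrinks_to_zero(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(5, 300))
        g = cg.fully_conditioned_coactivity(X, penalty=1e9)
        assert np.abs(g.weights).max() < 1e-4

    def test_small_penalty_matches_ols(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(5, 500))
        g = cg.fully_conditioned_coactivity(X, penalty=1e-8, zscore=False)
        i = 2
        others = [j for j in range(5) if j != i]
        beta = np.linalg.lstsq(X[others].T, X[i], rcond=None)[0]
        assert np.allclose(g.weights[i, others], beta, atol=1e-5)

    def test_planted_motif_ranks_within_above_between(self):
        rng = np.random.default_rng(5)
        n = 2000
        drive = rng.normal(size=n)
        X = rng.normal(size=(9, n))
        X[:3] += 1.2 * drive
        g = cg.fully_conditioned_coactivity(X, penalty=1.0)
        within = [g.weights[i, j] for i in range(3) for j in range(3) if i != j]
        between = [g.weights[i, j] for i in range(3) for j in range(5, 9)]
        from scipy.stats import mannwhitneyu

        assert mannwhitneyu(within, between, alternative="greater").pvalue < 0.01

    def test_not_symmetric_in_general(self):
        rng = np.random.default_rng(6)
        X = rng.poisson(1.5, (6, 400))
        g = cg.fully_conditioned_coactivity(X)
        assert not np.array_equal(g.weights, g.weights.T)


class TestNodeStrength:
    def test_uniform_weights(self):
        W = np.full((5, 5), 0.4)
        np.fill_diagonal(W, 0)
        assert np.allclose(cg.node_strength(W), 0.4)

    def test_sign_balanced_star_centre_zero(self):
        W = np.zeros((5, 5))
        W[0, 1] = W[1, 0] = 1.0
        W[0, 2] = W[2, 0] = -1.0
        W[0, 3] = W[3, 0] = 0.5
        W[0, 4] = W[4, 0] = -0.5
        assert cg.node_strength(W)[0] == pytest.approx(0.0)


class TestStructuralBalance:
    def test_all_positive_k4(self):
        W = np.ones((4, 4)) - np.eye(4)
        assert cg.structural_balance(W) == 1.0

    def test_single_negative_edge_triangle(self):
        W = np.ones((3, 3)) - np.eye(3)
        W[0, 1] = W[1, 0] = -1.0
        assert cg.structural_balance(W) == 0.0

    def test_two_negative_edges_balanced(self):
        W = -np.ones((3, 3)) + np.eye(3)
        W[0, 1] = W[1, 0] = 1.0
        assert cg.structural_balance(W) == 1.0

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(hst.integers(3, 8), hst.integers(0, 10_000))
    def test_matches_exhaustive_triad_census(self, n, seed):
        rng = np.random.default_rng(seed)
        W = rng.choice([-1.0, 0.0, 1.0], size=(n, n), p=[0.3, 0.2, 0.5])
        W = np.triu(W, 1)
        W = W + W.T
        a = cg.structural_balance(W)
        b = cg.structural_balance_census(W)
        assert (np.isnan(a) and np.isnan(b)) or a == pytest.approx(b)

    def test_no_triads_undefined(self):
        assert np.isnan(cg.structural_balance(np.zeros((5, 5))))


class TestGini:
    def test_perfect_equality(self):
        assert cg.gini_sparsity([1, 1, 1, 1]) == 0.0

    def test_single_active_unit(self):
        assert cg.gini_sparsity([0, 0, 0, 8]) == pytest.approx(0.75)

    def test_scale_invariance(self):
        x = np.random.default_rng(7).poisson(2.0, 30) + 1
        assert cg.gini_sparsity(x) == pytest.approx(cg.gini_sparsity(7.3 * x))

    def test_matches_mean_absolute_difference_oracle(self):
        """Sorted-rank form equals the classic MAD Gini on 1,000 random vectors."""
        rng = np.random.default_rng(8)
        for _ in range(1000):
            x = rng.gamma(1.0, 2.0, rng.integers(2, 25))
            mad = np.abs(x[:, None] - x[None, :]).mean()
            oracle = mad / (2.0 * x.mean())
            assert cg.gini_sparsity(x) == pytest.approx(oracle, abs=1e-9)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            cg.gini_sparsity([0, 0, 0])


class TestAbid:
    def test_collinear_neighbours_dimension_one(self):
        pts = np.linspace(0, 1, 30)[None, :]  # events on a line in 1-D
        D, mean = cg.abid_dimensionality(np.vstack([pts, 2 * pts]), k=5, zscore=False)
        assert mean == pytest.approx(1.0, abs=1e-6)

    def test_orthogonal_neighbours_k2(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]]).T  # units x events
        D, _ = cg.abid_dimensionality(pts, k=2, zscore=False)
        assert D[0] == pytest.approx(2.0)

    @pytest.mark.parametrize("d", [2, 3])
    def test_isotropic_gaussian_calibration(self, d):
        rng = np.random.default_rng(40 + d)
        X = rng.normal(size=(d, 2000))
        _, mean = cg.abid_dimensionality(X, k=50, zscore=False)
        assert abs(mean - d) / d < 0.10

    def test_d5_gaussian_known_downward_bias(self):
        """At d=5 the diagonal terms bound the estimate by k*d/(k+d-1) = 4.63
        and the Gaussian density gradient at n=2000 biases it further down."""
        rng = np.random.default_rng(45)
        X = rng.normal(size=(5, 2000))
        _, mean = cg.abid_dimensionality(X, k=50, zscore=False)
        limit = 50 * 5 / (50 + 5 - 1)
        assert 3.9 < mean < limit

    def test_needs_more_events_than_k(self):
        with pytest.raises(ValueError):
            cg.abid_dimensionality(np.zeros((3, 10)), k=50)


class TestNormalizedDimensionality:
    def test_structureless_ratio_near_one(self):
        rng = np.random.default_rng(9)
        X = rng.poisson(2.0, (12, 400)).astype(float)
        ratio = cg.normalized_dimensionality(X, k=20, n_surrogates=5, seed=0)
        assert 0.9 < ratio < 1.1

    def test_planted_motifs_lower_ratio(self, spike_pvs):
        pv = spike_pvs[("post-sleep", "LM")].astype(float)
        ratio = cg.normalized_dimensionality(pv, k=50, n_surrogates=5, seed=1)
        assert 0 < ratio < 0.98


class TestParticipationRatio:
    def test_known_spectrum(self):
        """Singular values (sqrt(2), 1, 1) -> PR = 16/6."""
        rng = np.random.default_rng(10)
        basis, _ = np.linalg.qr(rng.normal(size=(8, 4)))
        v = basis[:, :3]
        ones = np.ones(8) / np.sqrt(8)
        v = v - ones[:, None] * (ones @ v)  # orthogonal to constant => centred
        v, _ = np.linalg.qr(v)
        Z = np.diag([np.sqrt(2), 1.0, 1.0]) @ v.T
        assert cg.participation_ratio(Z, zscore=False) == pytest.approx(16 / 6, abs=1e-6)

    def test_rank_one_gives_one(self):
        u = np.outer(np.arange(5.0), [1.0, -1.0])
        assert cg.participation_ratio(u, zscore=False) == pytest.approx(1.0)

    def test_equal_eigenvalues_give_n(self):
        Z = np.zeros((4, 8))
        Z[0, :2] = [1, -1]
        Z[1, 2:4] = [1, -1]
        Z[2, 4:6] = [1, -1]
        Z[3, 6:8] = [1, -1]
        assert cg.participation_ratio(Z, zscore=False) == pytest.approx(4.0)


class TestInclusion:
    def test_identical(self):
        assert cg.asymmetric_inclusion([1, 0, 2], [3, 0, 1]) == 1.0

    def test_disjoint(self):
        assert cg.asymmetric_inclusion([1, 0, 0], [0, 1, 1]) == 0.0

    def test_subset_asymmetry(self):
        m = [1, 1, 0]
        q = [1, 1, 1]
        assert cg.asymmetric_inclusion(m, q) == 1.0
        assert cg.asymmetric_inclusion(q, m) == pytest.approx(2 / 3)

    def test_empty_m_undefined(self):
        assert np.isnan(cg.asymmetric_inclusion([0, 0], [1, 1]))

    def test_resampled_identical_sets(self):
        rng = np.random.default_rng(11)
        pv = (rng.random((10, 40)) < 0.5).astype(int)
        out = cg.inclusion_resampled(pv, pv, n_iter=20, seed=0)
        assert np.all((0 <= out) & (out <= 1))

    def test_core_within_composite_structure(self, spike_pvs):
        """LM (core) patterns are included in Rad (composite) patterns more
        than the reverse construction would allow by chance."""
        lm = spike_pvs[("pre-sleep", "LM")]
        rad = spike_pvs[("pre-sleep", "Rad")]
        obs = cg.inclusion_resampled(lm, rad, n_iter=50, seed=1).mean()
        rng = np.random.default_rng(2)
        null = []
        for _ in range(20):
            lm_s = np.array([rng.permutation(c) for c in lm.T]).T
            rad_s = np.array([rng.permutation(c) for c in rad.T]).T
            null.append(cg.inclusion_resampled(lm_s, rad_s, n_iter=10, seed=3).mean())
        assert obs > np.percentile(null, 97.5)


class TestExcitabilityControl:
    def test_rates_only_generator_within_band(self):
        rng = np.random.default_rng(12)
        rates = rng.gamma(2.0, 1.0, 15)
        X = rng.poisson(rates[:, None], (15, 500)).astype(int)
        obs, surr = cg.excitability_control_pc1(X, n_surrogates=100, seed=0)
        lo, hi = np.percentile(surr, [2.5, 97.5])
        assert lo - 0.05 <= obs <= hi + 0.05

    def test_rate_independent_motif_below_band(self):
        rng = np.random.default_rng(13)
        n = 800
        X = rng.poisson(2.0, (15, n))
        active = rng.random(n) < 0.5
        X[:5, active] += rng.poisson(2.0, (5, active.sum()))  # same-rate motif units
        X[5:, ~active] += rng.poisson(2.0, (10, (~active).sum())) // 2
        obs, surr = cg.excitability_control_pc1(X, n_surrogates=100, seed=1)
        assert obs < np.percentile(surr, 2.5)

    def test_r_in_valid_range(self, spike_pvs):
        obs, surr = cg.excitability_control_pc1(
            spike_pvs[("post-sleep", "Rad")], n_surrogates=20, seed=2
        )
        assert -1 <= obs <= 1
        assert np.all((-1 <= surr) & (surr <= 1))
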