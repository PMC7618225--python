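import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from hypothesis.extra.numpy import arrays
from scipy.special import iv

from ripplelamina import population_activity as pa


def poisson_spikes(rate, duration, rng, unit=0):
    n = rng.poisson(rate * duration)
    return np.full(n, unit), np.sort(rng.uniform(0, duration, n))


class TestPopulationVectors:
    def test_window_is_half_open_and_counts_exact(self):
        spikes = (np.array([0, 0, 0, 1]), np.array([0.976, 1.0, 1.0249, 1.025]))
        counts = pa.population_vectors(spikes, [0, 1], [1.0])
        assert counts[0, 0] == 3  # spike at +25 ms excluded (half-open)
        assert counts[1, 0] == 0

    def test_shape_and_nonnegativity(self, spike_pvs):
        pv = spike_pvs[("post-sleep", "Rad")]
        assert pv.ndim == 2 and pv.shape[0] == spike_pvs["unit_ids"].size
        assert (pv >= 0).all()


class TestPeth:
    def test_homogeneous_poisson_flat(self):
        rng = np.random.default_rng(0)
        units, times = poisson_spikes(20.0, 2000.0, rng)
        events = np.arange(5.0, 1995.0, 2.0)
        rates, lags = pa.compute_peth((units, times), [0], events)
        se = rates[0].std()
        assert np.abs(rates[0] - 20.0).max() < 20.0 * 0.2 + 3 * se

    def test_planted_doubling_peak(self):
        rng = np.random.default_rng(1)
        units, times = poisson_spikes(10.0, 1000.0, rng)
        events = np.arange(5.0, 995.0, 1.0)
        extra = np.concatenate([rng.uniform(t - 0.01, t + 0.01, rng.poisson(0.2)) for t in events])
        units = np.concatenate([units, np.zeros(extra.size, dtype=int)])
        times = np.concatenate([times, extra])
        rates, lags = pa.compute_peth((units, times), [0], events)
        assert pa.peak_rate(rates, lags)[0] > 1.5 * 10.0

    def test_rate_integral_matches_spike_count(self):
        rng = np.random.default_rng(2)
        units, times = poisson_spikes(15.0, 500.0, rng)
        events = np.arange(5.0, 495.0, 5.0)
        rates, lags = pa.compute_peth((units, times), [0], events, smoothing_sd_ms=0)
        bin_s = lags[1] - lags[0]
        per_event = rates[0].sum() * bin_s
        m = (times[None, :] >= events[:, None] - 0.2) & (times[None, :] < events[:, None] + 0.2)
        assert per_event == pytest.approx(m.sum() / events.size, rel=0.01)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            pa.compute_peth((np.array([0]), np.array([1.0])), [0], [])


class TestDeltaLogRate:
    def test_examples(self):
        assert pa.delta_log_rate(5.0, 5.0) == 0.0
        assert pa.delta_log_rate(50.0, 5.0) == pytest.approx(1.0)
        assert np.isnan(pa.delta_log_rate(5.0, 0.0))


class TestPhaseCoupling:
    def test_point_mass(self):
        phase, coh = pa.ripple_phase_coupling(np.full(100, np.pi / 2))
        assert phase == pytest.approx(np.pi / 2, abs=0.14)  # bin-centre quantisation
        assert coh == pytest.approx(1.0, abs=1e-9)

    def test_uniform_phases_low_coherence(self):
        rng = np.random.default_rng(3)
        _, coh = pa.ripple_phase_coupling(rng.uniform(0, 2 * np.pi, 200_000))
        assert coh < 0.05

    def test_von_mises_coherence_matches_bessel_oracle(self):
        rng = np.random.default_rng(4)
        kappa = 2.0
        sample = rng.vonmises(1.0, kappa, 100_000) % (2 * np.pi)
        _, coh = pa.ripple_phase_coupling(sample)
        assert coh == pytest.approx(iv(1, kappa) / iv(0, kappa), abs=0.05)

    def test_no_spikes_undefined(self):
        phase, coh = pa.ripple_phase_coupling([])
        assert np.isnan(phase) and np.isnan(coh)


def test_int_to_pyr_ratio():
    assert pa.int_to_pyr_ratio([4.0, 6.0], [5.0]) == pytest.approx(0.0)
    assert pa.int_to_pyr_ratio([10.0], [5.0]) == pytest.approx(np.log10(2))
    with pytest.raises(ValueError):
        pa.int_to_pyr_ratio([], [1.0])


class TestMarginShuffle:
    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        arrays(
            np.int64,
            hst.tuples(hst.integers(1, 8), hst.integers(1, 8)),
            elements=hst.integers(0, 6),
        )
    )
    def test_margins_conserved_exactly(self, X):
        out = pa.margin_preserving_shuffle(X, seed=0)
        assert np.array_equal(out.sum(axis=1), X.sum(axis=1))
        assert np.array_equal(out.sum(axis=0), X.sum(axis=0))

    def test_margins_conserved_on_large_random_matrices(self):
        rng = np.random.default_rng(5)
        for _ in range(1000):
            X = rng.poisson(1.0, size=(rng.integers(2, 30), rng.integers(2, 30)))
            out = pa.margin_preserving_shuffle(X, rng=rng)
            assert np.array_equal(out.sum(axis=1), X.sum(axis=1))
            assert np.array_equal(out.sum(axis=0), X.sum(axis=0))

    def test_two_by_two_exhaustive_support(self):
        X = np.array([[1, 0], [0, 1]])
        seen = set()
        for s in range(50):
            seen.add(tuple(pa.margin_preserving_shuffle(X, seed=s).ravel()))
        assert seen <= {(1, 0, 0, 1), (0, 1, 1, 0)}
        assert len(seen) == 2

    def test_planted_correlation_destroyed(self):
        rng = np.random.default_rng(6)
        common = rng.poisson(2.0, 2000)
        X = np.vstack([common + rng.poisson(0.3, 2000), common + rng.poisson(0.3, 2000)])
        X = np.vstack([X, rng.poisson(2.0, (6, 2000))])
        r_obs = np.corrcoef(X[0], X[1])[0, 1]
        rs = np.empty(200)
        for s in range(200):
            S = pa.margin_preserving_shuffle(X, seed=s)
            rs[s] = np.corrcoef(S[0], S[1])[0, 1]
        mc_se = rs.std(ddof=1) / np.sqrt(rs.size)
        assert r_obs > 0.5  # planted correlation present
        # independence oracle given the preserved margins: each column total T
        # is split multinomially by row shares p_i, so
        # Cov = p0 p1 (Var T - E T) and Var X_i = p_i^2 Var T + p_i (1-p_i) E T
        T = X.sum(axis=0).astype(float)
        p = X.sum(axis=1) / X.sum()
        cov = p[0] * p[1] * (T.var() - T.mean())
        var = p**2 * T.var() + p * (1 - p) * T.mean()
        r_indep = cov / np.sqrt(var[0] * var[1])
        assert abs(rs.mean() - r_indep) < 3 * mc_se + 0.01


class TestDecoding:
    def test_perfect_confusion_is_one_bit(self):
        assert pa._plugin_mi_bits(np.array([[50, 0], [0, 50]])) == pytest.approx(1.0)

    def test_plugin_bias_matches_analytic_oracle(self):
        """Independent labels: plug-in MI bias ~ (|X|-1)(|Y|-1) / (2 N ln 2)."""
        rng = np.random.default_rng(7)
        n = 500
        vals = []
        for _ in range(300):
            a = rng.integers(0, 2, n)
            b = rng.integers(0, 2, n)
            conf = np.zeros((2, 2))
            np.add.at(conf, (a, b), 1)
            vals.append(pa._plugin_mi_bits(conf))
        expected_bias = 1.0 / (2 * n * np.log(2))
        assert np.mean(vals) < 0.02
        assert np.mean(vals) == pytest.approx(expected_bias, rel=0.5)

    def test_independent_labels_within_control_band(self):
        rng = np.random.default_rng(8)
        X = rng.poisson(1.0, size=(20, 600))
        y = np.repeat(["Rad", "LM"], 300)
        out = pa.decode_ripple_type(
            X, y, n_cells=10, n_perm=10, n_cv=5, min_events_per_class=250, seed=0
        )
        assert out["mi_bits"] < 0.05
        assert abs(out["mi_bits"] - out["mi_null_bits"]) < 0.03

    def test_inclusion_rules_enforced(self):
        X = np.zeros((20, 100), dtype=int)
        y = np.repeat(["Rad", "LM"], 50)
        with pytest.raises(ValueError):
            pa.decode_ripple_type(X, y, n_cells=10)
        with pytest.raises(ValueError):
            pa.decode_ripple_type(
                np.zeros((5, 600), dtype=int),
                np.repeat(["Rad", "LM"], 300),
                n_cells=15,
                min_events_per_class=250,
            )


class TestTemporalPatternFeatures:
    def test_two_columns_per_unit_and_zscore(self):
        rng = np.random.default_rng(9)
        units, times = poisson_spikes(20.0, 300.0, rng)
        u2, t2 = poisson_spikes(15.0, 300.0, rng, unit=1)
        spikes = (np.concatenate([units, u2]), np.concatenate([times, t2]))
        events = np.arange(5.0, 295.0, 1.0)
        feats, flagged = pa.temporal_pattern_features(spikes, [0, 1], events)
        assert feats.shape == (events.size, 4)
        assert np.allclose(feats.mean(axis=0), 0, atol=1e-9)
        assert flagged == []

    def test_silent_unit_flagged(self):
        rng = np.random.default_rng(10)
        units, times = poisson_spikes(20.0, 100.0, rng)
        events = np.arange(5.0, 95.0, 1.0)
        feats, flagged = pa.temporal_pattern_features((units, times), [0, 7], events)
        assert 7 in flagged
        assert np.allclose(feats[:, 2:], 0.0)

    def test_planted_pre_event_transient_separates_classes(self):
        """A CA3-like pre-peak transient in LM events shows up in the features."""
        rng = np.random.default_rng(11)
        n_ev = 300
        events = np.arange(5.0, 5.0 + n_ev)
        labels = np.repeat(["LM", "Rad"], n_ev // 2)
        base_u, base_t = poisson_spikes(5.0, events.max() + 5, rng)
        extra = [
            rng.uniform(t - 0.11, t - 0.09, 3)
            for t, lab in zip(events, labels)
            if lab == "LM"
        ]
        times = np.concatenate([base_t, *extra])
        units = np.zeros(times.size, dtype=int)
        feats, _ = pa.temporal_pattern_features((units, times), [0], events)
        counts = pa.population_vectors((units, times), [0], events).astype(float)
        d_feat = np.abs(
            feats[labels == "LM"].mean(axis=0) - feats[labels == "Rad"].mean(axis=0)
        ).max()
        zc = pa.zscore_rows(counts)[0]
        d_count = abs(zc[labels == "LM"].mean() - zc[labels == "Rad"].mean())
        assert d_feat > d_count
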