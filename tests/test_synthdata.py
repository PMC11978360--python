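"""Generative-model checks: planted structure, moments, reproducibility."""

import numpy as np
import pytest

from midpipe import (LinearTaskSpec, SessionConfig, SpikingTaskSpec,
                     bin_delay_activity, gen_linear_task, gen_session,
                     gen_spiking_task)


class TestLinearTask:
    def test_zero_signal_classes_coincide(self):
        p, _ = gen_linear_task(LinearTaskSpec(n_dims=2, signal_d=0.0,
                                              n_patterns=1000, seed=1))
        mu_pos = p.matrix[p.labels == 1].mean(axis=0)
        mu_neg = p.matrix[p.labels == -1].mean(axis=0)
        # class means identical up to 4 standard errors of the difference
        se = np.sqrt(2.0 / 500)
        assert np.linalg.norm(mu_pos - mu_neg) < 4 * se * np.sqrt(2)

    def test_mean_projection_separation_equals_d(self):
        d = 10.0
        p, t = gen_linear_task(LinearTaskSpec(n_dims=10, signal_d=d,
                                              n_patterns=400, seed=2))
        w_hat = t.weight_vector / np.linalg.norm(t.weight_vector)
        proj = p.matrix @ w_hat
        gap = proj[p.labels == 1].mean() - proj[p.labels == -1].mean()
        # separation along w is d * |w| = d; noise SE ~ sqrt(1/200)*2
        assert gap == pytest.approx(d, abs=4 * np.sqrt(2.0 / 200))

    def test_class_mean_difference_recovers_w(self):
        # with d=4, T=2000, n=50 the empirical mean difference vector is
        # d*w + noise of per-coordinate SE sqrt(4/T); its normalized overlap
        # with w concentrates near d/sqrt(d^2 + 4n/T) ~ 0.98
        p, t = gen_linear_task(LinearTaskSpec(n_dims=50, signal_d=4.0,
                                              n_patterns=2000, seed=3))
        diff = (p.matrix[p.labels == 1].mean(axis=0)
                - p.matrix[p.labels == -1].mean(axis=0))
        overlap = diff @ t.weight_vector / np.linalg.norm(diff)
        assert overlap > 0.95

    def test_unit_norm_sparse_ground_truth(self):
        _, t = gen_linear_task(LinearTaskSpec(n_dims=20, signal_d=1.0,
                                              sparseness_s=0.2,
                                              n_patterns=10, seed=0))
        assert np.linalg.norm(t.weight_vector) == pytest.approx(1.0)
        assert np.count_nonzero(t.weight_vector) == 4

    def test_noise_covariance_near_identity(self):
        p, t = gen_linear_task(LinearTaskSpec(n_dims=5, signal_d=2.0,
                                              n_patterns=5000, seed=4))
        noise = p.matrix - p.labels[:, None] * t.weight_vector[None, :]
        cov = np.cov(noise.T)
        se = np.sqrt(2.0 / 5000)  # SE of a covariance entry for N(0,1)
        assert np.all(np.abs(cov - np.eye(5)) < 5 * se * 5)

    def test_reproducible(self):
        spec = LinearTaskSpec(n_dims=8, signal_d=3.0, n_patterns=64, seed=11)
        a, _ = gen_linear_task(spec)
        b, _ = gen_linear_task(spec)
        np.testing.assert_array_equal(a.matrix, b.matrix)
        np.testing.assert_array_equal(a.labels, b.labels)

    @pytest.mark.parametrize("kwargs", [
        dict(n_dims=1, signal_d=1.0, n_patterns=10),
        dict(n_dims=5, signal_d=-1.0, n_patterns=10),
        dict(n_dims=5, signal_d=1.0, n_patterns=10, sparseness_s=1.5),
    ])
    def test_invalid_spec_rejected(self, kwargs):
        with pytest.raises(ValueError):
            LinearTaskSpec(**kwargs)


class TestSpikingTask:
    def test_p_fail_one_plants_nothing(self):
        p, t = gen_spiking_task(SpikingTaskSpec(
            n_neurons=20, rate_lambda=0.1, sparseness_s=0.2, p_fail=1.0,
            n_patterns=500, seed=5))
        assert t.planted_bin_indices.size == 0
        # Poisson mean = lambda within 4 SE
        se = np.sqrt(0.1 / 500)
        assert np.all(np.abs(p.matrix.mean(axis=0) - 0.1) < 4 * se)

    def test_plant_increments_exactly_the_weight_vector(self):
        spec = SpikingTaskSpec(n_neurons=20, rate_lambda=0.1,
                               sparseness_s=0.2, p_fail=0.0,
                               n_patterns=500, seed=6)
        p, t = gen_spiking_task(spec)
        # replay the generator's pre-plant draw with the same seed
        rng = np.random.default_rng(spec.seed)
        labels = np.empty(500, dtype=int)
        labels[:250] = 1
        labels[250:] = -1
        rng.shuffle(labels)
        pre = rng.poisson(0.1, size=(500, 20)).astype(float)
        delta = p.matrix - pre
        assert np.count_nonzero(t.weight_vector) == 4
        pos = p.labels == 1
        np.testing.assert_array_equal(delta[pos], np.tile(t.weight_vector,
                                                          (pos.sum(), 1)))
        assert np.all(delta[~pos] == 0)

    def test_planted_count_matches_p_fail(self):
        p, t = gen_spiking_task(SpikingTaskSpec(
            n_neurons=30, rate_lambda=0.05, sparseness_s=0.1, p_fail=0.5,
            n_patterns=1000, seed=7))
        n_pos = int((p.labels == 1).sum())
        assert t.planted_bin_indices.size == round(0.5 * n_pos)
        assert np.all(p.labels[t.planted_bin_indices] == 1)

    def test_unplanted_bins_poisson_dispersion(self):
        p, t = gen_spiking_task(SpikingTaskSpec(
            n_neurons=10, rate_lambda=0.2, sparseness_s=0.2, p_fail=1.0,
            n_patterns=5000, seed=8))
        counts = p.matrix.ravel()
        # index of dispersion test: (n-1) * var/mean ~ chi2(n-1)
        from scipy import stats
        n = counts.size
        stat = (n - 1) * counts.var() / counts.mean()
        lo, hi = stats.chi2.ppf([0.005, 0.995], n - 1)
        assert lo < stat < hi

    def test_too_sparse_rejected(self):
        with pytest.raises(ValueError):
            SpikingTaskSpec(n_neurons=20, rate_lambda=0.1,
                            sparseness_s=0.01, p_fail=0.5, n_patterns=100)


class TestSession:
    def test_window_layout(self):
        s, _ = gen_session(SessionConfig(n_trials=8, delay_s=60.0, seed=1))
        assert len(s.delay_windows) == 8
        for (a0, b0, _), (a1, b1, _) in zip(s.delay_windows,
                                            s.delay_windows[1:]):
            assert b0 - a0 == pytest.approx(60.0)
            assert a1 >= b0

    def test_zero_rate_no_plant_is_silent(self):
        s, _ = gen_session(SessionConfig(rate_hz=0.0, n_trials=2,
                                         delay_s=5.0, seed=2))
        assert all(st.size == 0 for st in s.unit_spikes.values())

    def test_binning_roundtrip_recovers_planted_bins(self):
        cfg = SessionConfig(n_units=20, n_trials=6, delay_s=20.0,
                            rate_hz=1.0, bin_width=0.1,
                            plant_sparseness=0.2, plant_p_fail=0.5, seed=3)
        session, truth = gen_session(cfg)
        raw = bin_delay_activity(session, cfg.bin_width)
        # the generator may exclude units that never spiked; align by id
        all_units = sorted(session.unit_spikes)
        planted_units = np.flatnonzero(truth.weight_vector)
        w_cols = [list(raw.neuron_ids).index(all_units[j])
                  for j in planted_units if all_units[j] in list(raw.neuron_ids)]
        assert len(w_cols) == len(planted_units)  # planted units spiked
        assert raw.n_bins == len(truth.labels)
        np.testing.assert_array_equal(raw.labels, truth.labels)
        planted_counts = raw.matrix[truth.planted_bin_indices][:, w_cols]
        assert np.all(planted_counts >= 1)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SessionConfig(delay_s=-1.0)
        with pytest.raises(ValueError):
            SessionConfig(rate_hz=-0.5)
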