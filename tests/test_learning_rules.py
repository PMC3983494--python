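"""Plasticity-rule correctness: gradients, unbiasedness, variance
reduction, and the online three-factor rule."""

import numpy as np
import pytest

from spikevar.core_dynamics import (DualNetwork, NeuronParams, SpikeRaster,
                                    run_network, trace_from_raster)
from spikevar.free_energy import FreeEnergyTracker, windowed_free_energy
from spikevar.inference_eval import (EnumerationOracle, oracle_expectation,
                                     oracle_marginal)
from spikevar.learning_rules import (HebbianTraces, LearnerConfig,
                                     _q_score_sum, fully_observed_gradient,
                                     naive_batch_update, online_step,
                                     post_factor, run_online_batch,
                                     simplified_step,
                                     variance_reduced_update,
                                     variance_scaling_experiment)


def fd_gradient(fn, w, mask, eps=1e-6):
    """Central finite differences of fn(w) over the masked entries."""
    grad = np.zeros_like(w)
    for i, j in zip(*np.nonzero(mask)):
        w[i, j] += eps
        f_plus = fn()
        w[i, j] -= 2 * eps
        f_minus = fn()
        w[i, j] += eps
        grad[i, j] = (f_plus - f_minus) / (2 * eps)
    return grad


class TestPostFactor:
    def test_continuous_limit_values(self):
        """No spike with rho*dt = a gives -a/du; a spike gives (1-a)/du."""
        p = NeuronParams(eta0=0.0, rho0=0.01)  # rho*dt = 0.01 at u = 0
        net = DualNetwork(1, 0, params=p)
        spikes = np.array([[0, 1]], dtype=np.uint8)
        tr = trace_from_raster(net, SpikeRaster(spikes))
        assert post_factor(tr, "G", 0, 0) == pytest.approx(-0.01)
        assert post_factor(tr, "G", 0, 1) == pytest.approx(0.99)

    def test_discrete_exact_mean_zero_under_sampler(self):
        """The discrete-exact factor has exactly zero mean under the
        1 - exp(-rho dt) spike sampler, for any rate."""
        for a in (0.01, 0.5, 1.0, 3.0):
            p_spike = 1 - np.exp(-a)
            coef_spike = a / np.expm1(a)
            mean = p_spike * coef_spike - (1 - p_spike) * a
            assert mean == pytest.approx(0.0, abs=1e-15)


class TestFullyObservedGradient:
    def test_matches_finite_differences(self):
        """Batch gradient vs central finite differences of the
        continuous-limit complete log-likelihood (random 5-neuron net)."""
        from spikevar.free_energy import complete_log_likelihood
        rng = np.random.default_rng(30)
        net = DualNetwork.random_init(5, 0, weight_sd=0.2, seed=31)
        raster = SpikeRaster((rng.random((5, 100)) < 0.3).astype(np.uint8))
        grad = fully_observed_gradient(trace_from_raster(net, raster))
        fd = fd_gradient(
            lambda: complete_log_likelihood(trace_from_raster(net, raster), "G"),
            net.w_g, net.structural_mask("G"))
        denom = np.maximum(np.abs(fd), 1.0)
        assert np.max(np.abs(grad - fd) / denom) < 1e-5

    def test_silent_presynaptic_neuron_gives_zero_column(self):
        rng = np.random.default_rng(32)
        spikes = (rng.random((4, 50)) < 0.4).astype(np.uint8)
        spikes[2] = 0
        net = DualNetwork.random_init(4, 0, weight_sd=0.1, seed=33)
        grad = fully_observed_gradient(trace_from_raster(net, SpikeRaster(spikes)))
        assert np.all(grad[:, 2] == 0)

    def test_convex_ml_converges_to_same_optimum(self):
        """Gradient ascent from two different initializations reaches the
        same maximum-likelihood weights (the problem is convex)."""
        rng = np.random.default_rng(34)
        raster = SpikeRaster((rng.random((3, 300)) < 0.25).astype(np.uint8))
        finals = []
        for seed in (1, 2):
            net = DualNetwork.random_init(3, 0, weight_sd=0.5, seed=seed)
            for _ in range(400):
                tr = trace_from_raster(net, raster)
                net.w_g += 2e-3 * fully_observed_gradient(tr)
            finals.append(net.w_g.copy())
        assert np.allclose(finals[0], finals[1], atol=5e-3)


class TestBatchUpdates:
    def test_zero_modulator_freezes_recognition_weights(self, enumerable_net,
                                                        enumerable_clamp):
        tr = run_network(enumerable_net, "learn", 4, clamp=enumerable_clamp,
                         rng_seed=1)
        _, dw_q = naive_batch_update(tr, 0.0, LearnerConfig())
        assert np.all(dw_q == 0)

    def test_zero_baseline_reduces_to_naive(self, enumerable_net,
                                            enumerable_clamp):
        tr = run_network(enumerable_net, "learn", 4, clamp=enumerable_clamp,
                         rng_seed=2)
        cfg = LearnerConfig()
        f = windowed_free_energy(tr)
        assert np.allclose(variance_reduced_update(tr, f, 0.0, cfg)[1],
                           naive_batch_update(tr, f, cfg)[1])

    def test_score_expectation_is_zero(self, enumerable_net, enumerable_clamp):
        """Exact <grad log q>_q = 0 over the enumerated recognition
        distribution (discrete-exact form throughout)."""
        oracle = EnumerationOracle(2, 4, enumerable_clamp)
        exp_score = oracle_expectation(
            oracle, enumerable_net,
            lambda tr: _q_score_sum(tr, "discrete_exact"))
        assert np.max(np.abs(exp_score)) < 1e-10

    def test_updates_unbiased_for_free_energy_gradient(self, enumerable_net,
                                                       enumerable_clamp):
        """Exact expected naive and baseline-removed recognition updates
        coincide and equal -mu_q times the finite-difference gradient of
        the enumerated expected free energy."""
        cfg = LearnerConfig(form="discrete_exact")
        oracle = EnumerationOracle(2, 4, enumerable_clamp)

        def naive_dwq(tr):
            f = windowed_free_energy(tr, form="discrete_exact")
            return naive_batch_update(tr, f, cfg)[1]

        def vr_dwq(tr):
            f = windowed_free_energy(tr, form="discrete_exact")
            return variance_reduced_update(tr, f, 3.7, cfg)[1]  # any constant

        exp_naive = oracle_expectation(oracle, enumerable_net, naive_dwq)
        exp_vr = oracle_expectation(oracle, enumerable_net, vr_dwq)
        assert np.max(np.abs(exp_naive - exp_vr)) < 1e-8

        def expected_f():
            return oracle_marginal(oracle, enumerable_net)["expected_free_energy"]

        fd = fd_gradient(expected_f, enumerable_net.w_q,
                         enumerable_net.structural_mask("Q"))
        assert np.max(np.abs(exp_naive - (-cfg.mu_q * fd))) < 1e-8

    def test_baseline_removal_lowers_empirical_variance(self):
        """Across independent batches at fixed weights, the baseline-removed
        update of a recognition synapse has smaller variance than the naive
        update."""
        rng = np.random.default_rng(40)
        net = DualNetwork.random_init(6, 6, weight_sd=0.01, seed=41)
        cfg = LearnerConfig()
        f_hats, scores = [], []
        for _ in range(200):
            clamp = (rng.random((6, 100)) < 0.05).astype(np.uint8)
            tr = run_network(net, "learn", 100, clamp=clamp, rng_seed=rng)
            f_hats.append(windowed_free_energy(tr))
            scores.append(_q_score_sum(tr, cfg.form)[6, 0])
        f_hats, scores = np.array(f_hats), np.array(scores)
        var_naive = np.var(f_hats * scores)
        var_vr = np.var((f_hats - f_hats.mean()) * scores)
        assert var_vr < var_naive

    def test_structural_zeros_preserved(self, enumerable_net, enumerable_clamp):
        tr = run_network(enumerable_net, "learn", 4, clamp=enumerable_clamp,
                         rng_seed=3)
        cfg = LearnerConfig()
        f = windowed_free_energy(tr)
        for dw_g, dw_q in (naive_batch_update(tr, f, cfg),
                           variance_reduced_update(tr, f, 1.0, cfg)):
            assert np.all(np.diag(dw_g) == 0)
            assert np.all(np.diag(dw_q) == 0)
            assert np.all(dw_q[:2] == 0)


class TestOnlineRule:
    def make_learn_trace(self, seed=50, n_bins=30):
        net = DualNetwork.random_init(3, 2, weight_sd=0.1, seed=seed)
        rng = np.random.default_rng(seed + 1)
        clamp = (rng.random((3, n_bins)) < 0.2).astype(np.uint8)
        return net, run_network(net, "learn", n_bins, clamp=clamp,
                                rng_seed=seed + 2)

    def test_zero_novelty_freezes_recognition_weights(self):
        net, tr = self.make_learn_trace()
        traces = HebbianTraces.zeros(net)
        # baseline timescale ~ fast timescale and warm start: e_N == 0 on
        # the first update by construction
        tracker = FreeEnergyTracker(10.0, 10.0)
        traces, dw_g, dw_q, tracker = online_step(traces, tr, 0,
                                                  tracker, LearnerConfig())
        assert np.all(dw_q == 0)

    def test_hebbian_trace_low_pass_response(self):
        """Under a constant pre/post product p the trace converges to p
        geometrically with time constant tau_g."""
        cfg = LearnerConfig(tau_g=10.0)
        h = 0.0
        p = 0.8
        values = []
        for _ in range(100):
            h += (1.0 / cfg.tau_g) * (p - h)
            values.append(h)
        expected = p * (1 - (1 - 1 / cfg.tau_g) ** np.arange(1, 101))
        assert np.allclose(values, expected, atol=1e-12)

    def test_online_steps_preserve_structural_zeros(self):
        net, tr = self.make_learn_trace(seed=60)
        traces = HebbianTraces.zeros(net)
        tracker = FreeEnergyTracker()
        for t in range(tr.n_bins):
            traces, dw_g, dw_q, tracker = online_step(traces, tr, t, tracker,
                                                      LearnerConfig())
            assert np.all(np.diag(dw_g) == 0)
            assert np.all(dw_q[:3] == 0)

    def test_time_averaged_online_matches_batch_gradient(self):
        """On stationary clamped data the accumulated online generative
        update is proportional to the batch gradient over the same window
        (within a few percent over a long window)."""
        rng = np.random.default_rng(70)
        net = DualNetwork.random_init(4, 0, weight_sd=0.05, seed=71)
        clamp = (rng.random((4, 6000)) < 0.2).astype(np.uint8)
        tr = trace_from_raster(net, SpikeRaster(clamp))
        cfg = LearnerConfig(tau_g=10.0)
        pf = post_factor(tr, "G")
        batch = fully_observed_gradient(tr)
        h = np.zeros((4, 4))
        acc = np.zeros((4, 4))
        for t in range(tr.n_bins):
            outer = np.outer(pf[:, t], tr.phi[:, t])
            np.fill_diagonal(outer, 0.0)
            h += (1.0 / cfg.tau_g) * (outer - h)
            acc += h
        denom = np.abs(batch).max()
        assert np.max(np.abs(acc - batch)) / denom < 0.05

    def test_simplified_reduces_to_generative_rule_without_hidden(self):
        net = DualNetwork.random_init(3, 0, weight_sd=0.1, seed=80)
        rng = np.random.default_rng(81)
        clamp = (rng.random((3, 20)) < 0.3).astype(np.uint8)
        tr = trace_from_raster(net, SpikeRaster(clamp))
        traces = HebbianTraces.zeros(net)
        tracker = FreeEnergyTracker()
        cfg = LearnerConfig()
        traces2, dw, _ = simplified_step(traces, tr, 0, tracker.copy(), cfg)
        traces3, dw_g, dw_q, _ = online_step(traces, tr, 0, tracker.copy(), cfg)
        assert np.allclose(dw, dw_g)

    def test_online_batch_driver_reproducible_and_clamped(self):
        net = DualNetwork.random_init(4, 2, seed=90)
        rng1, rng2 = np.random.default_rng(5), np.random.default_rng(5)
        clamp = (np.random.default_rng(91).random((4, 50)) < 0.3).astype(np.uint8)
        cfg = LearnerConfig(mu_g=1e-4, mu_q=1e-5, variant="online")
        outs = []
        for rng in (rng1, rng2):
            n = net.copy()
            out = run_online_batch(n, clamp, HebbianTraces.zeros(n),
                                   FreeEnergyTracker(), cfg, rng)
            outs.append((out["f_series"].copy(), n.w_g.copy()))
        assert np.array_equal(outs[0][0], outs[1][0])
        assert np.array_equal(outs[0][1], outs[1][1])


def test_variance_scaling_experiment_api():
    table, s_naive, s_vr = variance_scaling_experiment(
        [2, 4], n_batches=40, warmup=5, batch_bins=50, seed=0)
    assert list(table["n_hidden"]) == [2, 4]
    assert (table["var_naive"] > 0).all() and (table["var_vr"] > 0).all()
    with pytest.raises(ValueError):
        variance_scaling_experiment([4], n_batches=40)
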