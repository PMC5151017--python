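"""RBM conditionals, CD-1 updates, and exact enumeration oracles."""

import numpy as np
import pytest

from morphdbn.rbm import (
    BERNOULLI,
    GAUSSIAN,
    CDTrainingConfig,
    RBMParameters,
    _all_binary_states,
    cd1_update,
    exact_log_likelihood,
    exact_log_partition,
    exact_loglik_gradient,
    free_energy,
    gibbs_step,
    hidden_conditional,
    initialize_rbm,
    train_rbm,
    visible_conditional,
)
from morphdbn.simulate import tiny_fixture


def _random_params(n_vis, n_hid, seed, family=BERNOULLI, scale=1.0):
    rng = np.random.default_rng(seed)
    return RBMParameters(rng.normal(0, scale, (n_hid, n_vis)),
                         rng.normal(0, scale, n_vis),
                         rng.normal(0, scale, n_hid), family)


class TestConditionals:
    def test_zero_parameters_give_half(self):
        params = RBMParameters(np.zeros((3, 4)), np.zeros(4), np.zeros(3))
        v = np.array([1.0, 0.0, 1.0, 1.0])
        np.testing.assert_allclose(hidden_conditional(params, v), 0.5)
        np.testing.assert_allclose(
            visible_conditional(params, np.ones(3)), 0.5)

    def test_single_unit_saturation_monotone(self):
        probs = []
        for w in (-30.0, -1.0, 0.0, 1.0, 30.0):
            params = RBMParameters(np.array([[w]]), np.zeros(1), np.zeros(1))
            probs.append(hidden_conditional(params, np.ones(1))[0])
        assert probs[2] == pytest.approx(0.5)
        assert probs == sorted(probs)
        assert probs[0] < 1e-12 and probs[-1] > 1 - 1e-12

    def test_matches_per_unit_logistic_loop(self):
        params = _random_params(4, 3, seed=0)
        v = np.random.default_rng(1).random(4)
        got = hidden_conditional(params, v)
        for j in range(3):
            pre = sum(params.W[j, i] * v[i] for i in range(4)) + params.b_hid[j]
            assert got[j] == pytest.approx(1.0 / (1.0 + np.exp(-pre)),
                                           rel=1e-12)

    def test_gaussian_zero_weights_mean_is_bias(self):
        params = RBMParameters(np.zeros((2, 5)), np.arange(5.0), np.zeros(2),
                               GAUSSIAN)
        np.testing.assert_array_equal(
            visible_conditional(params, np.ones(2)), np.arange(5.0))

    def test_transpose_consistency(self):
        params = _random_params(4, 3, seed=2)
        swapped = RBMParameters(params.W.T, params.b_hid, params.b_vis)
        h = np.random.default_rng(3).random(3)
        np.testing.assert_allclose(visible_conditional(params, h),
                                   hidden_conditional(swapped, h), rtol=1e-14)

    def test_dimension_mismatch_raises(self):
        params = _random_params(4, 3, seed=4)
        with pytest.raises(ValueError, match="length"):
            hidden_conditional(params, np.zeros(5))
        with pytest.raises(ValueError, match="length"):
            visible_conditional(params, np.zeros(4))


class TestGibbsStep:
    def test_saturated_biases_force_fixed_point(self):
        params = RBMParameters(np.zeros((3, 4)), np.full(4, 30.0),
                               np.full(3, -30.0))
        for seed in (0, 1, 2):
            h, v = gibbs_step(params, np.zeros(4),
                              np.random.default_rng(seed))
            np.testing.assert_array_equal(h, np.zeros(3))
            np.testing.assert_array_equal(v, np.ones(4))

    def test_gaussian_chain_mean_matches_conditional(self):
        """Monte Carlo: mean of v' at a pinned hidden state, 4 SE band."""
        params = _random_params(3, 2, seed=5, family=GAUSSIAN)
        # pin h by saturating hidden biases
        params.b_hid[:] = 30.0
        target = visible_conditional(params, np.ones(2))
        rng = np.random.default_rng(6)
        n = 10_000
        draws = np.array([gibbs_step(params, np.zeros(3), rng)[1]
                          for _ in range(n)])
        se = draws.std(axis=0, ddof=1) / np.sqrt(n)
        assert np.all(np.abs(draws.mean(axis=0) - target) < 4 * se)

    def test_same_seed_same_sequence(self):
        params = _random_params(4, 3, seed=7)
        seqs = []
        for _ in range(2):
            rng = np.random.default_rng(8)
            v = np.array([1.0, 0.0, 1.0, 0.0])
            chain = []
            for _ in range(5):
                h, v = gibbs_step(params, v, rng)
                chain.append((h.copy(), v.copy()))
            seqs.append(chain)
        for (h1, v1), (h2, v2) in zip(*seqs):
            np.testing.assert_array_equal(h1, h2)
            np.testing.assert_array_equal(v1, v2)


class TestCD1Update:
    def test_zero_learning_rate_is_identity(self):
        params = _random_params(3, 2, seed=9)
        cfg = CDTrainingConfig(learning_rate=0.0)
        updated, _ = cd1_update(params, np.array([[1.0, 0.0, 1.0]]), cfg,
                                np.random.default_rng(0))
        np.testing.assert_array_equal(updated.W, params.W)
        np.testing.assert_array_equal(updated.b_vis, params.b_vis)

    def test_single_update_matches_hand_computation(self):
        """Replay the same random draws and form the CD-1 statistics by
        explicit scalar arithmetic."""
        params = _random_params(2, 2, seed=10, scale=0.7)
        batch = np.array([[1.0, 0.0], [1.0, 1.0]])
        cfg = CDTrainingConfig(learning_rate=0.3)
        updated, _ = cd1_update(params, batch, cfg,
                                np.random.default_rng(12))

        sig = lambda x: 1.0 / (1.0 + np.exp(-x))
        rng = np.random.default_rng(12)
        h0 = np.empty((2, 2))
        for i in range(2):
            for j in range(2):
                h0[i, j] = sig(params.W[j] @ batch[i] + params.b_hid[j])
        u = rng.random((2, 2))
        h_sample = (u < h0).astype(float)
        v1 = np.empty((2, 2))
        for i in range(2):
            for j in range(2):
                v1[i, j] = sig(h_sample[i] @ params.W[:, j] + params.b_vis[j])
        h1 = np.empty((2, 2))
        for i in range(2):
            for j in range(2):
                h1[i, j] = sig(params.W[j] @ v1[i] + params.b_hid[j])
        grad_W = (h0.T @ batch - h1.T @ v1) / 2
        expected_W = params.W + 0.3 * grad_W
        np.testing.assert_allclose(updated.W, expected_W, rtol=1e-12)
        np.testing.assert_allclose(updated.b_vis,
                                   params.b_vis + 0.3 * (batch - v1).mean(0),
                                   rtol=1e-12)
        np.testing.assert_allclose(updated.b_hid,
                                   params.b_hid + 0.3 * (h0 - h1).mean(0),
                                   rtol=1e-12)

    def test_weight_decay_term_is_exactly_minus_lr_wd_w(self):
        params = _random_params(3, 2, seed=11)
        batch = np.array([[1.0, 0.0, 1.0]])
        with_wd, _ = cd1_update(params, batch,
                                CDTrainingConfig(learning_rate=0.1,
                                                 weight_decay=0.5),
                                np.random.default_rng(1))
        without, _ = cd1_update(params, batch,
                                CDTrainingConfig(learning_rate=0.1),
                                np.random.default_rng(1))
        np.testing.assert_allclose(with_wd.W - without.W,
                                   -0.1 * 0.5 * params.W, rtol=1e-12)
        np.testing.assert_array_equal(with_wd.b_vis, without.b_vis)

    def test_empty_minibatch_rejected(self):
        params = _random_params(3, 2, seed=12)
        with pytest.raises(ValueError, match="empty"):
            cd1_update(params, np.empty((0, 3)), CDTrainingConfig(),
                       np.random.default_rng(0))


class TestTrainRBM:
    def test_zero_epochs_returns_initialization(self):
        data = np.array([[1.0, 0.0, 1.0, 0.0]] * 4)
        cfg = CDTrainingConfig(epochs=0, rng_seed=5)
        params, log = train_rbm(data, 3, cfg)
        expected = initialize_rbm(4, 3, BERNOULLI, cfg.init_weight_sd,
                                  np.random.default_rng(5))
        np.testing.assert_array_equal(params.W, expected.W)
        assert log == []

    def test_cd1_improves_exact_likelihood_on_tiny_models(self):
        """CD-1 raises the exact average log-likelihood vs initialization
        on a skewed two-pattern dataset in at least 8 of 10 seeds."""
        patterns = np.array([[1.0, 1.0, 0.0, 0.0]] * 7
                            + [[0.0, 0.0, 1.0, 1.0]] * 3)
        wins = 0
        for seed in range(10):
            cfg = CDTrainingConfig(learning_rate=0.2, epochs=30,
                                   rng_seed=seed)
            init = initialize_rbm(4, 3, BERNOULLI, cfg.init_weight_sd,
                                  np.random.default_rng(seed))
            trained, _ = train_rbm(patterns, 3, cfg)
            wins += (exact_log_likelihood(trained, patterns)
                     > exact_log_likelihood(init, patterns))
        assert wins >= 8

    def test_gaussian_training_curve_mostly_non_increasing(self, zscored_cohort):
        z, _, _ = zscored_cohort
        data = z.features[:100, :30]
        cfg = CDTrainingConfig(learning_rate=0.01, epochs=10, rng_seed=0)
        _, log = train_rbm(data, 16, cfg, visible_family=GAUSSIAN)
        assert len(log) == 10
        non_increasing = int(np.sum(np.diff(log) <= 0))
        assert non_increasing >= 8

    def test_nonfinite_data_rejected(self):
        data = np.array([[1.0, np.nan]])
        with pytest.raises(ValueError, match="finite"):
            train_rbm(data, 2, CDTrainingConfig())

    def test_bernoulli_range_enforced(self):
        with pytest.raises(ValueError, match="bernoulli"):
            train_rbm(np.array([[2.0, 0.0]]), 2, CDTrainingConfig())


class TestExactOracles:
    def test_zero_parameters_uniform_distribution(self):
        params = RBMParameters(np.zeros((3, 5)), np.zeros(5), np.zeros(3))
        data = np.random.default_rng(0).integers(0, 2, (6, 5)).astype(float)
        assert exact_log_likelihood(params, data) == pytest.approx(
            -5 * np.log(2), rel=1e-12)

    def test_free_energy_zero_parameters(self):
        params = RBMParameters(np.zeros((4, 3)), np.zeros(3), np.zeros(4))
        assert free_energy(params, np.ones(3)) == pytest.approx(
            -4 * np.log(2), rel=1e-12)

    def test_gaussian_free_energy_bowl(self):
        b = np.array([1.0, -2.0, 0.5])
        params = RBMParameters(np.zeros((2, 3)), b, np.zeros(2), GAUSSIAN)
        f_min = free_energy(params, b)
        for shift in (0.1, -0.7, 2.0):
            assert free_energy(params, b + shift) > f_min

    def test_hidden_permutation_invariance(self):
        params = _random_params(3, 3, seed=13)
        permuted = RBMParameters(params.W[[2, 0, 1]], params.b_vis,
                                 params.b_hid[[2, 0, 1]])
        data = _all_binary_states(3)[:4]
        assert exact_log_likelihood(params, data) == pytest.approx(
            exact_log_likelihood(permuted, data), rel=1e-12)

    def test_free_energy_path_matches_joint_enumeration(self):
        """Second, independent enumeration: sum the unnormalized joint over
        all (v, h) pairs on a 3+3 model."""
        params = _random_params(3, 3, seed=14)
        vs = _all_binary_states(3)
        hs = _all_binary_states(3)
        # log p*(v) = logsumexp_h [ h W v + b_vis.v + b_hid.h ]
        joint_logp = np.array([
            [h @ params.W @ v + params.b_vis @ v + params.b_hid @ h
             for h in hs] for v in vs])
        from scipy.special import logsumexp
        log_pstar_v = logsumexp(joint_logp, axis=1)
        log_z = logsumexp(log_pstar_v)
        data = vs[[0, 3, 5]]
        direct = np.mean([log_pstar_v[list(map(tuple, vs)).index(tuple(d))]
                          for d in data]) - log_z
        assert exact_log_likelihood(params, data) == pytest.approx(
            direct, abs=1e-10)
        np.testing.assert_allclose(-free_energy(params, vs), log_pstar_v,
                                   rtol=1e-12)

    def test_model_too_large_rejected(self):
        params = RBMParameters(np.zeros((10, 11)), np.zeros(11), np.zeros(10))
        with pytest.raises(ValueError, match="enumeration"):
            exact_log_partition(params)

    def test_gradient_fidelity_finite_differences(self):
        """Analytic expected-statistics gradient vs central differences of
        the exact log-likelihood, <= 6-unit model, 1e-5 relative."""
        params = _random_params(3, 3, seed=15, scale=0.8)
        data = _all_binary_states(3)[[1, 2, 6, 7]]
        dW, dbv, dbh = exact_loglik_gradient(params, data)
        eps = 1e-6

        def ll(p):
            return exact_log_likelihood(p, data)

        for (j, i) in [(0, 0), (1, 2), (2, 1)]:
            up = params.copy(); up.W[j, i] += eps
            dn = params.copy(); dn.W[j, i] -= eps
            fd = (ll(up) - ll(dn)) / (2 * eps)
            assert fd == pytest.approx(dW[j, i], rel=1e-5, abs=1e-9)
        for i in range(3):
            up = params.copy(); up.b_vis[i] += eps
            dn = params.copy(); dn.b_vis[i] -= eps
            fd = (ll(up) - ll(dn)) / (2 * eps)
            assert fd == pytest.approx(dbv[i], rel=1e-5, abs=1e-9)
        for j in range(3):
            up = params.copy(); up.b_hid[j] += eps
            dn = params.copy(); dn.b_hid[j] -= eps
            fd = (ll(up) - ll(dn)) / (2 * eps)
            assert fd == pytest.approx(dbh[j], rel=1e-5, abs=1e-9)


def test_tiny_fixture_generating_params_beat_perturbations():
    """The generating parameters should out-score sd-0.5 perturbations of
    themselves on their own sample, in >= 9/10 seeds."""
    wins = 0
    for seed in range(10):
        fx = tiny_fixture("rbm", seed=seed)
        ll_true = exact_log_likelihood(fx.params, fx.data)
        prng = np.random.default_rng(seed + 1000)
        perturbed = RBMParameters(
            fx.params.W + prng.normal(0, 0.5, fx.params.W.shape),
            fx.params.b_vis + prng.normal(0, 0.5, 4),
            fx.params.b_hid + prng.normal(0, 0.5, 3))
        wins += ll_true >= exact_log_likelihood(perturbed, fx.data)
    assert wins >= 9
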