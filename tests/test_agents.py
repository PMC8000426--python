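"""Agents: speaker/listener wiring and both gradient estimators."""

import numpy as np
import pytest

import colorib as cl
from colorib.agents import (
    _softmax,
    game_loss,
    gs_sample,
    init_listener,
    init_speaker,
    listener_position_dist,
    reinforce_speaker_grad,
    speaker_probs,
)


class TestSpeaker:
    def test_probs_are_a_distribution(self, rng):
        sp = init_speaker(32, hidden=16, depth=3, rng=rng)
        p = speaker_probs(sp, np.array([50.0, 10.0, -20.0]))
        assert p.shape == (32,)
        assert np.all(p >= 0) and p.sum() == pytest.approx(1.0)

    def test_zero_weights_give_uniform(self):
        sp = init_speaker(1024, hidden=8, depth=3, rng=np.random.default_rng(0))
        sp.weights = [(np.zeros_like(W), np.zeros_like(b)) for W, b in sp.weights]
        p = speaker_probs(sp, np.array([12.0, 3.0, 4.0]))
        assert np.allclose(p, 1 / 1024)

    def test_deterministic_given_seed(self):
        a = init_speaker(16, 8, 3, np.random.default_rng(4))
        b = init_speaker(16, 8, 3, np.random.default_rng(4))
        x = np.array([30.0, -5.0, 12.0])
        assert np.array_equal(speaker_probs(a, x), speaker_probs(b, x))


class TestGumbelSoftmax:
    def test_matches_formula_for_fixed_noise(self):
        p = np.array([0.6, 0.3, 0.1])
        tau = 2.5
        g = np.random.default_rng(9).gumbel(size=3)
        y = gs_sample(p, tau, np.random.default_rng(9))
        expect = np.exp((g + np.log(p)) / tau)
        expect /= expect.sum()
        assert np.allclose(y, expect, atol=1e-12)

    def test_on_simplex(self, rng):
        p = rng.dirichlet(np.ones(8))
        y = gs_sample(p, 1.0, rng)
        assert np.all(y >= 0) and y.sum() == pytest.approx(1.0)

    def test_gumbel_max_frequency_law(self, rng):
        p = np.array([0.5, 0.3, 0.15, 0.05])
        y = gs_sample(np.tile(p, (100_000, 1)), 1.0, rng)
        freq = np.bincount(y.argmax(axis=1), minlength=4) / 100_000
        se = np.sqrt(p * (1 - p) / 100_000)
        assert np.all(np.abs(freq - p) < 4 * se)

    def test_low_tau_is_nearly_one_hot(self, rng):
        # top-two Gumbel spacings are ~Exp(1), so max(y) >= 0.999 needs
        # spacing > tau * ln(999): tau = 1e-3 puts that below the 1% quantile
        p = rng.dirichlet(np.ones(16), size=10_000)
        y = gs_sample(p, 1e-3, rng)
        assert np.mean(y.max(axis=1) >= 0.999) >= 0.99

    def test_high_tau_is_nearly_uniform(self, rng):
        p = rng.dirichlet(np.ones(16))
        y = gs_sample(p, 1e6, rng)
        assert np.all(np.abs(y - 1 / 16) < 1e-3)

    def test_zero_probabilities_are_log_clamped(self, rng):
        p = np.array([1.0, 0.0, 0.0])
        y = gs_sample(p, 1.0, rng)
        assert np.all(np.isfinite(y))
        assert y.argmax() == 0

    def test_nonpositive_tau_rejected(self, rng):
        with pytest.raises(ValueError, match="tau"):
            gs_sample(np.array([0.5, 0.5]), 0.0, rng)


class TestListener:
    def test_position_distribution_sums_to_one(self, rng):
        lp = init_listener(8, 5, rng)
        msg = np.eye(8)[3]
        cands = rng.normal(50, 20, size=(2, 3))
        q = listener_position_dist(lp, msg, cands)
        assert q.shape == (2,) and q.sum() == pytest.approx(1.0)

    def test_swapping_candidates_swaps_probabilities(self, rng):
        lp = init_listener(8, 5, rng)
        msg = np.eye(8)[2]
        cands = rng.normal(50, 20, size=(2, 3))
        q = listener_position_dist(lp, msg, cands)
        q_swapped = listener_position_dist(lp, msg, cands[::-1])
        assert np.allclose(q_swapped, q[::-1], atol=1e-12)

    def test_zero_embedding_is_uninformative(self, rng):
        lp = init_listener(8, 5, rng)
        lp.embed = np.zeros_like(lp.embed)
        q = listener_position_dist(lp, np.eye(8)[0], rng.normal(size=(2, 3)))
        assert np.allclose(q, 0.5)


class TestGameLoss:
    def test_values(self):
        assert game_loss(np.array([1.0, 0.0]), 0) == pytest.approx(0.0)
        assert game_loss(np.array([0.5, 0.5]), 1) == pytest.approx(np.log(2))
        assert game_loss(np.array([0.2, 0.8]), 0) == pytest.approx(-np.log(0.2))


class TestReinforceGradient:
    def test_constant_loss_equal_to_baseline_gives_zero(self, rng):
        p = rng.dirichlet(np.ones(4), size=64)
        words = rng.integers(4, size=64)
        g = reinforce_speaker_grad(p, words, np.full(64, 0.7), 0.7, 0.0)
        assert np.allclose(g, 0.0)

    def test_entropy_gradient_vanishes_at_uniform(self):
        p = np.full((8, 5), 0.2)
        words = np.zeros(8, dtype=int)
        g = reinforce_speaker_grad(p, words, np.zeros(8), 0.0, 0.5)
        assert np.allclose(g, 0.0, atol=1e-12)

    def test_unbiased_against_analytic_policy_gradient(self, rng):
        """2-word toy game, frozen Listener: the Monte-Carlo mean of the
        score-function gradient must match d/dlogits of the expected loss."""
        lp = init_listener(2, 5, rng)
        cands = np.array([[60.0, 10.0, 5.0], [20.0, -30.0, 40.0]])
        L = np.array([game_loss(listener_position_dist(lp, np.eye(2)[w], cands), 0)
                      for w in range(2)])
        logits = np.array([0.4, -0.3])
        p = _softmax(logits)
        analytic = p * (L - p @ L)          # d E[L] / d logits
        n = 100_000
        words = (rng.random(n) < p[1]).astype(int)
        losses = L[words]
        grad = reinforce_speaker_grad(np.tile(p, (n, 1)), words, losses,
                                      baseline=0.31, entropy_coeff=0.0)
        total = grad.sum(axis=0)            # mean over batch is already /n
        per_sample = (losses - 0.31)[:, None] * (np.eye(2)[words] - p)
        se = per_sample.std(axis=0) / np.sqrt(n)
        assert np.all(np.abs(total - analytic) < 3 * se + 1e-12)


class TestTraining:
    def test_same_seed_same_trajectory(self, blob_palette):
        game = cl.GameConfig(percentile=60, vocab_size=16, seed=0)
        cfg = cl.TrainConfig(method="gs", tau=1.0, batch_size=64,
                             learning_rate=2e-3, speaker_hidden=16,
                             max_interactions=20_000, eval_every=10,
                             plateau_evals=2, seed=11)
        r1 = cl.train(blob_palette, game, cfg)
        r2 = cl.train(blob_palette, game, cfg)
        assert r1.trajectory == r2.trajectory
        for (W1, b1), (W2, b2) in zip(r1.speaker.weights, r2.speaker.weights):
            assert np.array_equal(W1, W2) and np.array_equal(b1, b2)

    def test_converged_flag_requires_success_threshold(self, blob_palette):
        game = cl.GameConfig(percentile=60, vocab_size=16, seed=0)
        cfg = cl.TrainConfig(method="gs", tau=1.0, batch_size=64,
                             learning_rate=2e-3, speaker_hidden=16,
                             max_interactions=150_000, eval_every=10,
                             plateau_evals=2, seed=0)
        run = cl.train(blob_palette, game, cfg)
        assert run.converged == (run.final_success >= cfg.success_threshold)
        assert run.converged

    def test_reinforce_also_learns_blob_game(self, blob_palette):
        game = cl.GameConfig(percentile=60, vocab_size=16, seed=0)
        cfg = cl.TrainConfig(method="reinforce", batch_size=64,
                             learning_rate=2e-3, speaker_hidden=16,
                             max_interactions=150_000, eval_every=10,
                             plateau_evals=2, seed=0)
        run = cl.train(blob_palette, game, cfg)
        assert run.final_success >= 0.95


class TestSuccessRate:
    def test_untrained_agents_near_chance(self, standin):
        rng = np.random.default_rng(3)
        sp = init_speaker(64, 16, 3, rng)
        lp = init_listener(64, 5, rng)
        thr = cl.distance_threshold(standin, 50)
        s = cl.success_rate(sp, lp, standin, thr, mode="exact")
        assert 0.3 < s < 0.7

    def test_exact_and_sampled_agree(self, standin):
        rng = np.random.default_rng(3)
        sp = init_speaker(64, 16, 3, rng)
        lp = init_listener(64, 5, rng)
        thr = cl.distance_threshold(standin, 50)
        exact = cl.success_rate(sp, lp, standin, thr, mode="exact")
        sampled = cl.success_rate(sp, lp, standin, thr, mode="sampled",
                                  n_rounds=40_000, rng=np.random.default_rng(5))
        assert abs(exact - sampled) < 4 * np.sqrt(0.25 / 40_000) + 0.01
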