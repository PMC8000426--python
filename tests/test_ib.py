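"""Information-plane scoring: meanings, mutual informations, the annealed
limit curve, and the inefficiency score."""

import numpy as np
import pytest

import colorib as cl
from colorib.ib import IBCurve, IBPoint, LN2, _mutual_infos, compute_ib_curve


def brute_force_complexity(enc, prior):
    """Literal double sum over chips and words."""
    pw = np.array([sum(prior[c] * enc[c, w] for c in range(enc.shape[0]))
                   for w in range(enc.shape[1])])
    total = 0.0
    for c in range(enc.shape[0]):
        for w in range(enc.shape[1]):
            if enc[c, w] > 0:
                total += prior[c] * enc[c, w] * np.log2(enc[c, w] / pw[w])
    return total


def brute_force_accuracy(enc, prior, M):
    """Literal triple sum over the explicit joint p(u, w)."""
    n, W = enc.shape
    joint = np.zeros((W, n))
    for w in range(W):
        for u in range(n):
            joint[w, u] = sum(prior[c] * enc[c, w] * M[c, u] for c in range(n))
    pw = joint.sum(axis=1)
    pu = joint.sum(axis=0)
    total = 0.0
    for w in range(W):
        for u in range(n):
            if joint[w, u] > 0:
                total += joint[w, u] * np.log2(joint[w, u] / (pw[w] * pu[u]))
    return total


class TestMeanings:
    def test_mode_at_center(self, standin, meanings):
        assert np.all(meanings.M.argmax(axis=1) == np.arange(standin.n_chips))

    def test_probability_ratio_closed_form(self, palette4):
        m = cl.build_meanings(palette4, 64.0)
        d = palette4.dist[0, 1]
        assert m.M[0, 0] / m.M[0, 1] == pytest.approx(np.exp(d ** 2 / 128.0))

    def test_full_matrix_hand_computed(self, palette4):
        m = cl.build_meanings(palette4, 10.0)
        raw = np.exp(-palette4.dist ** 2 / 20.0)
        assert np.allclose(m.M, raw / raw.sum(axis=1, keepdims=True), atol=1e-12)

    def test_rows_normalized(self, meanings):
        assert np.allclose(meanings.M.sum(axis=1), 1.0, atol=1e-12)

    def test_nonpositive_sigma2_rejected(self, palette4):
        with pytest.raises(ValueError, match="sigma2"):
            cl.build_meanings(palette4, 0.0)


class TestComplexityAccuracy:
    def test_one_word_system_is_free_and_useless(self, standin, meanings):
        ns = cl.NamingSystem(["w"], np.ones((330, 1)))
        assert cl.complexity(ns, standin) == pytest.approx(0.0, abs=1e-12)
        assert cl.accuracy(ns, meanings, standin) == pytest.approx(0.0, abs=1e-12)

    def test_identity_encoder_costs_log2_n(self, standin):
        ns = cl.NamingSystem(list(range(330)), np.eye(330))
        assert cl.complexity(ns, standin) == pytest.approx(np.log2(330), abs=1e-10)

    def test_matches_brute_force_oracles(self, rng):
        coords = rng.normal(50, 15, size=(5, 3))
        pal = cl.Palette(np.arange(1, 6), list("AAAAA"), np.arange(5), coords,
                         rng.dirichlet(np.ones(5)))
        m = cl.build_meanings(pal, 64.0)
        for _ in range(10):
            enc = rng.dirichlet(np.ones(3), size=5)
            ns = cl.NamingSystem([0, 1, 2], enc)
            assert cl.complexity(ns, pal) == pytest.approx(
                brute_force_complexity(enc, pal.prior), abs=1e-10)
            assert cl.accuracy(ns, m, pal) == pytest.approx(
                brute_force_accuracy(enc, pal.prior, m.M), abs=1e-10)

    def test_accuracy_bounded_by_complexity(self, standin, meanings, rng):
        for seed in range(5):
            ns = cl.make_synthetic_naming(
                standin, cl.SyntheticNamingSpec(6, float(rng.uniform(2, 25)), seed))
            acc = cl.accuracy(ns, meanings, standin)
            cx = cl.complexity(ns, standin)
            assert -1e-12 <= acc <= cx + 1e-9


class TestIbStep:
    def test_fixed_point_stays_fixed(self, palette5):
        m = cl.build_meanings(palette5, 30.0)
        enc = np.full((5, 2), 0.5)
        enc[:3, 0], enc[:3, 1] = 0.9, 0.1
        for _ in range(8000):
            new = cl.ib_step(enc, m, palette5, 3.0)
            if new.shape == enc.shape and np.max(np.abs(new - enc)) < 1e-14:
                enc = new
                break
            enc = new
        again = cl.ib_step(enc, m, palette5, 3.0)
        assert np.max(np.abs(again - enc)) < 1e-10

    def test_objective_nonincreasing(self, palette5, rng):
        m = cl.build_meanings(palette5, 30.0)
        for beta in (1.5, 4.0, 20.0):
            enc = rng.dirichlet(np.ones(4), size=5)
            prev = np.inf
            for _ in range(50):
                cx, acc = _mutual_infos(enc, palette5.prior, m.M)
                obj = cx - beta * acc
                assert obj <= prev + 1e-9
                prev = obj
                enc = cl.ib_step(enc, m, palette5, beta)

    def test_beta_one_converges_to_trivial(self, palette5, rng):
        m = cl.build_meanings(palette5, 30.0)
        curve = compute_ib_curve(m, palette5, beta_init=64, n_beta=40,
                                 tol=1e-11, max_iter=3000, envelope=False)
        assert curve.complexity[np.argmin(curve.betas)] < 1e-3

    def test_beta_below_one_rejected(self, palette5):
        m = cl.build_meanings(palette5, 30.0)
        with pytest.raises(ValueError, match="beta"):
            cl.ib_step(np.eye(5), m, palette5, 0.5)


class TestCurve:
    def test_annealing_path_monotone_in_beta(self, standin_curve):
        order = np.argsort(standin_curve.betas)
        cx = standin_curve.complexity[order]
        acc = standin_curve.accuracy[order]
        assert np.all(np.diff(cx) >= -1e-8)
        assert np.all(np.diff(acc) >= -1e-8)

    def test_envelope_concave_and_increasing(self, standin_curve):
        env = standin_curve.envelope()
        assert np.all(np.diff(env.complexity) > 0)
        assert np.all(np.diff(env.accuracy) > 0)
        slopes = np.diff(env.accuracy) / np.diff(env.complexity)
        assert np.all(np.diff(slopes) < 1e-6)

    def test_interpolation_flat_beyond_ends(self, standin_curve):
        env = standin_curve.envelope()
        assert env.accuracy_at(0.0) == pytest.approx(0.0, abs=1e-6)
        assert env.accuracy_at(100.0) == pytest.approx(env.accuracy.max())


class TestInefficiency:
    def test_curve_points_have_zero_inefficiency(self, standin_curve):
        env = standin_curve.envelope()
        for i in range(0, len(env.complexity), 7):
            p = IBPoint(env.complexity[i], env.accuracy[i], env.betas[i])
            assert cl.inefficiency(p, env) == pytest.approx(0.0, abs=1e-9)

    def test_distance_to_toy_segment_hand_computed(self):
        curve = IBCurve(np.array([8.0, 1.0]), np.array([0.0, 2.0]),
                        np.array([0.0, 1.0]))
        p = IBPoint(1.0, 0.2)
        # foot of the perpendicular from (1, 0.2) to y = x/2
        expect = abs(0.2 - 0.5) / np.sqrt(1 + 0.25)
        assert cl.inefficiency(p, curve) == pytest.approx(expect, abs=1e-12)

    def test_invariant_to_word_relabeling(self, standin, meanings, standin_curve):
        env = standin_curve.envelope()
        ns = cl.make_synthetic_naming(standin, cl.SyntheticNamingSpec(5, 10.0, 3))
        perm = np.random.default_rng(0).permutation(5)
        ns2 = cl.NamingSystem([ns.words[i] for i in perm], ns.enc[:, perm])
        p1 = IBPoint(cl.complexity(ns, standin), cl.accuracy(ns, meanings, standin))
        p2 = IBPoint(cl.complexity(ns2, standin), cl.accuracy(ns2, meanings, standin))
        assert cl.inefficiency(p1, env) == pytest.approx(cl.inefficiency(p2, env))


class TestFitBeta:
    def test_curve_point_returns_own_beta(self, standin_curve):
        env = standin_curve.envelope()
        i = len(env.betas) // 2
        p = IBPoint(env.complexity[i], env.accuracy[i])
        assert cl.fit_beta(p, env) == pytest.approx(env.betas[i], rel=1e-6)

    def test_toy_two_point_curve_interpolates_log_linearly(self):
        curve = IBCurve(np.array([4.0, 1.0]), np.array([0.0, 2.0]),
                        np.array([0.0, 1.0]))
        p = IBPoint(1.0, 0.5)  # projects to the midpoint of the segment
        assert cl.fit_beta(p, curve) == pytest.approx(2.0, rel=1e-9)

    def test_monotone_along_dense_curve(self, standin_curve):
        env = standin_curve.envelope()
        fitted = [cl.fit_beta(IBPoint(c, a), env)
                  for c, a in zip(env.complexity, env.accuracy)]
        # larger beta trades accuracy for complexity: beta rises along the curve
        assert np.all(np.diff(fitted) >= -1e-6)
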