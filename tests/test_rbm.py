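"""RBM energies, conditionals, CD-1 and the exact enumeration oracles."""

import numpy as np
import pytest

from coughdnn.rbm import (
    RBMParams,
    TrainSchedule,
    cd1_statistics,
    cd1_step,
    energy,
    exact_gradient,
    init_rbm,
    log_likelihood,
    p_h_given_v,
    p_v_given_h,
    partition_function,
    train_rbm,
)


def _binary(W, b, a):
    return RBMParams(W=np.asarray(W, float), b=np.asarray(b, float),
                     a=np.asarray(a, float), unit_type="binary")


def _gaussian(W, b, a, sigma=None):
    return RBMParams(W=np.asarray(W, float), b=np.asarray(b, float),
                     a=np.asarray(a, float), unit_type="gaussian",
                     sigma=None if sigma is None else np.asarray(sigma, float))


class TestEnergy:
    def test_zero_parameters_zero_energy(self):
        p = _binary(np.zeros((2, 2)), np.zeros(2), np.zeros(2))
        for v in ([0, 0], [1, 0], [1, 1]):
            for h in ([0, 0], [0, 1], [1, 1]):
                assert energy(p, v, h) == 0.0

    def test_single_coupling(self):
        p = _binary([[2.0]], [0.0], [0.0])
        assert energy(p, [1.0], [1.0]) == pytest.approx(-2.0)

    def test_gaussian_at_visible_bias_with_no_hidden(self):
        p = _gaussian(np.ones((3, 2)), [0.5, -1.0, 2.0], np.zeros(2))
        assert energy(p, p.b, [0.0, 0.0]) == pytest.approx(0.0)

    def test_dimension_mismatch_rejected(self):
        p = _binary(np.zeros((2, 2)), np.zeros(2), np.zeros(2))
        with pytest.raises(ValueError):
            energy(p, [1.0], [0.0, 1.0])


class TestConditionals:
    def test_zero_parameters_give_half(self):
        p = _binary(np.zeros((3, 4)), np.zeros(3), np.zeros(4))
        np.testing.assert_allclose(p_h_given_v(p, np.zeros(3)), 0.5)

    def test_unit_weight_sigmoid(self):
        p = _binary([[1.0]], [0.0], [0.0])
        assert p_h_given_v(p, [1.0])[0] == pytest.approx(1 / (1 + np.exp(-1)), abs=1e-6)

    def test_hidden_means_in_open_interval(self):
        rng = np.random.default_rng(0)
        p = _binary(rng.normal(size=(4, 3)), rng.normal(size=4), rng.normal(size=3))
        means = p_h_given_v(p, rng.integers(0, 2, size=(10, 4)).astype(float))
        assert np.all(means > 0) and np.all(means < 1)

    def test_binary_visible_given_zero_hidden(self):
        p = _binary(np.ones((2, 2)), [0.3, -0.7], np.zeros(2))
        expected = 1 / (1 + np.exp(-np.array([0.3, -0.7])))
        np.testing.assert_allclose(p_v_given_h(p, np.zeros(2)), expected)

    def test_gaussian_visible_given_zero_hidden(self):
        sigma = np.array([1.5, 0.5])
        p = _gaussian(np.ones((2, 3)), [1.0, -2.0], np.zeros(3), sigma)
        np.testing.assert_allclose(p_v_given_h(p, np.zeros(3)), p.b)

    def test_gaussian_conditionals_reduce_to_linear_form_at_unit_sigma(self):
        """With sigma = 1 the hidden conditional equals the binary formula
        and the visible mean is W h + b."""
        rng = np.random.default_rng(1)
        W, b, a = rng.normal(size=(3, 2)), rng.normal(size=3), rng.normal(size=2)
        g = _gaussian(W, b, a)
        bi = _binary(W, b, a)
        v = rng.normal(size=3)
        np.testing.assert_allclose(p_h_given_v(g, v), p_h_given_v(bi, v))
        h = np.array([1.0, 0.0])
        np.testing.assert_allclose(p_v_given_h(g, h), W @ h + b)


class TestPartitionFunction:
    def test_all_zero_one_by_one(self):
        p = _binary(np.zeros((1, 1)), np.zeros(1), np.zeros(1))
        assert partition_function(p) == pytest.approx(4.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_joint_distribution_normalizes(self, seed):
        rng = np.random.default_rng(seed)
        p = _binary(rng.normal(size=(3, 3)), rng.normal(size=3), rng.normal(size=3))
        Z = partition_function(p)
        total = 0.0
        import itertools
        for v in itertools.product([0.0, 1.0], repeat=3):
            for h in itertools.product([0.0, 1.0], repeat=3):
                total += np.exp(-energy(p, np.array(v), np.array(h))) / Z
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_invariant_under_hidden_unit_exchange(self):
        rng = np.random.default_rng(2)
        p = _binary(rng.normal(size=(2, 3)), rng.normal(size=2), rng.normal(size=3))
        swapped = _binary(p.W[:, [1, 0, 2]], p.b, p.a[[1, 0, 2]])
        assert partition_function(p) == pytest.approx(partition_function(swapped))

    def test_large_model_rejected(self):
        p = _binary(np.zeros((10, 10)), np.zeros(10), np.zeros(10))
        with pytest.raises(ValueError):
            partition_function(p)


class TestExactGradient:
    def test_uniform_data_zero_parameters_zero_gradient(self):
        """When the empirical distribution is uniform over all visibles and
        the model is symmetric, data and model terms coincide."""
        import itertools
        p = _binary(np.zeros((3, 2)), np.zeros(3), np.zeros(2))
        data = np.array(list(itertools.product([0.0, 1.0], repeat=3)))
        dW, da, db = exact_gradient(p, data)
        np.testing.assert_allclose(dW, 0.0, atol=1e-12)
        np.testing.assert_allclose(da, 0.0, atol=1e-12)
        np.testing.assert_allclose(db, 0.0, atol=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_finite_differences(self, seed):
        """Exact gradient equals central finite differences of the exact
        log likelihood within 1e-5."""
        rng = np.random.default_rng(seed)
        V, H = 3, 2
        p = _binary(0.5 * rng.normal(size=(V, H)), 0.5 * rng.normal(size=V),
                    0.5 * rng.normal(size=H))
        data = rng.integers(0, 2, size=(6, V)).astype(float)
        dW, da, db = exact_gradient(p, data)
        eps = 1e-5

        def ll(params):
            return log_likelihood(params, data)

        for i in range(V):
            for j in range(H):
                Wp, Wm = p.W.copy(), p.W.copy()
                Wp[i, j] += eps
                Wm[i, j] -= eps
                fd = (ll(_binary(Wp, p.b, p.a)) - ll(_binary(Wm, p.b, p.a))) / (2 * eps)
                assert dW[i, j] == pytest.approx(fd, abs=1e-5)
        for i in range(V):
            bp, bm = p.b.copy(), p.b.copy()
            bp[i] += eps
            bm[i] -= eps
            fd = (ll(_binary(p.W, bp, p.a)) - ll(_binary(p.W, bm, p.a))) / (2 * eps)
            assert db[i] == pytest.approx(fd, abs=1e-5)
        for j in range(H):
            ap, am = p.a.copy(), p.a.copy()
            ap[j] += eps
            am[j] -= eps
            fd = (ll(_binary(p.W, p.b, ap)) - ll(_binary(p.W, p.b, am))) / (2 * eps)
            assert da[j] == pytest.approx(fd, abs=1e-5)

    def test_consistent_under_hidden_relabeling(self):
        rng = np.random.default_rng(3)
        p = _binary(rng.normal(size=(2, 2)), rng.normal(size=2), rng.normal(size=2))
        data = rng.integers(0, 2, size=(5, 2)).astype(float)
        dW, da, _ = exact_gradient(p, data)
        swapped = _binary(p.W[:, ::-1], p.b, p.a[::-1])
        dWs, das, _ = exact_gradient(swapped, data)
        np.testing.assert_allclose(dWs, dW[:, ::-1], atol=1e-12)
        np.testing.assert_allclose(das, da[::-1], atol=1e-12)


class TestCD1:
    def test_zero_lr_leaves_parameters_unchanged(self):
        rng = np.random.default_rng(0)
        p = init_rbm(3, 2, seed=0)
        batch = rng.integers(0, 2, size=(8, 3)).astype(float)
        q = cd1_step(p, batch, 0.0, np.random.default_rng(1))
        np.testing.assert_array_equal(q.W, p.W)
        np.testing.assert_array_equal(q.a, p.a)
        np.testing.assert_array_equal(q.b, p.b)

    def test_update_scales_linearly_with_lr(self):
        rng = np.random.default_rng(0)
        p = init_rbm(3, 2, seed=0)
        batch = rng.integers(0, 2, size=(8, 3)).astype(float)
        q1 = cd1_step(p, batch, 0.1, np.random.default_rng(42))
        q2 = cd1_step(p, batch, 0.2, np.random.default_rng(42))
        np.testing.assert_allclose(q2.W - p.W, 2 * (q1.W - p.W), atol=1e-12)

    def test_same_seed_reproduces_update(self):
        rng = np.random.default_rng(0)
        p = init_rbm(4, 3, seed=1)
        batch = rng.integers(0, 2, size=(16, 4)).astype(float)
        q1 = cd1_step(p, batch, 0.05, np.random.default_rng(7))
        q2 = cd1_step(p, batch, 0.05, np.random.default_rng(7))
        np.testing.assert_array_equal(q1.W, q2.W)

    def test_empty_minibatch_rejected(self):
        p = init_rbm(2, 2)
        with pytest.raises(ValueError):
            cd1_step(p, np.zeros((0, 2)), 0.1, np.random.default_rng(0))

    def test_cd1_direction_correlates_with_exact_gradient(self):
        """On random small binary RBMs the CD-1 update direction has
        positive dot product with the exact gradient in >= 95/100 cases."""
        rng = np.random.default_rng(123)
        hits = 0
        for _ in range(100):
            p = _binary(0.5 * rng.normal(size=(2, 2)),
                        0.5 * rng.normal(size=2), 0.5 * rng.normal(size=2))
            probs = rng.uniform(0.2, 0.8, size=2)
            data = (rng.uniform(size=(64, 2)) < probs).astype(float)
            dW, da, db = cd1_statistics(p, data, np.random.default_rng(rng.integers(2**31)))
            eW, ea, eb = exact_gradient(p, data)
            dot = np.sum(dW * eW) + np.sum(da * ea) + np.sum(db * eb)
            hits += dot > 0
        assert hits >= 95


class TestTrainRBM:
    def test_zero_epochs_identity(self):
        p = init_rbm(3, 2, seed=0)
        q, hist = train_rbm(p, np.zeros((4, 3)), TrainSchedule(epochs=0))
        np.testing.assert_array_equal(q.W, p.W)
        assert hist == []

    def test_training_improves_exact_likelihood(self):
        """CD-1 training on a 2-pattern dataset raises the exact data
        log likelihood of a tiny binary RBM."""
        rng = np.random.default_rng(5)
        data = np.array([[1, 1, 0, 0], [0, 0, 1, 1]] * 16, dtype=float)
        p = init_rbm(4, 3, seed=5)
        before = log_likelihood(p, data)
        q, hist = train_rbm(p, data, TrainSchedule(lr=0.05, batch_size=8, epochs=200, seed=5))
        assert log_likelihood(q, data) > before
        assert len(hist) == 200
        assert np.all(np.isfinite(hist))
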