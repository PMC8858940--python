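"""Network mechanics: activations, gradients, training and model search."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import tabata_ee as t
from tabata_ee.bpnn import Scaling, mse, select_best_width


class TestLogsig:
    def test_worked_values(self):
        assert t.logsig(0.0) == pytest.approx(0.5)
        assert t.logsig(math.log(3)) == pytest.approx(0.75)

    def test_stable_at_extremes(self):
        assert t.logsig(1000.0) == 1.0
        assert t.logsig(-1000.0) == 0.0
        assert np.isfinite(t.logsig(np.array([-750.0, 750.0]))).all()

    @settings(max_examples=50, derandomize=True)
    @given(st.floats(-100, 100))
    def test_symmetry_identity(self, x):
        assert t.logsig(x) + t.logsig(-x) == pytest.approx(1.0)


class TestHiddenRange:
    def test_classic_configuration(self):
        cands = t.heuristic_hidden_range(14, 1)
        assert cands == list(range(4, 16))
        assert len(cands) == 12

    def test_small_input_clipped_at_4(self):
        cands = t.heuristic_hidden_range(3, 1)
        assert cands[0] == 4
        assert all(4 <= c <= 15 for c in cands)


class TestInitAndForward:
    def test_seeded_init(self):
        a = t.init_network(5, 4, 1, seed=9)
        b = t.init_network(5, 4, 1, seed=9)
        c = t.init_network(5, 4, 1, seed=10)
        assert np.array_equal(a.w1, b.w1) and np.array_equal(a.w2, b.w2)
        assert not np.array_equal(a.w1, c.w1)
        assert a.w1.shape == (4, 6) and a.w2.shape == (1, 5)
        assert (np.abs(a.w1) <= 0.5).all()

    def test_zero_weights_give_half(self):
        m = t.NetworkModel(3, 2, 1, np.zeros((2, 4)), np.zeros((1, 3)))
        assert t.forward(m, [0.3, 0.7, 0.1]) == pytest.approx(0.5)

    def test_output_in_unit_interval(self, rng):
        for _ in range(20):
            m = t.init_network(4, 3, 1, seed=int(rng.integers(1 << 30)))
            out = t.forward(m, rng.uniform(0, 1, 4))
            assert 0.0 < out < 1.0

    def test_hand_computed_221_unit_weights(self):
        m = t.NetworkModel(2, 2, 1, np.ones((2, 3)), np.ones((1, 3)))
        a, b = 0.2, 0.7
        u = 1 / (1 + math.exp(-(a + b + 1)))
        expected = 1 / (1 + math.exp(-(2 * u + 1)))
        assert t.forward(m, [a, b]) == pytest.approx(expected, abs=1e-12)

    def test_length_mismatch_rejected(self):
        m = t.init_network(3, 2, 1, 0)
        with pytest.raises(ValueError):
            t.forward(m, [0.1, 0.2])


def finite_difference_gradients(model, X, T, eps=1e-6):
    """Central-difference oracle for the batch MSE gradients."""
    grads = []
    for w in (model.w1, model.w2):
        g = np.zeros_like(w)
        it = np.nditer(w, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            orig = w[idx]
            w[idx] = orig + eps
            e_plus = mse(model, X, T)
            w[idx] = orig - eps
            e_minus = mse(model, X, T)
            w[idx] = orig
            g[idx] = (e_plus - e_minus) / (2 * eps)
        grads.append(g)
    return grads


class TestGradients:
    def test_matches_finite_differences(self, rng):
        for trial in range(5):
            m = t.init_network(5, 4, 1, seed=100 + trial)
            X = rng.uniform(0, 1, (7, 5))
            T = rng.uniform(0.1, 0.9, (7, 1))
            g1, g2, _ = t.gradients(m, X, T)
            f1, f2 = finite_difference_gradients(m, X, T)
            for a, n in ((g1, f1), (g2, f2)):
                rel = np.linalg.norm(a - n) / (np.linalg.norm(a)
                                               + np.linalg.norm(n))
                assert rel < 1e-6

    def test_one_epoch_matches_hand_derived_step(self):
        # 1-1-1 net, momentum 0, one sample: chain rule written out by hand
        w, b1, v, b2 = 0.4, -0.2, 0.3, 0.1
        x, target, lr = 0.6, 0.7, 0.01
        m = t.NetworkModel(1, 1, 1, np.array([[w, b1]]), np.array([[v, b2]]))
        cfg = t.TrainConfig(max_epochs=1, lr0=lr, momentum=0.0, goal=0.0,
                            lr_up=1.0, lr_down=1.0)
        trained, hist = t.train(m, np.array([[x]]), np.array([target]), cfg)
        u = 1 / (1 + math.exp(-(w * x + b1)))
        o = 1 / (1 + math.exp(-(v * u + b2)))
        do = 2 * (o - target) * o * (1 - o)
        dv, db2 = do * u, do
        du = do * v * u * (1 - u)
        dw, db1 = du * x, du
        assert trained.w2[0, 0] == pytest.approx(v - lr * dv, abs=1e-12)
        assert trained.w2[0, 1] == pytest.approx(b2 - lr * db2, abs=1e-12)
        assert trained.w1[0, 0] == pytest.approx(w - lr * dw, abs=1e-12)
        assert trained.w1[0, 1] == pytest.approx(b1 - lr * db1, abs=1e-12)
        assert len(hist) == 1


class TestTraining:
    def test_xor_learned_within_budget(self):
        X = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=float)
        y = np.array([0.1, 0.9, 0.9, 0.1])
        m = t.init_network(2, 6, 1, seed=1)
        cfg = t.TrainConfig(seed=1)
        trained, hist = t.train(m, X, y, cfg)
        assert hist[-1] < cfg.goal
        assert len(hist) <= cfg.max_epochs

    def test_zero_epochs_leaves_weights_unchanged(self):
        m = t.init_network(3, 2, 1, 0)
        w1, w2 = m.w1.copy(), m.w2.copy()
        trained, hist = t.train(m, np.zeros((2, 3)), np.full(2, 0.5),
                                t.TrainConfig(max_epochs=0))
        assert hist == []
        assert np.array_equal(trained.w1, w1)
        assert np.array_equal(trained.w2, w2)

    def test_error_history_monotone_under_strict_acceptance(self):
        # err_ratio 1.0: every accepted epoch must not increase the error
        rng = np.random.default_rng(0)
        X = rng.uniform(0, 1, (20, 3))
        y = 0.1 + 0.8 * rng.uniform(size=20)
        m = t.init_network(3, 4, 1, seed=2)
        _, hist = t.train(m, X, y, t.TrainConfig(max_epochs=200,
                                                 err_ratio=1.0))
        assert all(b <= a + 1e-15 for a, b in zip(hist, hist[1:]))


class TestPredictEE:
    def fit_small(self, noise=0.0, seed=3):
        rng = np.random.default_rng(seed)
        X = rng.uniform(0, 1, (40, 3))
        y = 1.0 + 2.0 * X[:, 0] + noise * rng.normal(size=40)
        cfg = t.TrainConfig(seed=seed, max_epochs=2000)
        model, hist = t.fit_bpnn(X, y, 5, cfg)
        return model, X, y, hist

    def test_converged_fit_predicts_training_targets(self):
        model, X, y, hist = self.fit_small()
        # goal is on scaled MSE; translate to an EE-scale RMS tolerance
        span = (model.scaling.t_max - model.scaling.t_min) / 0.8
        tol = math.sqrt(max(hist[-1], 1e-12)) * span * 3
        assert np.sqrt(np.mean((t.predict_ee(model, X) - y) ** 2)) < tol

    def test_predictions_bounded_by_target_scaling(self, rng):
        model, X, y, _ = self.fit_small(noise=0.3)
        pred = t.predict_ee(model, rng.uniform(-2, 3, (50, 3)))
        lo = model.scaling.unscale_t(np.array([0.0]))[0]
        hi = model.scaling.unscale_t(np.array([1.0]))[0]
        assert ((pred > lo) & (pred < hi)).all()

    def test_unfitted_model_rejected(self):
        m = t.init_network(3, 2, 1, 0)
        with pytest.raises(ValueError, match="unfitted"):
            t.predict_ee(m, np.zeros((1, 3)))

    def test_feature_permutation_invariance(self):
        model, X, _, _ = self.fit_small()
        perm = [2, 0, 1]
        permuted = t.NetworkModel(
            3, model.n_hidden, 1,
            np.hstack([model.w1[:, perm], model.w1[:, -1:]]),
            model.w2.copy(),
            scaling=Scaling(x_min=model.scaling.x_min[perm],
                            x_max=model.scaling.x_max[perm],
                            t_min=model.scaling.t_min,
                            t_max=model.scaling.t_max))
        np.testing.assert_allclose(t.predict_ee(permuted, X[:, perm]),
                                   t.predict_ee(model, X), rtol=1e-12)


class TestHiddenNodeSearch:
    def test_constructed_profile_selection(self):
        assert select_best_width({4: 1.0, 6: 0.2, 8: 0.9}) == 6
        assert select_best_width({4: 0.5, 5: 0.5, 6: 0.5}) == 4  # tie rule

    def test_bookkeeping(self):
        rng = np.random.default_rng(5)
        X = rng.uniform(0, 1, (60, 3))
        y = 1.0 + X[:, 0]
        cfg = t.TrainConfig(seed=5, max_epochs=50)
        best, rmses = t.hidden_node_search(X, y, [4, 5, 6], cfg)
        assert set(rmses) == {4, 5, 6}
        assert best in rmses
        assert rmses[best] == min(rmses.values())

    def test_needs_two_candidates(self):
        with pytest.raises(ValueError):
            t.hidden_node_search(np.zeros((4, 2)), np.zeros(4), [6],
                                 t.TrainConfig())


def test_model_json_roundtrip_bit_exact():
    rng = np.random.default_rng(8)
    X = rng.uniform(0, 1, (30, 4))
    y = rng.uniform(1, 2, 30)
    model, _ = t.fit_bpnn(X, y, 5, t.TrainConfig(seed=8, max_epochs=20))
    back = t.NetworkModel.from_json(model.to_json())
    assert np.array_equal(back.w1, model.w1)
    assert np.array_equal(back.w2, model.w2)
    assert np.array_equal(back.scaling.x_min, model.scaling.x_min)
    assert back.scaling.t_max == model.scaling.t_max
    np.testing.assert_array_equal(t.predict_ee(back, X),
                                  t.predict_ee(model, X))
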