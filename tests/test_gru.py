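"""GRU cell, forward pass, loss and training contracts."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from repogru import (
    GruParameters,
    TrainConfig,
    bce_loss,
    forward,
    gru_step,
    load_parameters,
    predict,
    save_parameters,
    train,
)
from repogru.features import PairFeatureTable


def _sigmoid(x):
    return 1.0 / (1.0 + math.exp(-x))


def _scalar_params(w=1.0, u=1.0, b=0.0, dense_w=1.0, dense_b=0.0):
    a = np.array
    return GruParameters(
        W_z=a([[w]]), W_r=a([[w]]), W_h=a([[w]]),
        U_z=a([[u]]), U_r=a([[u]]), U_h=a([[u]]),
        b_z=a([b]), b_r=a([b]), b_h=a([b]),
        dense_w=a([dense_w]), dense_b=dense_b,
    )


def _table(X, y=None):
    n = X.shape[0]
    return PairFeatureTable(X, np.zeros((n, 2), int), ["D"] * n, ["d"] * n, y)


class TestGruStep:
    def test_zero_parameters_zero_state(self):
        p = GruParameters.zeros(3, 2)
        st_ = gru_step(p, np.zeros(3), np.zeros(2))
        np.testing.assert_array_equal(st_.z, [0.5, 0.5])
        np.testing.assert_array_equal(st_.r, [0.5, 0.5])
        np.testing.assert_array_equal(st_.c, [0.0, 0.0])
        np.testing.assert_array_equal(st_.h, [0.0, 0.0])

    def test_scalar_midpoint(self):
        p = _scalar_params(w=1.0, u=1.0, b=0.0)
        st_ = gru_step(p, np.array([0.0]), np.array([0.0]))
        assert st_.z[0] == pytest.approx(0.5)

    def test_scalar_hand_computed(self):
        # W=U=1, b=0, i=1, h_prev=0.5
        p = _scalar_params()
        i_t, h_prev = 1.0, 0.5
        z = _sigmoid(i_t + h_prev)
        r = _sigmoid(i_t + h_prev)
        c = math.tanh(i_t + r * h_prev)
        h = (1 - z) * h_prev + z * c
        st_ = gru_step(p, np.array([i_t]), np.array([h_prev]))
        assert st_.z[0] == pytest.approx(z, abs=1e-10)
        assert st_.r[0] == pytest.approx(r, abs=1e-10)
        assert st_.c[0] == pytest.approx(c, abs=1e-10)
        assert st_.h[0] == pytest.approx(h, abs=1e-10)

    def test_shape_mismatch_rejected(self):
        p = GruParameters.zeros(3, 2)
        with pytest.raises(ValueError):
            gru_step(p, np.zeros(4), np.zeros(2))

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=50, derandomize=True)
    def test_gate_bounds_and_state_bound(self, seed):
        rng = np.random.default_rng(seed)
        p = GruParameters.init(4, 3, seed % 1000)
        i_t = rng.normal(0, 3, 4)
        h_prev = rng.uniform(-1, 1, 3)
        st_ = gru_step(p, i_t, h_prev)
        assert ((st_.z > 0) & (st_.z < 1)).all()
        assert ((st_.r > 0) & (st_.r < 1)).all()
        assert ((st_.c > -1) & (st_.c < 1)).all()
        # h_t is a convex combination of h_prev and c_t
        bound = max(np.abs(h_prev).max(), 1.0)
        assert np.abs(st_.h).max() <= bound + 1e-12


class TestForward:
    def test_zero_network_outputs_half(self):
        p = GruParameters.zeros(4, 3)
        assert forward(p, np.ones(4)) == 0.5

    def test_inference_is_deterministic(self):
        p = GruParameters.init(6, 4, seed=9)
        x = np.random.default_rng(1).normal(size=6)
        assert forward(p, x) == forward(p, x)

    def test_matches_composed_hand_oracle(self):
        p = _scalar_params(dense_w=2.0, dense_b=-0.5)
        x = np.array([1.0])
        h = gru_step(p, x, np.array([0.0])).h[0]
        assert forward(p, x, timesteps=1) == pytest.approx(
            _sigmoid(2.0 * h - 0.5), abs=1e-10
        )

    def test_multi_timestep_chunking(self):
        # width 4, timesteps 2: two steps over chunks of width 2
        p = GruParameters.init(2, 3, seed=0)
        x = np.array([0.1, -0.2, 0.3, 0.4])
        h = np.zeros(3)
        for chunk in (x[:2], x[2:]):
            h = np.atleast_1d(gru_step(p, chunk, h).h)
        expected = 1.0 / (1.0 + np.exp(-(h @ p.dense_w + p.dense_b)))
        assert forward(p, x, timesteps=2) == pytest.approx(float(expected), abs=1e-12)

    def test_indivisible_width_rejected(self):
        p = GruParameters.init(2, 3, seed=0)
        with pytest.raises(ValueError, match="divisible"):
            forward(p, np.ones(5), timesteps=2)


class TestBceLoss:
    def test_symmetric_point(self):
        assert bce_loss(0.5, 0) == pytest.approx(math.log(2))
        assert bce_loss(0.5, 1) == pytest.approx(math.log(2))

    def test_perfect_prediction_limit(self):
        assert bce_loss(1.0, 1) == pytest.approx(0.0, abs=1e-6)

    def test_direct_evaluation(self):
        assert bce_loss(0.8, 1) == pytest.approx(-math.log(0.8), abs=1e-12)

    def test_clipping_keeps_loss_finite(self):
        assert np.isfinite(bce_loss(0.0, 1))
        assert np.isfinite(bce_loss(1.0, 0))


class TestTrain:
    @staticmethod
    def _separable(n=200, seed=3):
        rng = np.random.default_rng(seed)
        X = np.vstack(
            [rng.normal(1.5, 1, (n // 2, 6)), rng.normal(-1.5, 1, (n // 2, 6))]
        )
        y = np.array([1] * (n // 2) + [0] * (n // 2))
        return _table(X, y)

    def test_separable_toy_reaches_high_accuracy(self):
        cfg = TrainConfig(hidden=8, epochs=25, batch_size=32, seed=3, dropout=0.1)
        params, history = train(self._separable(), cfg)
        scores = predict(params, self._separable(), cfg)
        acc = ((scores >= 0.5) == self._separable().labels).mean()
        assert acc >= 0.95
        assert len(history) == 25

    def test_loss_decreases_early(self):
        cfg = TrainConfig(hidden=8, epochs=5, batch_size=32, seed=3)
        _, history = train(self._separable(), cfg)
        assert history[-1] < history[0]

    def test_zero_epochs_returns_initialization(self):
        cfg = TrainConfig(hidden=8, epochs=0, seed=1)
        params, history = train(self._separable(), cfg)
        expected = GruParameters.init(6, 8, seed=1)
        np.testing.assert_array_equal(params.W_z, expected.W_z)
        assert history == []

    def test_seed_reproducibility_bitwise(self):
        cfg = TrainConfig(hidden=8, epochs=4, batch_size=32, seed=7, dropout=0.25)
        p1, h1 = train(self._separable(), cfg)
        p2, h2 = train(self._separable(), cfg)
        assert h1 == h2
        np.testing.assert_array_equal(p1.W_h, p2.W_h)
        np.testing.assert_array_equal(p1.dense_w, p2.dense_w)

    def test_single_class_rejected(self):
        t = _table(np.random.default_rng(0).normal(size=(20, 4)), np.ones(20))
        with pytest.raises(ValueError, match="class"):
            train(t, TrainConfig(hidden=4, epochs=1))


class TestPredict:
    def test_matches_forward_row_by_row(self):
        cfg = TrainConfig(hidden=8, epochs=2, batch_size=16, seed=0)
        table = TestTrain._separable(60)
        params, _ = train(table, cfg)
        scores = predict(params, table, cfg)
        for i in range(0, 60, 13):
            assert scores[i] == pytest.approx(
                forward(params, table.features[i]), abs=1e-12
            )
        assert ((scores > 0) & (scores < 1)).all()

    def test_permutation_equivariance(self):
        cfg = TrainConfig(hidden=8, epochs=1, seed=0)
        table = TestTrain._separable(40)
        params, _ = train(table, cfg)
        perm = np.random.default_rng(0).permutation(40)
        permuted = _table(table.features[perm], table.labels[perm])
        np.testing.assert_allclose(
            predict(params, permuted, cfg), predict(params, table, cfg)[perm]
        )

    def test_width_mismatch_rejected(self):
        cfg = TrainConfig(hidden=8, epochs=1, seed=0)
        params, _ = train(TestTrain._separable(40), cfg)
        with pytest.raises(ValueError, match="width"):
            predict(params, _table(np.ones((3, 5))), cfg)


class TestSerialization:
    def test_round_trip(self, tmp_path):
        cfg = TrainConfig(hidden=8, epochs=2, batch_size=16, seed=5)
        table = TestTrain._separable(60)
        params, _ = train(table, cfg)
        path = tmp_path / "model.npz"
        save_parameters(params, cfg, path)
        loaded, loaded_cfg = load_parameters(path)
        np.testing.assert_array_equal(loaded.U_h, params.U_h)
        assert loaded_cfg == cfg
        np.testing.assert_allclose(
            predict(loaded, table, loaded_cfg), predict(params, table, cfg)
        )


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        """Analytic BPTT gradients agree with central finite differences."""
        from repogru.gru import _backward_batch, _forward_batch, _PARAM_NAMES

        rng = np.random.default_rng(0)
        p = GruParameters.init(3, 4, seed=2)
        X = rng.normal(size=(5, 6))  # timesteps=2, chunk width 3
        y = np.array([1.0, 0.0, 1.0, 1.0, 0.0])

        def loss_at(params):
            probs = _forward_batch(params, X, 2)
            return float(np.mean(bce_loss(probs, y)))

        probs, cache = _forward_batch(p, X, 2, keep_cache=True)
        grads = _backward_batch(p, cache, cache[2], cache[3], probs, y)

        eps = 1e-6
        for name in ("W_z", "U_h", "b_r", "dense_w"):
            arr = getattr(p, name)
            flat_idx = (0,) if arr.ndim == 1 else (0, 1)
            pert = p.copy()
            getattr(pert, name)[flat_idx] += eps
            up = loss_at(pert)
            pert = p.copy()
            getattr(pert, name)[flat_idx] -= eps
            down = loss_at(pert)
            numeric = (up - down) / (2 * eps)
            assert grads[name][flat_idx] == pytest.approx(numeric, abs=1e-5)
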