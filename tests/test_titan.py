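"""Attention predictor: algebraic contracts of the attention, memory and
output heads, plus training behavior on a separable toy."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from causalblend import titan
from causalblend._autograd import Tensor
from causalblend.titan import TitanConfig, TitanModel, attention_weights, \
    bce_loss, memory_update


@pytest.fixture(scope="module")
def small_model():
    return TitanModel(TitanConfig(hidden=32, layers=2, heads=4, seed=3),
                      n_features=5, treatment_cols=[4])


@pytest.fixture(scope="module")
def toy_fit():
    """Linearly separable toy problem with a trained reduced model."""
    rng = np.random.default_rng(0)
    X = rng.normal(0, 1, (200, 4))
    y = (X[:, 0] > 0).astype(float)
    model = TitanModel(TitanConfig(hidden=32, layers=2, heads=4, epochs=8,
                                   batch_size=64, lr=3e-3, seed=1),
                       n_features=4, treatment_cols=[3])
    trace = model.fit(X, y)
    return model, X, y, trace


class TestAttention:
    def test_rows_sum_to_one(self, rng):
        Q = rng.normal(0, 1, (6, 8))
        K = rng.normal(0, 1, (6, 8))
        W = attention_weights(Q, K, 8)
        assert np.allclose(W.sum(axis=-1), 1.0, atol=1e-7)
        assert (W > 0).all()

    def test_zero_query_uniform(self):
        W = attention_weights(np.zeros((4, 8)), np.ones((4, 8)), 8)
        assert np.allclose(W, 0.25)

    def test_length_one_sequence(self, rng):
        V = rng.normal(0, 1, (1, 8))
        W = attention_weights(rng.normal(0, 1, (1, 8)),
                              rng.normal(0, 1, (1, 8)), 8)
        assert W.shape == (1, 1) and W[0, 0] == pytest.approx(1.0)
        assert np.allclose(W @ V, V)

    def test_invalid_dk(self):
        with pytest.raises(ValueError):
            attention_weights(np.zeros((2, 2)), np.zeros((2, 2)), 0)


class TestMemory:
    def test_gate_limits(self):
        z = np.array([0.6, 0.2])
        _, m_new = memory_update(z, np.array([0.1, 0.9]),
                                 np.eye(2) * 1e6, np.full(2, 1e6))
        assert np.allclose(m_new, [0.1, 0.9])  # gate -> 1 keeps old memory
        _, m_new = memory_update(z, np.array([0.1, 0.9]),
                                 np.eye(2) * -1e6, np.full(2, -1e6))
        assert np.allclose(m_new, z)  # gate -> 0 writes the representation

    def test_half_gate_midpoint(self):
        g, m_new = memory_update(np.array([0.6]), np.array([0.2]),
                                 np.zeros((1, 1)), np.zeros(1))
        assert g[0] == pytest.approx(0.5)
        assert m_new[0] == pytest.approx(0.4)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-5, 5), min_size=3, max_size=3),
           st.lists(st.floats(-5, 5), min_size=3, max_size=3))
    def test_update_is_convex(self, z, memory):
        z, memory = np.array(z), np.array(memory)
        rng = np.random.default_rng(abs(hash(tuple(z))) % 2**31)
        _, m_new = memory_update(z, memory, rng.normal(0, 1, (3, 3)),
                                 rng.normal(0, 1, 3))
        lo, hi = np.minimum(z, memory), np.maximum(z, memory)
        assert ((m_new >= lo - 1e-12) & (m_new <= hi + 1e-12)).all()


class TestForward:
    def test_eval_mode_deterministic(self, small_model, rng):
        X = rng.normal(0, 1, (7, 5))
        assert np.array_equal(small_model.predict(X), small_model.predict(X))

    def test_representation_width(self, small_model, rng):
        z = small_model.encode(rng.normal(0, 1, (3, 5)))
        assert z.shape == (3, 32)

    def test_dropout_passes_differ(self, small_model, rng):
        X = rng.normal(0, 1, (5, 5))
        r = np.random.default_rng(11)
        assert not np.allclose(small_model.predict_stochastic(X, r),
                               small_model.predict_stochastic(X, r))

    def test_layer_norm_standardizes(self, rng):
        x = Tensor(rng.normal(2, 3, (4, 16)))
        out = titan._layer_norm(x, Tensor(np.ones(16)), Tensor(np.zeros(16)))
        assert np.allclose(out.data.mean(axis=-1), 0.0, atol=1e-5)
        assert np.allclose(out.data.std(axis=-1), 1.0, atol=1e-4)

    def test_zero_output_head_gives_half(self, small_model, rng):
        model = TitanModel(TitanConfig(hidden=32, layers=2, heads=4, seed=3),
                           5, [4])
        model.params["Wo"].data[:] = 0.0
        model.params["bo"].data = np.zeros(())
        assert np.allclose(model.predict(rng.normal(0, 1, (4, 5))), 0.5)

    def test_output_monotone_in_bias(self, small_model, rng):
        X = rng.normal(0, 1, (3, 5))
        base = small_model.predict(X)
        small_model.params["bo"].data = small_model.params["bo"].data + 1.0
        shifted = small_model.predict(X)
        small_model.params["bo"].data = small_model.params["bo"].data - 1.0
        assert (shifted > base).all()
        assert ((base > 0) & (base < 1)).all()

    def test_shape_mismatch_rejected(self, small_model):
        with pytest.raises(ValueError):
            small_model.predict(np.zeros((2, 9)))


class TestTraining:
    def test_bce_closed_form(self):
        assert bce_loss(np.array([0.5]), np.array([1.0])) == \
               pytest.approx(np.log(2), abs=1e-12)

    def test_separable_toy_fits(self, toy_fit):
        model, X, y, trace = toy_fit
        assert ((model.predict(X) > 0.5) == y).mean() > 0.95

    def test_training_loss_decreases(self, toy_fit):
        _, _, _, trace = toy_fit
        assert trace[4]["train_loss"] < trace[0]["train_loss"]

    def test_early_stopping_respects_patience(self):
        rng = np.random.default_rng(2)
        X = rng.normal(0, 1, (60, 3))
        y = rng.binomial(1, 0.5, 60).astype(float)  # unlearnable labels
        model = TitanModel(TitanConfig(hidden=16, layers=1, heads=2,
                                       epochs=40, batch_size=30, lr=1e-4,
                                       patience=4, seed=0), 3, [2])
        trace = model.fit(X, y)
        assert len(trace) < 40

    def test_single_class_warns(self):
        model = TitanModel(TitanConfig(hidden=16, layers=1, heads=2, epochs=1,
                                       batch_size=20, seed=0), 3, [2])
        with pytest.warns(UserWarning):
            model.fit(np.random.default_rng(0).normal(0, 1, (30, 3)),
                      np.ones(30))

    def test_nonbinary_labels_rejected(self, small_model):
        with pytest.raises(ValueError):
            small_model.fit(np.zeros((10, 5)), np.full(10, 0.3))


class TestCounterfactuals:
    def test_factual_arm_identity(self, toy_fit, rng):
        model, X, _, _ = toy_fit
        X1 = X.copy()
        X1[:, 3] = 1.0
        assert np.array_equal(model.counterfactual_predict(X1, 1),
                              model.predict(X1))

    def test_outputs_in_open_interval(self, toy_fit, rng):
        model, X, _, _ = toy_fit
        for arm in (0, 1):
            p = model.counterfactual_predict(X, arm)
            assert ((p > 0) & (p < 1)).all()

    def test_unknown_arm_rejected(self, toy_fit):
        model, X, _, _ = toy_fit
        with pytest.raises(ValueError):
            model.counterfactual_predict(X, 7)

    def test_dgp_contrast_tracks_oracle(self, study5000):
        """A reduced model trained on the simulated study recovers the mean
        potential-outcome contrast within 0.1 on held-out units."""
        obs, truth = study5000.observed, study5000.truth
        feats = ["X0", "X2", "X4", "Z"]
        X = obs[feats].to_numpy()
        X = (X - X.mean(0)) / X.std(0)
        X = np.column_stack([X, obs["T"].to_numpy()])
        y = obs["Y"].to_numpy(float)
        model = TitanModel(TitanConfig(hidden=32, layers=2, heads=4, epochs=8,
                                       batch_size=256, lr=2e-3, seed=0),
                           X.shape[1], [4])
        model.fit(X[:3000], y[:3000], X[3000:4000], y[3000:4000])
        hold = slice(4000, 5000)
        contrast = (model.counterfactual_predict(X[hold], 1)
                    - model.counterfactual_predict(X[hold], 0)).mean()
        oracle = (truth["p1"] - truth["p0"]).to_numpy()[hold].mean()
        assert abs(contrast - oracle) < 0.1


class TestPersistence:
    def test_checkpoint_roundtrip(self, toy_fit, tmp_path, rng):
        model, X, _, _ = toy_fit
        path = tmp_path / "model.npz"
        model.save(path)
        loaded = TitanModel.load(path)
        assert np.array_equal(loaded.predict(X), model.predict(X))

    def test_loss_trace_csv(self, toy_fit, tmp_path):
        model = toy_fit[0]
        model.write_loss_trace(tmp_path / "trace.csv")
        lines = (tmp_path / "trace.csv").read_text().strip().splitlines()
        assert lines[0] == "epoch,train_loss,val_loss"
        assert len(lines) == len(model.loss_trace) + 1


class TestMLPBaseline:
    def test_fits_toy(self):
        rng = np.random.default_rng(0)
        X = rng.normal(0, 1, (200, 3))
        y = (X[:, 0] + X[:, 1] > 0).astype(float)
        model = titan.MLPModel(titan.MLPConfig(hidden=32, layers=2, epochs=30,
                                               batch_size=64, lr=1e-2, seed=0),
                               3, [2])
        model.fit(X, y)
        assert ((model.predict(X) > 0.5) == y).mean() > 0.9

    def test_stochastic_passes_differ(self):
        model = titan.MLPModel(titan.MLPConfig(hidden=16, layers=2, seed=0),
                               3, [2])
        X = np.random.default_rng(1).normal(0, 1, (10, 3))
        r = np.random.default_rng(2)
        assert not np.allclose(model.predict_stochastic(X, r),
                               model.predict_stochastic(X, r))
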