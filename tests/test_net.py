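"""Classifier: forward pass, loss, gradients, training, persistence."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from densecg import synthetic
from densecg.errors import FormatError, InvalidSpecError, ShapeError
from densecg.net import (Topology, TrainingConfig, forward, loss,
                         loss_and_gradients, param_count, predict, train,
                         save_model, load_model)


class TestParamCount:
    @pytest.mark.parametrize("n_in,widths,expected", [
        (4, (128, 32), 4908),
        (4, (4, 4), 68),
        (4, (8, 4), 104),
        (137, (128, 32), 22198),
        (137, (), 2 * 137 + 4 * 138),   # BN + single output layer
    ])
    def test_closed_form(self, n_in, widths, expected):
        assert param_count(Topology(n_in, widths)) == expected

    def test_matches_instantiated_scalar_count(self):
        m = synthetic.fixture_network([7, 5, 3, 4], "indexed")
        assert m.n_params() == param_count(m.topology)


class TestForward:
    def test_zero_weights_uniform_probs(self):
        m = synthetic.fixture_network([3, 2, 4], "explicit",
                                      weights=[np.zeros((3, 2)), np.zeros((2, 4))])
        res = forward(m, np.array([1.0, -2.0, 0.5]))
        assert np.allclose(res.probs, 0.25)

    def test_hand_calculated_2_2_2(self):
        W1 = np.array([[1.0, 2.0], [3.0, -1.0]])
        W2 = np.array([[1.0, -1.0], [2.0, 1.0]])
        b1, b2 = np.array([0.5, -0.5]), np.array([0.0, 1.0])
        m = synthetic.fixture_network([2, 2, 2], "explicit",
                                      weights=[W1, W2], biases=[b1, b2])
        x = np.array([1.0, 1.0])
        # s1 = [1+3+0.5, 2-1-0.5] = [4.5, 0.5]; relu same
        # logits = [4.5*1+0.5*2, 4.5*(-1)+0.5*1+1] = [5.5, -3.0]
        res = forward(m, x)
        assert res.logits == pytest.approx([5.5, -3.0], abs=1e-12)
        assert list(res.activations[0]) == [True, True]

    @settings(max_examples=30, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_softmax_normalization_property(self, seed):
        rng = np.random.default_rng(seed)
        m = synthetic.fixture_network([5, 4, 4], "indexed")
        res = forward(m, rng.normal(scale=3.0, size=(7, 5)))
        assert np.allclose(res.probs.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(res.probs >= 0)

    def test_dropout_train_vs_infer(self):
        m = synthetic.fixture_network([4, 8, 4], "indexed")
        rng = np.random.default_rng(0)
        X = rng.normal(size=(16, 4))
        r_inf = forward(m, X, mode="infer")
        r_trn = forward(m, X, mode="train", dropout_rate=0.5,
                        rng=np.random.default_rng(1))
        assert not np.allclose(r_inf.probs, r_trn.probs)

    def test_dimension_mismatch(self):
        m = synthetic.fixture_network([4, 2, 4], "indexed")
        with pytest.raises(ShapeError):
            forward(m, np.zeros(5))


class TestLoss:
    def test_perfect_prediction_zero_loss(self):
        p = np.array([[0.0, 1.0, 0.0, 0.0]])
        p[0, 1] = 1.0
        assert loss(np.array([[0, 1, 0, 0.0]]), ["AF"],
                    (0.25, 0.25, 0.25, 0.25)) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_probs_closed_form(self):
        val = loss(np.full((1, 4), 0.25), ["N"], (0.25, 0.25, 0.25, 0.25))
        assert val == pytest.approx(0.25 * np.log(4.0), rel=1e-12)

    def test_weights_must_sum_to_one(self):
        with pytest.raises(InvalidSpecError):
            loss(np.full((1, 4), 0.25), ["N"], (0.5, 0.5, 0.5, 0.5))

    def test_uniform_weights_equal_quarter_unweighted(self, rng):
        probs = rng.dirichlet(np.ones(4), size=20)
        y = rng.integers(0, 4, size=20)
        weighted = loss(probs, y, (0.25,) * 4)
        unweighted = -np.mean(np.log(probs[np.arange(20), y]))
        assert weighted == pytest.approx(unweighted / 4.0, rel=1e-12)

    def test_zero_prob_clipped_with_warning(self):
        p = np.array([[1.0, 0.0, 0.0, 0.0]])
        with pytest.warns(RuntimeWarning):
            val = loss(p, ["AF"], (0.25,) * 4)
        assert np.isfinite(val)


class TestGradients:
    def test_analytic_matches_central_differences(self):
        """Backprop gradients agree with finite differences to 1e-5."""
        m = synthetic.fixture_network([5, 4, 3, 4], "indexed")
        rng = np.random.default_rng(3)
        X = rng.normal(size=(8, 5))
        y = np.array([0, 1, 2, 3, 0, 1, 2, 3])
        cw = (0.1, 0.2, 0.3, 0.4)
        _, grads, _ = loss_and_gradients(m, X, y, cw)
        eps = 1e-6

        def fd(setter, getter):
            v0 = getter()
            setter(v0 + eps)
            lp, _, _ = loss_and_gradients(m, X, y, cw)
            setter(v0 - eps)
            lm, _, _ = loss_and_gradients(m, X, y, cw)
            setter(v0)
            return (lp - lm) / (2 * eps)

        checks = []
        for l in range(3):
            W = m.dense.W[l]
            i, j = rng.integers(W.shape[0]), rng.integers(W.shape[1])
            g = fd(lambda v, W=W, i=i, j=j: W.__setitem__((i, j), v),
                   lambda W=W, i=i, j=j: W[i, j])
            checks.append((g, grads["W"][l][i, j]))
            b = m.dense.b[l]
            g = fd(lambda v, b=b, j=j: b.__setitem__(j, v), lambda b=b, j=j: b[j])
            checks.append((g, grads["b"][l][j]))
        for arrname in ("gamma", "beta"):
            arr = getattr(m.bn, arrname)
            g = fd(lambda v, a=arr: a.__setitem__(2, v), lambda a=arr: a[2])
            checks.append((g, grads[arrname][2]))
        for fd_val, an_val in checks:
            assert fd_val == pytest.approx(an_val, rel=1e-5, abs=1e-10)


class TestTraining:
    def _separable_table(self, n=400, seed=0):
        spec = synthetic.TableSpec(
            n_per_class={"N": n // 4, "AF": n // 4, "O": n // 4, "X": n // 4},
            n_features=8,
            informative_features={0: {"N": 5.0}, 1: {"AF": 5.0},
                                  2: {"O": 5.0}, 3: {"X": 5.0}},
            noise_sd=1.0, seed=seed)
        return synthetic.generate_feature_table(spec)

    def test_separable_data_learned(self):
        X, y = self._separable_table()
        model, hist = train(X, y, Topology(8, (16, 8)),
                            TrainingConfig(seed=1, max_epochs=200, batch_size=64))
        pred, _ = predict(model, X)
        assert (pred == y).mean() >= 0.99
        assert len(hist) <= 200

    def test_same_seed_identical_weights(self):
        X, y = self._separable_table(n=200, seed=5)
        cfg = TrainingConfig(seed=7, max_epochs=15)
        topo = Topology(8, (8,))
        m1, _ = train(X, y, topo, cfg)
        m2, _ = train(X, y, topo, cfg)
        for a, b in zip(m1.dense.W, m2.dense.W):
            assert np.array_equal(a, b)
        assert np.array_equal(m1.bn.gamma, m2.bn.gamma)

    def test_early_stopping_within_patience_of_best(self):
        X, y = self._separable_table(n=200, seed=6)
        cfg = TrainingConfig(seed=2, max_epochs=500, patience=10)
        model, hist = train(X, y, Topology(8, (8,)), cfg)
        best_epoch = model.meta["best_epoch"]
        assert len(hist) <= best_epoch + cfg.patience + 1

    def test_single_class_rejected(self):
        X = np.zeros((10, 4))
        with pytest.raises(InvalidSpecError):
            train(X, ["N"] * 10, Topology(4, (4,)), TrainingConfig())

    def test_one_small_step_reduces_loss(self):
        """A single tiny-learning-rate Adam step goes downhill."""
        X, y = self._separable_table(n=80, seed=8)
        topo = Topology(8, (6,))
        cfg = TrainingConfig(seed=3, max_epochs=1, batch_size=80,
                             learning_rate=1e-4, dropout_rate=0.0, patience=0)
        model, hist = train(X, y, topo, cfg)
        from densecg.net import _init_model
        m0 = _init_model(topo, cfg, np.random.default_rng(cfg.seed))
        res0 = forward(m0, X, mode="train")
        l0 = loss(res0.probs, y, cfg.class_weights)
        res1 = forward(model, X, mode="train")
        l1 = loss(res1.probs, y, cfg.class_weights)
        assert l1 < l0


class TestPredictAndPersistence:
    def test_argmax_and_tie_rule(self):
        m = synthetic.fixture_network([4, 4], "explicit",
                                      weights=[np.zeros((4, 4))])
        labels, probs = predict(m, np.eye(4))
        assert np.allclose(probs, 0.25)
        assert list(labels) == ["N"] * 4  # exact tie -> lowest class index

    def test_batch_prediction_shape(self):
        m = synthetic.fixture_network([3, 5, 4], "indexed")
        labels, probs = predict(m, np.random.default_rng(0).normal(size=(9, 3)))
        assert len(labels) == 9 and probs.shape == (9, 4)

    def test_save_load_round_trip(self, tmp_path):
        m = synthetic.fixture_network([6, 5, 4], "indexed")
        m.meta["note"] = "fixture"
        path = tmp_path / "model.h5"
        save_model(m, path)
        m2 = load_model(path)
        x = np.linspace(-1, 1, 6)
        assert np.array_equal(forward(m, x).probs, forward(m2, x).probs)
        assert m2.meta["note"] == "fixture"

    def test_corrupt_container_rejected(self, tmp_path):
        p = tmp_path / "junk.h5"
        p.write_bytes(b"not hdf5 at all")
        with pytest.raises(FormatError):
            load_model(p)
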