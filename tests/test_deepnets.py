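"""Denoising autoencoders, the stack, RBM, and the deep baselines."""

import numpy as np
import pytest

from emosda import deepnets as dn


class TestCorruption:
    def test_exact_zero_count(self):
        x = np.arange(1, 3841, dtype=float)
        out = dn.corrupt_input(x, 0.2, seed=0)
        assert int(np.sum(out == 0)) == round(0.2 * 3840) == 768

    def test_identity_and_full(self):
        x = np.arange(1, 11, dtype=float)
        assert np.array_equal(dn.corrupt_input(x, 0.0, 1), x)
        assert not dn.corrupt_input(x, 1.0, 1).any()

    def test_uncorrupted_coordinates_preserved(self, rng):
        x = rng.normal(size=100) + 10.0
        out = dn.corrupt_input(x, 0.3, seed=7)
        kept = out != 0
        assert np.array_equal(out[kept], x[kept])

    def test_invalid_q_rejected(self):
        with pytest.raises(ValueError):
            dn.corrupt_input(np.ones(5), 1.5, 0)


class TestDAELayer:
    def test_identity_representable(self, rng):
        """With code dim = input dim, no corruption and a linear encoder,
        training drives the reconstruction error far below the variance."""
        X = rng.normal(size=(256, 20))
        layer = dn.DAELayer.create(20, 20, corruption=0.0, seed=0,
                                   encoder_activation="identity")
        dn.dae_pretrain_layer(layer, X, epochs=200, seed=0, lr=1e-2)
        assert layer.loss_trace[-1] < 1e-3 * X.var()

    def test_deterministic_training(self, rng):
        X = rng.normal(size=(128, 16))
        l1 = dn.DAELayer.create(16, 8, seed=1)
        l2 = dn.DAELayer.create(16, 8, seed=1)
        dn.dae_pretrain_layer(l1, X, epochs=5, seed=2)
        dn.dae_pretrain_layer(l2, X, epochs=5, seed=2)
        assert l1.loss_trace == l2.loss_trace
        assert np.array_equal(l1.W, l2.W)

    def test_loss_trace_decreases_smoothed(self, rng):
        X = rng.normal(size=(256, 32))
        layer = dn.DAELayer.create(32, 16, seed=0)
        dn.dae_pretrain_layer(layer, X, epochs=60, seed=0)
        t = np.array(layer.loss_trace)
        smooth = np.convolve(t, np.ones(10) / 10, mode="valid")
        assert smooth[-1] < smooth[0]
        assert np.all(np.diff(smooth) < 0.01)   # no sustained increase

    def test_dimension_mismatch_rejected(self, rng):
        layer = dn.DAELayer.create(16, 8)
        with pytest.raises(ValueError):
            dn.dae_pretrain_layer(layer, rng.normal(size=(10, 7)))


class TestSDAStack:
    def test_single_layer_reduces_to_dae(self, rng):
        X = rng.normal(size=(128, 16))
        stack = dn.SDAStack.create((16, 8), seed=3)
        lone = dn.DAELayer.create(16, 8, seed=int(
            np.random.default_rng(3).integers(2 ** 31)))
        dn.sda_pretrain(stack, X, epochs_per_layer=5, seed=4)
        dn.dae_pretrain_layer(lone, X, epochs=5,
                              seed=int(np.random.default_rng(4).integers(2 ** 31)))
        assert np.array_equal(stack.layers[0].W, lone.W)

    def test_code_dimension(self, rng):
        X = rng.normal(size=(64, 32))
        stack = dn.SDAStack.create((32, 16, 8), seed=0)
        dn.sda_pretrain(stack, X, epochs_per_layer=2, seed=0)
        assert stack.encode(X).shape == (64, 8)

    def test_pretraining_lowers_initial_reconstruction_error(self, rng):
        """The greedy unsupervised stage must start fine-tuning at a
        strictly lower reconstruction error than random initialization."""
        X = rng.normal(size=(300, 64))
        X[:, :8] += rng.normal(size=(300, 1))   # correlated structure
        pre = dn.SDAStack.create((64, 32, 16), seed=5)
        rand = dn.SDAStack.create((64, 32, 16), seed=5)
        dn.sda_pretrain(pre, X, epochs_per_layer=20, seed=5)
        assert pre.reconstruction_error(X) < rand.reconstruction_error(X)

    def test_encode_before_training_rejected(self, rng):
        stack = dn.SDAStack.create((16, 8), seed=0)
        with pytest.raises(dn.UntrainedStackError):
            dn.encode_features(stack, rng.normal(size=(4, 16)))

    def test_encode_features_shape_and_determinism(self, rng):
        X = rng.normal(size=(64, 32))
        stack = dn.SDAStack.create((32, 8), seed=0)
        dn.sda_pretrain(stack, X, epochs_per_layer=2, seed=0)
        t1 = dn.encode_features(stack, X)
        t2 = dn.encode_features(stack, X)
        assert t1.n_features == 8
        assert np.array_equal(t1.values, t2.values)


class TestFineTune:
    def test_plain_cross_entropy_when_unregularized(self, rng):
        """With all regularizers off, the loss on a hand-checked batch is
        the mean negative log-probability of the true classes."""
        stack = dn.SDAStack.create((4, 3), seed=0)
        X = rng.normal(size=(4, 4))
        y = np.array([0, 1, 1, 0])
        spec = dn.LossSpec(lam0=1.0, lam1=0.0, lam2=0.0, lam3=0.0)
        p = stack.predict_proba(X)
        hand = -np.mean(np.log(p[np.arange(4), y] + 1e-12))
        assert dn.sda_loss(stack, X, y, spec) == pytest.approx(hand)

    def test_cost_term_zero_when_all_correct(self):
        stack = dn.SDAStack.create((2, 2), seed=0)
        # rig the head so predictions are always correct
        stack.layers[0].W = np.eye(2) * 5
        stack.layers[0].b = np.zeros(2)
        stack.W_out = np.array([[10.0, -10.0], [-10.0, 10.0]])
        stack.b_out = np.zeros(2)
        X = np.array([[3.0, -3.0], [-3.0, 3.0]])
        y = np.array([0, 1])
        only_cost = dn.LossSpec(lam0=0.0, lam1=0.0, lam2=0.0, lam3=1.0)
        assert dn.sda_loss(stack, X, y, only_cost) == 0.0

    def test_separable_data_high_heldout_accuracy(self, rng):
        X = rng.normal(size=(400, 32))
        y = rng.integers(0, 2, 400)
        X[y == 1, :8] += 2.0
        stack = dn.SDAStack.create((32, 16, 8), seed=0)
        dn.sda_pretrain(stack, X[:300], epochs_per_layer=20, seed=0)
        dn.fine_tune(stack, X[:300], y[:300], epochs=40, seed=0)
        assert np.mean(stack.predict(X[300:]) == y[300:]) > 0.9

    def test_misaligned_labels_rejected(self, rng):
        stack = dn.SDAStack.create((8, 4), seed=0)
        with pytest.raises(ValueError):
            dn.fine_tune(stack, rng.normal(size=(10, 8)), np.zeros(9))

    def test_reproducible_pipeline(self, rng):
        X = rng.normal(size=(100, 16))
        y = rng.integers(0, 2, 100)
        outs = []
        for _ in range(2):
            stack = dn.SDAStack.create((16, 8), seed=7)
            dn.sda_pretrain(stack, X, epochs_per_layer=3, seed=7)
            dn.fine_tune(stack, X, y, epochs=3, seed=7)
            outs.append(stack.predict_proba(X))
        assert np.array_equal(outs[0], outs[1])


class TestAutoencoderFineTune:
    def test_trace_starts_at_initial_error_and_improves(self, rng):
        X = rng.normal(size=(200, 32))
        X[:, :4] += rng.normal(size=(200, 1)) * 2
        stack = dn.SDAStack.create((32, 16), seed=0)
        e0 = stack.reconstruction_error(X)
        trace = dn.sda_autoencoder_finetune(stack, X, epochs=30, seed=0)
        assert trace[0] == pytest.approx(e0)
        assert trace[-1] < trace[0]


class TestRBM:
    def test_zero_weights_hidden_prob_is_sigmoid_bias(self):
        rbm = dn.RBMLayer.create(6, 3, seed=0)
        rbm.W[:] = 0.0
        rbm.b[:] = np.array([0.5, -1.0, 0.0])
        v = np.ones((2, 6))
        expected = 1.0 / (1.0 + np.exp(-rbm.b))
        assert np.allclose(rbm.hidden_prob(v), expected)

    def test_energy_matches_hand_evaluation(self):
        rbm = dn.RBMLayer.create(3, 2, seed=1)
        rbm.W = np.array([[0.1, -0.2], [0.3, 0.0], [-0.1, 0.4]])
        rbm.b = np.array([0.2, -0.3])
        rbm.c = np.array([0.0, 0.1, -0.2])
        v = np.array([1.0, 0.0, 1.0])
        h = np.array([1.0, 1.0])
        hand = -(1 * 0.1 * 1 + 1 * (-0.2) * 1 + 1 * (-0.1) * 1 + 1 * 0.4 * 1) \
            - (0.2 + -0.3) - (0.0 + -0.2)
        assert rbm.energy(v, h) == pytest.approx(hand)

    def test_reconstruction_error_decreases(self, rng):
        X = (rng.random((200, 12)) < 0.3).astype(float)
        X[:, :4] = X[:, 4:8]          # learnable correlation
        rbm = dn.RBMLayer.create(12, 6, seed=0)
        errs = []
        for epoch in range(50):
            dn.rbm_cd_update(rbm, X, lr=0.1, seed=epoch)
            errs.append(dn.rbm_reconstruction_error(rbm, X))
        smooth = np.convolve(errs, np.ones(10) / 10, mode="valid")
        assert smooth[-1] < smooth[0]


class TestDBN:
    def test_pretrain_and_classify_separable(self, rng):
        """A small deep-belief stack with a logistic head learns a strong
        mean shift well above chance."""
        n = 300
        y = rng.integers(0, 2, n)
        X = rng.normal(size=(n, 24))
        X[y == 1, :6] += 2.0
        dbn = dn.DBN.create((24, 12, 6), seed=0)
        dbn.pretrain(X[:200], epochs_per_layer=10, seed=0)
        dbn.fit_head(X[:200], y[:200], epochs=200)
        assert np.mean(dbn.predict(X[200:]) == y[200:]) > 0.8

    def test_predict_before_head_rejected(self, rng):
        dbn = dn.DBN.create((8, 4), seed=0)
        with pytest.raises(dn.UntrainedStackError):
            dbn.predict(rng.normal(size=(3, 8)))


class TestBaselines:
    def test_dnn_architecture(self):
        m = dn.build_baseline("dnn", 3840, seed=0)
        assert m.layer_widths == (3840, 800, 200, 20, 2)
        with pytest.raises(ValueError):
            dn.build_baseline("dnn", 1000)

    def test_cnn_accepts_60x64_image(self, rng):
        m = dn.build_baseline("cnn", 3840, seed=0)
        p = m.predict_proba(rng.normal(size=(4, 3840)))
        assert p.shape == (4, 2)
        assert np.allclose(p.sum(axis=1), 1.0)

    def test_baselines_beat_chance_on_separable_data(self, rng):
        """Both reference nets learn a strong class shift well above the
        0.5 chance level."""
        n = 300
        y = rng.integers(0, 2, n)
        X = rng.normal(size=(n, 3840))
        X[y == 1, 500:700] += 1.5
        Xte = rng.normal(size=(100, 3840))
        yte = rng.integers(0, 2, 100)
        Xte[yte == 1, 500:700] += 1.5
        for name, epochs in (("dnn", 8), ("cnn", 8)):
            m = dn.build_baseline(name, 3840, seed=0)
            m.fit(X, y, epochs=epochs)
            assert np.mean(m.predict(Xte) == yte) > 0.6, name
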