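"""Classifier architecture, training behaviour, and cross-validation."""

import copy

import numpy as np
import pytest
from scipy.special import erf

from mmgdecode.model import FoldResult, MovementDecoder
from mmgdecode.nn import ModelConfig, ResidualConv1DNet, gelu


class TestGelu:
    def test_zero(self):
        assert gelu(np.array(0.0)) == 0.0

    def test_saturation(self):
        assert gelu(np.array(10.0)) == pytest.approx(10.0, abs=1e-6)

    def test_negative_value_against_erf_oracle(self):
        phi = 0.5 * (1.0 + erf(-1.0 / np.sqrt(2.0)))
        assert gelu(np.array(-1.0)) == pytest.approx(-phi)
        assert gelu(np.array(-1.0)) == pytest.approx(-0.1587, abs=1e-4)


class TestArchitecture:
    def test_output_probabilities(self):
        net = ResidualConv1DNet(ModelConfig(T=20, C=8, seed=0))
        x = np.random.default_rng(0).standard_normal((5, 20, 8))
        probs = net.predict_proba(x)
        assert probs.shape == (5, 3)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(probs >= 0) and np.all(probs <= 1)

    def test_residual_block_preserves_shape(self):
        net = ResidualConv1DNet(ModelConfig(T=20, C=8, seed=0))
        x = np.random.default_rng(1).standard_normal((3, 20, 8))
        _, cache = net.forward(x)
        assert cache["r"].shape == x.shape  # residual add requires equal shapes

    def test_residual_identity_with_zeroed_convolutions(self):
        net = ResidualConv1DNet(ModelConfig(T=20, C=4, dropout=0.0, seed=0))
        net.params["W1"][:] = 0.0
        net.params["W2"][:] = 0.0
        x = np.random.default_rng(2).standard_normal((4, 20, 4)).astype(np.float32)
        _, cache = net.forward(x, training=False)
        # both conv paths vanish; the block reduces to GELU(input)
        assert np.allclose(cache["r"], x, atol=1e-6)

    def test_parameter_count_matches_layer_sum(self):
        T, C, R, H, Z, F = 20, 8, 128, 16, 100, 3
        t_out = -(-T // 2)
        flat = t_out * H
        expected = (
            C * R          # pointwise conv, no bias
            + 2 * R        # BN gamma/beta
            + 3 * R * C    # kernel-3 conv, no bias
            + 2 * C        # BN
            + 3 * C * H + H  # strided conv with bias
            + flat * Z + Z   # FC1
            + Z * Z + Z      # FC2
            + Z * F + F      # output FC
        )
        net = ResidualConv1DNet(ModelConfig(T=T, C=C))
        assert net.n_parameters == expected

    def test_window_shorter_than_kernel_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(T=2, C=4)


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        cfg = ModelConfig(
            T=8, C=3, residual_filters=7, head_filters=4, fc_units=5,
            dropout=0.0, dtype="float64", seed=1,
        )
        net = ResidualConv1DNet(cfg)
        rng = np.random.default_rng(0)
        X = rng.standard_normal((4, 8, 3))
        y = np.array([0, 1, 2, 1])
        onehot = np.eye(3)[y]
        run0 = copy.deepcopy(net.running)
        probs, cache = net.forward(X, training=True, rng=np.random.default_rng(0))
        _, grads = net.backward(cache, (probs - onehot) / 4, param_grads=True)
        net.running = copy.deepcopy(run0)

        def loss():
            net.running = copy.deepcopy(run0)
            p, _ = net.forward(X, training=True, rng=np.random.default_rng(0))
            return -np.mean(np.sum(onehot * np.log(p + 1e-12), axis=1))

        eps = 1e-6
        rng2 = np.random.default_rng(5)
        for name, P in net.params.items():
            flat_idx = rng2.choice(P.size, size=min(8, P.size), replace=False)
            for fi in flat_idx:
                idx = np.unravel_index(fi, P.shape)
                orig = P[idx]
                P[idx] = orig + eps
                lp = loss()
                P[idx] = orig - eps
                lm = loss()
                P[idx] = orig
                num = (lp - lm) / (2 * eps)
                assert grads[name][idx] == pytest.approx(num, rel=1e-4, abs=1e-8), name

    def test_input_gradients_match_finite_differences(self):
        cfg = ModelConfig(
            T=6, C=2, residual_filters=5, head_filters=3, fc_units=4,
            dropout=0.0, dtype="float64", seed=2,
        )
        net = ResidualConv1DNet(cfg)
        rng = np.random.default_rng(1)
        X = rng.standard_normal((3, 6, 2))
        y = np.array([0, 2, 1])
        dx = net.input_gradients(X, y)
        eps = 1e-6
        for idx in [(0, 0, 0), (1, 3, 1), (2, 5, 0)]:
            orig = X[idx]
            X[idx] = orig + eps
            lp = net.sample_losses(X, y)[idx[0]]
            X[idx] = orig - eps
            lm = net.sample_losses(X, y)[idx[0]]
            X[idx] = orig
            assert dx[idx] == pytest.approx((lp - lm) / (2 * eps), rel=1e-5, abs=1e-9)


class TestTraining:
    def _separable_data(self, n=300, T=20, C=4, seed=0):
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 3, n)
        X = rng.standard_normal((n, T, C)) * 0.3
        for i in range(n):
            X[i, :, y[i] % C] += 2.0  # class-coded channel offset
        return X, y

    def test_capacity_on_separable_data(self):
        X, y = self._separable_data()
        net = ResidualConv1DNet(ModelConfig(T=20, C=4, seed=0))
        net.fit(X, y, epochs=30, seed=0)
        assert np.mean(net.predict(X) == y) >= 0.99

    def test_loss_curve_recorded_and_finite(self):
        X, y = self._separable_data(n=120)
        net = ResidualConv1DNet(ModelConfig(T=20, C=4, seed=1))
        net.fit(X, y, epochs=12, seed=1)
        assert net.loss_curve.shape == (12,)
        assert np.all(np.isfinite(net.loss_curve))
        assert net.loss_curve[-1] < net.loss_curve[0]

    def test_seed_determinism(self):
        X, y = self._separable_data(n=150)
        curves = []
        for _ in range(2):
            net = ResidualConv1DNet(ModelConfig(T=20, C=4, seed=3))
            net.fit(X, y, epochs=5, seed=4)
            curves.append(net.loss_curve.copy())
        assert np.array_equal(curves[0], curves[1])

    def test_inference_determinism(self):
        X, y = self._separable_data(n=100)
        net = ResidualConv1DNet(ModelConfig(T=20, C=4, seed=0))
        net.fit(X, y, epochs=3, seed=0)
        p1, p2 = net.predict_proba(X), net.predict_proba(X)
        assert np.array_equal(p1, p2)
        assert np.array_equal(p1.argmax(axis=1), net.predict(X))

    def test_nonfinite_loss_aborts(self):
        X, y = self._separable_data(n=60)
        X[0, 0, 0] = np.inf
        net = ResidualConv1DNet(ModelConfig(T=20, C=4, seed=0))
        with pytest.raises(RuntimeError, match="diverged"):
            net.fit(X, y, epochs=1, seed=0)


class TestFoldResult:
    def test_probability_validation(self):
        with pytest.raises(ValueError, match="sum to 1"):
            FoldResult(
                fold=0, y_true=np.array([0]), y_pred=np.array([0]),
                proba=np.array([[0.5, 0.2, 0.2]]), accuracy=1.0,
            )


class TestMovementDecoder:
    def test_fit_small_experiment(self, small_envs):
        env_sets, events = small_envs
        dec = MovementDecoder(env_sets["EMG"], events)
        res = dec.fit(k=5, seed=0, n_train=40, n_test=20, epochs=10)
        assert len(res.fold_results) == 5
        # 20 test windows per class per fold -> confusion rows sum to 100
        cm = res.confusion_matrix()
        assert np.all(cm.sum(axis=1) == 100)
        assert 0.0 <= res.mean_accuracy <= 1.0
        # high-SNR EMG should already decode well above chance at 10 epochs
        assert res.mean_accuracy > 0.6
        assert "mean accuracy" in res.summary()

    def test_modalities_must_not_mix(self, small_envs):
        env_sets, events = small_envs
        with pytest.raises(ValueError, match="modality"):
            MovementDecoder(env_sets["EMG"] + env_sets["MMG"], events + events)


class TestCheckpoint:
    def test_save_load_roundtrip(self, tmp_path):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((90, 20, 4))
        y = rng.integers(0, 3, 90)
        net = ResidualConv1DNet(ModelConfig(T=20, C=4, seed=0))
        net.fit(X, y, epochs=3, seed=0)
        path = tmp_path / "model.npz"
        net.save(path)
        back = ResidualConv1DNet.load(path)
        assert back.cfg == net.cfg
        assert np.array_equal(back.predict_proba(X), net.predict_proba(X))
        assert np.array_equal(back.loss_curve, net.loss_curve)
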