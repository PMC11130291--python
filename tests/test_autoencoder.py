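"""Autoencoder architecture, loss functions, and training behavior."""

import numpy as np
import pytest

from msilowsig.autoencoder import (
    AEConfig,
    adjusted_mae,
    build_model,
    encode,
    kl_divergence,
    supervised_error,
    train,
)


class TestArchitecture:
    def test_default_config_latent_shape(self):
        model = build_model(AEConfig(n_features=20, patch_size=3, hidden=16, latent=64))
        x = np.random.default_rng(0).uniform(0, 1, (2, 3, 3, 20))
        assert encode(model, x).shape == (2, 2, 2, 64)

    def test_patch5_kernel4_latent_shape(self):
        model = build_model(
            AEConfig(n_features=20, patch_size=5, kernel2=4, hidden=16, latent=64)
        )
        x = np.random.default_rng(0).uniform(0, 1, (2, 5, 5, 20))
        assert encode(model, x).shape == (2, 2, 2, 64)

    def test_kernel_equal_to_patch_rejected(self):
        with pytest.raises(ValueError):
            AEConfig(n_features=20, patch_size=3, kernel2=3)

    def test_decoder_roundtrips_shape(self):
        cfg = AEConfig(n_features=11, hidden=8, latent=4)
        model = build_model(cfg)
        x = np.random.default_rng(1).uniform(0, 1, (3, 3, 3, 11))
        code = model.encoder.forward(x, training=False)
        rec = model.decoder.forward(code, training=False)
        assert rec.shape == x.shape

    def test_encode_is_deterministic_and_batch_independent(self):
        model = build_model(AEConfig(n_features=6, hidden=8, latent=4, seed=3))
        x = np.random.default_rng(2).uniform(0, 1, (5, 3, 3, 6))
        a = encode(model, x)
        b = encode(model, x)
        singles = np.concatenate([encode(model, x[i : i + 1]) for i in range(5)])
        assert np.array_equal(a, b)
        assert np.allclose(a, singles)


class TestAdjustedMae:
    def test_zero_for_exact_reconstruction(self):
        x = np.random.default_rng(0).uniform(0, 1, (4, 3, 3, 5))
        assert adjusted_mae(x, x) == 0.0

    def test_hand_summed_example(self):
        # two single-pixel patches with per-feature abs diffs {0.1, 0.3} and
        # {0.1, 0.1}: mean over patches of the per-patch sums = 0.3
        x = np.zeros((2, 1, 1, 2))
        xhat = np.array([[[[0.1, 0.3]]], [[[0.1, 0.1]]]])
        assert adjusted_mae(x, xhat) == pytest.approx(0.3)

    def test_equals_elementwise_mae_times_pixels_and_features(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            shape = (rng.integers(1, 5), 3, 3, rng.integers(1, 8))
            x = rng.uniform(0, 1, shape)
            xhat = rng.uniform(0, 1, shape)
            scale = shape[1] * shape[2] * shape[3]
            assert adjusted_mae(x, xhat) == pytest.approx(
                np.abs(x - xhat).mean() * scale, abs=1e-10
            )

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            adjusted_mae(np.zeros((1, 3, 3, 2)), np.zeros((1, 3, 3, 3)))


class TestSupervisedError:
    def test_no_selected_pixels_gives_zero(self):
        x = np.random.default_rng(0).uniform(0, 1, (2, 3, 3, 4))
        ann = np.full((2, 3, 3), 0.5)
        assert supervised_error(x, x + 1, ann, threshold=0.6) == 0.0

    def test_selection_and_mean(self):
        # pixels with annotations {0.5, 0.9}; only the second is selected,
        # its per-pixel feature sum is 0.4
        x = np.zeros((1, 1, 2, 2))
        xhat = np.array([[[[0.5, 0.5], [0.1, 0.3]]]])
        ann = np.array([[[0.5, 0.9]]])
        assert supervised_error(x, xhat, ann, threshold=0.6) == pytest.approx(0.4)

    def test_threshold_zero_equals_mean_of_pixel_sums(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 1, (3, 3, 3, 4))
        xhat = rng.uniform(0, 1, (3, 3, 3, 4))
        ann = rng.uniform(0.01, 1, (3, 3, 3))
        expected = np.abs(x - xhat).sum(axis=-1).mean()
        assert supervised_error(x, xhat, ann, threshold=0.0) == pytest.approx(expected)


class TestKlDivergence:
    def test_standard_gaussian_is_zero(self):
        assert kl_divergence(np.zeros(5), np.zeros(5)) == pytest.approx(0.0)

    def test_unit_mean_closed_form(self):
        assert kl_divergence(np.array([1.0]), np.array([0.0])) == pytest.approx(0.5)

    def test_logvar_one_closed_form(self):
        expected = -0.5 * (2.0 - np.e)
        assert kl_divergence(np.array([0.0]), np.array([1.0])) == pytest.approx(expected)

    def test_nonnegative_on_random_inputs(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            mu = rng.normal(0, 2, rng.integers(1, 10))
            logvar = rng.normal(0, 1, mu.shape)
            assert kl_divergence(mu, logvar) >= 0.0


def _toy_patches(n=48, p=3, f=6, seed=0):
    rng = np.random.default_rng(seed)
    base = rng.uniform(0, 1, (n, 1, 1, f))
    return np.clip(np.repeat(np.repeat(base, p, 1), p, 2)
                   + rng.normal(0, 0.05, (n, p, p, f)), 0, 1)


class TestTraining:
    def test_loss_decreases_on_toy_data(self):
        x = _toy_patches()
        cfg = AEConfig(n_features=6, hidden=16, latent=3, epochs=25,
                       learning_rate=1e-3 / 2, seed=0)
        model = train(build_model(cfg), x)
        log = model.training_log
        assert log[-1]["train_loss"] < log[0]["train_loss"]

    def test_same_seed_identical_final_losses(self):
        x = _toy_patches()
        cfg = AEConfig(n_features=6, hidden=8, latent=3, epochs=3, seed=5)
        a = train(build_model(cfg), x)
        b = train(build_model(cfg), x)
        assert a.training_log[-1]["train_loss"] == b.training_log[-1]["train_loss"]

    def test_semisupervised_without_hypoxia_equals_unsupervised(self):
        x = _toy_patches(n=32)
        ann = np.full((32, 3, 3), 0.3)  # nothing above the 0.6 threshold
        semi_cfg = AEConfig(n_features=6, hidden=8, latent=3, epochs=3,
                            mode="semisupervised", seed=2)
        unsup_cfg = AEConfig(n_features=6, hidden=8, latent=3, epochs=3,
                             mode="unsupervised", seed=2)
        semi = train(build_model(semi_cfg), x, annotations=ann)
        unsup = train(build_model(unsup_cfg), x)
        assert semi.training_log[-1]["train_loss"] == pytest.approx(
            unsup.training_log[-1]["train_loss"]
        )

    def test_semisupervised_requires_annotations(self):
        cfg = AEConfig(n_features=6, hidden=8, latent=3, mode="semisupervised")
        with pytest.raises(ValueError):
            train(build_model(cfg), _toy_patches(8))

    def test_high_learning_rate_warns(self):
        cfg = AEConfig(n_features=6, hidden=8, latent=3, epochs=1,
                       learning_rate=1e-3, seed=0)
        with pytest.warns(UserWarning, match="learning rate"):
            train(build_model(cfg), _toy_patches(16))

    def test_variational_trains_and_encodes_mean(self):
        x = _toy_patches(n=32)
        cfg = AEConfig(n_features=6, hidden=8, latent=3, epochs=3,
                       mode="variational", seed=1)
        model = train(build_model(cfg), x)
        assert "train_kl" in model.training_log[-1]
        z = encode(model, x)  # mean vector: deterministic
        assert np.array_equal(z, encode(model, x))


class TestGradients:
    def test_backprop_matches_numerical_gradients(self):
        """Analytic gradients of the full loss agree with finite differences
        (away from BN-invariant bias directions and ReLU/MAE kinks)."""
        from msilowsig.autoencoder import _forward_backward

        rng = np.random.default_rng(0)
        cfg = AEConfig(n_features=5, patch_size=3, hidden=7, latent=4, seed=1)
        model = build_model(cfg)
        x = rng.uniform(0, 1, (6, 3, 3, 5))
        _forward_backward(model, x, None, np.random.default_rng(9))
        params = model.params
        grads = [g.copy() for g in model.grads]
        # check weight matrices only: conv biases feeding a BatchNorm are
        # exactly loss-invariant, so both gradients are ~0 there
        targets = [model.encoder.layers[0].w, model.encoder.layers[3].w,
                   model.decoder.layers[0].w, model.decoder.layers[3].w]
        rng2 = np.random.default_rng(1)
        for p in targets:
            gi = next(i for i, q in enumerate(params) if q is p)
            for _ in range(4):
                idx = tuple(rng2.integers(0, s) for s in p.shape)
                eps = 1e-6
                orig = p[idx]
                p[idx] = orig + eps
                lp = _forward_backward(model, x, None, np.random.default_rng(9))["total"]
                p[idx] = orig - eps
                lm = _forward_backward(model, x, None, np.random.default_rng(9))["total"]
                p[idx] = orig
                num = (lp - lm) / (2 * eps)
                assert num == pytest.approx(grads[gi][idx], rel=1e-4, abs=1e-7)
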