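import dataclasses
import warnings

import numpy as np
import pytest

import vplotvae as vv
from vplotvae import cvae as cv


def _tiny_config(**kw):
    base = dict(S=1, K=3, W=32, H=32, epochs=3, batch_size=16,
                warmup_steps=5, seed=11)
    base.update(kw)
    return cv.ModelConfig(**base)


def _random_stack(n, s, w, h, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.random((n, s, w, h))
    return cv.VPlotStack(x=x / x.sum(axis=3, keepdims=True))


class TestInitModel:
    def test_bottleneck_spatial_size(self):
        model = cv.init_model(cv.ModelConfig(S=1))
        assert (model._wb, model._hb) == (8, 4)

    def test_same_seed_identical_checksums(self):
        cfg = _tiny_config()
        assert cv.init_model(cfg).checksum() == cv.init_model(cfg).checksum()

    def test_posterior_mean_shape_is_k_by_s(self):
        model = cv.init_model(cv.ModelConfig(S=3, K=5))
        stack = _random_stack(4, 3, 128, 64)
        post = cv.encode(stack, model)
        assert post.mean.shape == (4, 5, 3)

    def test_indivisible_width_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            cv.ModelConfig(S=1, W=100)


class TestEncode:
    def test_deterministic_and_positive_sigma(self):
        model = cv.init_model(_tiny_config())
        stack = _random_stack(5, 1, 32, 32)
        p1, p2 = cv.encode(stack, model), cv.encode(stack, model)
        assert np.array_equal(p1.mean, p2.mean)
        assert np.all(p1.std > 0)

    def test_shape_mismatch_raises(self):
        model = cv.init_model(_tiny_config())
        with pytest.raises(ValueError, match="match"):
            cv.encode(_random_stack(3, 2, 32, 32), model)

    def test_shared_sigma_broadcasts(self):
        model = cv.init_model(_tiny_config(S=2, shared_sigma=True))
        post = cv.encode(_random_stack(3, 2, 32, 32), model)
        assert post.std.shape == (3, 3, 1)
        m, s = post.sample_slice(1)
        assert s.shape == m.shape

    def test_channel_relabeling_equivariance(self):
        """Swapping the two samples' channels together with the conv input
        weights, the embedding rows, and the decoder one-hot weights is a
        pure relabeling: posteriors swap accordingly."""
        cfg = _tiny_config(S=2, K=2)
        model = cv.init_model(cfg)
        stack = _random_stack(4, 2, 32, 32, seed=3)
        post = cv.encode(stack, model)
        # relabel sample 0 <-> 1 everywhere
        model2 = cv.init_model(cfg)
        conv1 = model2.encoder.layers[0]
        w = conv1.w.reshape(conv1.w.shape[0], 2, 9)
        w[:, [0, 1]] = w[:, [1, 0]]
        model2.embedding[[0, 1]] = model2.embedding[[1, 0]]
        # head_mu groups output as (K, S): swap the S columns
        hm = model2.head_mu.w.reshape(-1, cfg.K, 2)
        hm[:, :, [0, 1]] = hm[:, :, [1, 0]]
        model2.head_mu.b.reshape(cfg.K, 2)[:, [0, 1]] = \
            model2.head_mu.b.reshape(cfg.K, 2)[:, [1, 0]]
        hv = model2.head_logvar.w.reshape(-1, cfg.K, 2)
        hv[:, :, [0, 1]] = hv[:, :, [1, 0]]
        model2.head_logvar.b.reshape(cfg.K, 2)[:, [0, 1]] = \
            model2.head_logvar.b.reshape(cfg.K, 2)[:, [1, 0]]
        stack2 = cv.VPlotStack(x=stack.x[:, ::-1])
        post2 = cv.encode(stack2, model2)
        assert np.allclose(post2.mean, post.mean[:, :, ::-1], atol=1e-5)


class TestDecode:
    def test_columns_sum_to_one_over_prior_draws(self):
        model = cv.init_model(_tiny_config())
        rng = np.random.default_rng(1)
        z = rng.standard_normal((100, 3))
        xhat = cv.decode(z, 0, model)
        assert np.allclose(xhat.sum(axis=2), 1.0, atol=1e-5)
        assert np.all((xhat > 0) & (xhat < 1))

    def test_deterministic(self):
        model = cv.init_model(_tiny_config())
        z = np.ones(3)
        assert np.array_equal(cv.decode(z, 0, model), cv.decode(z, 0, model))

    def test_nonfinite_z_rejected(self):
        model = cv.init_model(_tiny_config())
        with pytest.raises(ValueError, match="finite"):
            cv.decode(np.array([np.nan, 0, 0]), 0, model)

    def test_bad_sample_id_rejected(self):
        model = cv.init_model(_tiny_config())
        with pytest.raises(ValueError, match="sample_id"):
            cv.decode(np.zeros(3), 5, model)


class TestElboLoss:
    def test_kl_of_prior_is_zero(self):
        post = cv.LatentPosterior(mean=np.zeros((1, 5, 1)),
                                  std=np.ones((1, 5, 1)))
        assert cv._kl(post.mean, post.std) == 0.0

    def test_kl_unit_mean_closed_form(self):
        post = cv.LatentPosterior(mean=np.ones((1, 1, 1)),
                                  std=np.ones((1, 1, 1)))
        assert cv._kl(post.mean, post.std) == pytest.approx(0.5)

    def test_kl_nonnegative_random(self, rng):
        mean = rng.standard_normal((20, 5, 2))
        std = rng.random((20, 5, 2)) + 0.05
        assert cv._kl(mean, std) >= 0.0

    def test_matching_onehot_bce_near_zero(self):
        x = np.zeros((1, 1, 4, 8))
        x[..., 0] = 1.0
        assert cv._bce(x, x) < 1e-4 * x.size

    def test_elbo_total(self):
        stack = _random_stack(2, 1, 32, 32)
        post = cv.LatentPosterior(mean=np.zeros((2, 3, 1)),
                                  std=np.ones((2, 3, 1)))
        loss = cv.elbo_loss(stack, stack.x.copy(), post)
        assert loss == pytest.approx(cv._bce(stack.x, stack.x) / 2)


class TestTrain:
    def test_loss_decreases_and_history_reproducible(self):
        stack = _random_stack(30, 1, 32, 32, seed=5)
        cfg = _tiny_config(epochs=6)
        m1, h1 = cv.train(stack, cfg)
        m2, h2 = cv.train(stack, cfg)
        assert h1 == h2
        assert m1.checksum() == m2.checksum()
        assert h1[-1] < h1[0]

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            cv.train(cv.VPlotStack(x=np.zeros((0, 1, 32, 32))), _tiny_config())

    def test_stack_sample_mismatch_rejected(self):
        with pytest.raises(ValueError, match="S="):
            cv.train(_random_stack(4, 2, 32, 32), _tiny_config(S=1))

    def test_learning_rate_schedule_peaks_at_configured_rate(self):
        from vplotvae._nn import Adam
        opt = Adam([np.zeros(1)], [np.zeros(1)], lr=0.01, total_steps=200,
                   warmup_steps=50)
        lrs = [opt.learning_rate(t) for t in range(200)]
        assert max(lrs) == pytest.approx(0.01)
        assert np.argmax(lrs) == 49


class TestBatchFree:
    def test_single_sample_equals_reconstruction(self):
        stack = _random_stack(6, 1, 32, 32, seed=2)
        model, _ = cv.train(stack, _tiny_config(epochs=2))
        assert np.array_equal(cv.batch_free_vplot(stack, model),
                              cv.reconstruct(stack, model))

    def test_columns_sum_to_one(self):
        stack = _random_stack(4, 2, 32, 32, seed=2)
        model = cv.init_model(_tiny_config(S=2))
        xhat = cv.batch_free_vplot(stack, model)
        assert np.allclose(xhat.sum(axis=3), 1.0, atol=1e-5)

    def test_invalid_s0_rejected(self):
        with pytest.raises(ValueError, match="s0"):
            cv.ModelConfig(S=2, s0=2)


class TestExtractFeatures:
    def test_flattened_dimension_and_determinism(self):
        model = cv.init_model(cv.ModelConfig(S=2, K=5))
        stack = _random_stack(3, 2, 128, 64)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            feats = cv.extract_features(stack, model)
        assert feats.shape == (3, 10)
        assert not np.any(np.isnan(feats))
        # identical regions -> identical rows
        stack2 = cv.VPlotStack(x=np.repeat(stack.x[:1], 2, axis=0))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f2 = cv.extract_features(stack2, model)
        assert np.array_equal(f2[0], f2[1])

    def test_untrained_model_warns(self):
        model = cv.init_model(_tiny_config())
        with pytest.warns(UserWarning, match="untrained"):
            cv.extract_features(_random_stack(2, 1, 32, 32), model)


def test_checkpoint_roundtrip(tmp_path):
    stack = _random_stack(8, 2, 32, 32, seed=4)
    model, _ = cv.train(stack, _tiny_config(S=2, epochs=2))
    path = tmp_path / "model.h5"
    cv.save_model(model, path)
    back = cv.load_model(path)
    assert back.config == model.config
    p1, p2 = cv.encode(stack, model), cv.encode(stack, back)
    assert np.array_equal(p1.mean, p2.mean)
    assert np.array_equal(p1.std, p2.std)
    assert np.array_equal(cv.batch_free_vplot(stack, model),
                          cv.batch_free_vplot(stack, back))
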