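"""Model-construction contracts, training-loop behavior, and architecture
properties (shared trunks, per-level gradient isolation, determinism)."""

import numpy as np
import pytest

from lesionqr import nn
from lesionqr.models import (
    MultiHeadUNet,
    TrainConfig,
    build_bqr_unet,
    build_conv_vae,
    build_mlp_vae,
    load_params,
    save_params,
    train_bqr_unet,
    train_qrvae,
    train_unet_bce,
    train_vae,
)

SMALL = TrainConfig(
    latent_dim=8,
    epochs=3,
    batch_size=8,
    seed=0,
    image_shape=(1, 16, 16),
    widths=(8, 16, 32),
)


class TestBuildConvVae:
    def test_gaussian_head_shape_contract(self):
        m = build_conv_vae(SMALL, head="gaussian")
        x = np.zeros((2, 1, 16, 16))
        mu, lv = m.encode(x, train=False)
        assert mu.shape == lv.shape == (2, 8)
        outs = m.decode(mu, train=False)
        assert len(outs) == 2
        assert all(o.shape == x.shape for o in outs)

    def test_quantile_head_range_and_count(self):
        m = build_conv_vae(SMALL, head="quantile", levels=(0.15, 0.5))
        x = np.zeros((3, 1, 16, 16))
        mu, _ = m.encode(x, train=False)
        outs = m.decode(mu, train=False)
        assert len(outs) == 2
        for o in outs:
            assert o.shape == x.shape
            assert np.all((o >= 0) & (o <= 1))  # sigmoid range

    def test_shared_trunk_parameter_count(self):
        """Two heads share everything but the final layer, so the two-head
        model is far smaller than two one-head models."""
        two = build_conv_vae(SMALL, head="quantile", levels=(0.15, 0.5)).n_params()
        one = build_conv_vae(SMALL, head="quantile", levels=(0.5,)).n_params()
        assert two < 2 * one
        head_size = two - one  # exactly one extra head layer
        assert head_size == 8 * 3 * 3 * 1 + 1  # conv(8->1, 3x3) weights + bias

    def test_incompatible_shape_rejected_before_training(self):
        with pytest.raises(ValueError):
            build_conv_vae(SMALL.with_(image_shape=(1, 20, 20)))


class TestTrainingLoop:
    def test_loss_decreases_on_synthetic_images(self, image_data):
        imgs, _, _ = image_data
        _, log = train_qrvae(imgs[:16], (0.15, 0.5), SMALL)
        assert log[-1]["recon"] < log[0]["recon"]

    def test_constant_images_recover_constant_mean(self):
        data = np.full((16, 1, 16, 16), 0.63)
        cfg = SMALL.with_(epochs=25, learning_rate=3e-3)
        model, _ = train_vae(data, cfg)
        gf = model.predict_gaussian(data[:4])
        assert float(np.median(gf.mean)) == pytest.approx(0.63, abs=0.05)

    def test_training_log_is_deterministic(self, image_data):
        imgs, _, _ = image_data
        _, log_a = train_qrvae(imgs[:8], (0.5,), SMALL.with_(epochs=2))
        _, log_b = train_qrvae(imgs[:8], (0.5,), SMALL.with_(epochs=2))
        assert log_a == log_b

    def test_log_written_as_jsonl(self, image_data, tmp_path):
        imgs, _, _ = image_data
        path = tmp_path / "log.jsonl"
        _, log = train_qrvae(
            imgs[:8], (0.5,), SMALL.with_(epochs=2), log_path=path
        )
        import json

        lines = [json.loads(line) for line in path.read_text().splitlines()]
        assert lines == log

    def test_reparameterized_latent_is_standard_normal_under_null_encoder(
        self, image_data
    ):
        """With the encoder pinned to (mu=0, logvar=0) the decoder input over
        many steps is a standard normal draw."""
        imgs, _, _ = image_data
        model = build_conv_vae(SMALL, head="quantile", levels=(0.5,))
        zs = []
        true_encode = model.encode
        true_decode = model.decode

        def null_encode(x, train=True):
            mu, lv = true_encode(x, train=train)
            return np.zeros_like(mu), np.zeros_like(lv)

        def spy_decode(z, train=True):
            zs.append(z)
            return true_decode(z, train=train)

        model.encode = null_encode
        model.decode = spy_decode
        train_qrvae(imgs[:16], (0.5,), SMALL.with_(epochs=6), model=model)
        z = np.concatenate([a.ravel() for a in zs])
        assert z.mean() == pytest.approx(0.0, abs=0.1)
        assert z.std() == pytest.approx(1.0, abs=0.1)

    def test_per_level_gradient_isolation(self):
        """Backprop of one level's pinball term leaves the other heads'
        parameters untouched (no inter-level interaction)."""
        model = build_conv_vae(SMALL, head="quantile", levels=(0.15, 0.5, 0.85))
        x = np.random.default_rng(0).uniform(size=(4, 1, 16, 16))
        mu, lv = model.encode(x)
        eps = np.zeros_like(mu)
        outs = model.decode(mu)
        # gradient only through level 1
        gouts = [np.zeros_like(o) for o in outs]
        gouts[1] = np.ones_like(outs[1]) / outs[1].size
        for p in model.params():
            p.grad[...] = 0.0
        model.backward(gouts, np.zeros_like(mu), np.zeros_like(lv), eps, lv)
        assert all(np.all(p.grad == 0) for p in model.heads[0].params())
        assert all(np.all(p.grad == 0) for p in model.heads[2].params())
        assert any(np.any(p.grad != 0) for p in model.heads[1].params())

    def test_checkpoint_roundtrip(self, image_data, tmp_path):
        imgs, _, _ = image_data
        model, _ = train_qrvae(imgs[:8], (0.15, 0.5), SMALL.with_(epochs=2))
        pred = model.predict_quantiles(imgs[:2]).maps
        path = tmp_path / "ckpt.npz"
        save_params(model, path)
        fresh = build_conv_vae(SMALL, head="quantile", levels=(0.15, 0.5))
        load_params(fresh, path)
        np.testing.assert_allclose(fresh.predict_quantiles(imgs[:2]).maps, pred)


class TestMlpVae:
    def test_tabular_heads_unbounded(self):
        cfg = TrainConfig(latent_dim=2, epochs=1, batch_size=16, seed=0)
        m = build_mlp_vae(4, cfg, head="quantile", levels=(0.15, 0.5))
        z = np.random.default_rng(0).standard_normal((5, 2))
        outs = m.decode(z, train=False)
        assert len(outs) == 2 and outs[0].shape == (5, 4)

    def test_sampling_shapes(self):
        cfg = TrainConfig(latent_dim=2, epochs=2, batch_size=32, seed=0)
        rng = np.random.default_rng(1)
        data = rng.normal(size=(64, 4))
        m, _ = train_vae(data, cfg)
        samples = m.sample(100, np.random.default_rng(2))
        assert samples.shape == (100, 4)
        mq, _ = train_qrvae(data, (0.15, 0.5), cfg)
        assert mq.sample(50, np.random.default_rng(3)).shape == (50, 4)


class TestUNet:
    def test_forward_shape_contract(self):
        cfg = TrainConfig(image_shape=(1, 32, 32), seed=0)
        model = build_bqr_unet(cfg, (0.125, 0.375, 0.625, 0.875))
        logits = model.predict_logits(np.zeros((2, 1, 32, 32)))
        assert logits.shape == (4, 2, 32, 32)

    def test_head_only_parameter_difference(self):
        cfg = TrainConfig(image_shape=(1, 32, 32), seed=0)
        four = build_bqr_unet(cfg, (0.125, 0.375, 0.625, 0.875)).n_params()
        one = MultiHeadUNet(1, 1, base=8, seed=0).n_params()
        per_head = 8 + 1  # 1x1 conv weights + bias
        assert four - one == 3 * per_head

    def test_incompatible_shape_rejected(self):
        model = MultiHeadUNet(1, 2, base=4, seed=0)
        with pytest.raises(ValueError):
            model.forward(np.zeros((1, 1, 30, 30)))

    def test_bqr_converges_on_perfect_agreement_raters(self, rater_data):
        """With four identical raters every head's binarized map should
        recover the common lesion mask (Dice > 0.9 at each level)."""
        imgs, masks = rater_data
        levels = (0.125, 0.375, 0.625, 0.875)
        cfg = TrainConfig(
            epochs=30, batch_size=8, seed=0, image_shape=(1, 32, 32),
            learning_rate=3e-3,
        )
        model, log = train_bqr_unet(imgs, masks, levels, cfg, warmup_epochs=8)
        assert not log[-1]["trivial_solution"]
        phases = {e.get("phase") for e in log if "phase" in e}
        assert phases == {"warmup", "bqr"}  # log distinguishes the stages
        bqr_losses = [e["loss"] for e in log if e.get("phase") == "bqr"]
        assert bqr_losses[-1] < bqr_losses[0]
        from lesionqr.detection import dice

        logits = model.predict_logits(imgs)
        for i in range(len(levels)):
            d = np.mean(
                [dice(logits[i, j] >= 0, masks[j, 0]) for j in range(len(imgs))]
            )
            assert d > 0.9, f"level {levels[i]}: dice {d:.3f}"

    def test_warmup_protects_against_trivial_collapse(self, rater_data):
        """On imbalanced data, cold-started runs end in the all-background
        solution at least as often as warmed-up runs (paired seeds)."""
        imgs, masks = rater_data
        levels = (0.125, 0.375, 0.625, 0.875)
        flags = {True: 0, False: 0}
        for seed in (0, 1):
            for warm in (True, False):
                cfg = TrainConfig(
                    epochs=4, batch_size=8, seed=seed,
                    image_shape=(1, 32, 32), learning_rate=1e-3,
                )
                _, log = train_bqr_unet(
                    imgs, masks, levels, cfg, warmup=warm, warmup_epochs=4
                )
                flags[warm] += log[-1]["trivial_solution"]
        assert flags[False] >= flags[True]

    def test_baseline_bce_unet_trains(self, rater_data):
        imgs, masks = rater_data
        cfg = TrainConfig(
            epochs=3, batch_size=8, seed=0, image_shape=(1, 32, 32),
            learning_rate=3e-3,
        )
        model, log = train_unet_bce(imgs, masks, cfg)
        prob_logits = model.predict_logits(imgs)
        assert prob_logits.shape == (1, len(imgs), 32, 32)
        assert log[-1]["pos_weight"] > 1.0

    def test_unet_gradients_match_finite_differences(self):
        """End-to-end gradient check through skips, concat and heads."""
        rng = np.random.default_rng(0)
        model = MultiHeadUNet(1, 2, base=2, seed=1)
        x = rng.standard_normal((2, 1, 8, 8))
        gy = [rng.standard_normal((2, 1, 8, 8)) for _ in range(2)]

        def total(xv=None):
            outs = model.forward(x, train=True)
            return sum(float((o * g).sum()) for o, g in zip(outs, gy))

        total()
        for p in model.params():
            p.grad[...] = 0.0
        model.backward(gy)
        checked = 0
        for p in model.params()[::7]:
            idx = tuple(rng.integers(0, s) for s in p.value.shape)
            orig = p.value[idx]
            p.value[idx] = orig + 1e-5
            fp = total()
            p.value[idx] = orig - 1e-5
            fm = total()
            p.value[idx] = orig
            assert p.grad[idx] == pytest.approx((fp - fm) / 2e-5, rel=1e-4, abs=1e-6)
            checked += 1
        assert checked >= 5
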