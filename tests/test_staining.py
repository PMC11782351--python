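"""RCA-UNet regression: architecture contract, gradients, training, prediction."""

import numpy as np
import pytest

import vstain.nn as nn
from vstain.imgen import SceneSpec, generate_scene
from vstain.staining import (ModelConfig, build_model, load_model, normalize,
                             predict, predict_multiplex, save_model, train)

SMALL = dict(depth=2, base_channels=8, attention_reduction_r=4, patch_size_px=32)


class TestModelConfig:
    def test_patch_divisibility(self):
        with pytest.raises(ValueError):
            ModelConfig(depth=3, patch_size_px=36)

    def test_attention_reduction_bound(self):
        with pytest.raises(ValueError):
            ModelConfig(depth=1, base_channels=2, attention_reduction_r=64)


class TestArchitecture:
    def test_output_shape_single_channel(self):
        m = build_model(ModelConfig(**SMALL, seed=0))
        out = m.net.predict_array(np.zeros((1, 1, 64, 64), np.float32))
        assert out.shape == (1, 1, 64, 64)

    def test_attention_gate_strictly_in_unit_interval_on_zero_input(self):
        m = build_model(ModelConfig(**SMALL, seed=0))
        x = nn.Tensor(np.zeros((1, 1, 16, 16), np.float32))
        g = m.net.enc[0].attention_gate(x).data
        assert np.all(g > 0.0) and np.all(g < 1.0)

    def test_seeded_init_reproducible(self):
        cfg = ModelConfig(**SMALL, seed=42)
        x = np.random.default_rng(0).random((1, 1, 32, 32)).astype(np.float32)
        a = build_model(cfg).net.predict_array(x)
        b = build_model(cfg).net.predict_array(x)
        assert np.array_equal(a, b)

    def test_gradients_match_finite_differences(self):
        # float64 + tiny eps: backprop must agree with central differences
        old = nn.DTYPE
        nn.DTYPE = np.float64
        try:
            cfg = ModelConfig(depth=2, base_channels=4, attention_reduction_r=2,
                              patch_size_px=8, seed=0)
            m = build_model(cfg)
            rng = np.random.default_rng(1)
            x = rng.random((2, 1, 8, 8))
            y = rng.random((2, 1, 8, 8))
            loss = nn.mse_loss(m.net.forward(nn.Tensor(x)), y)
            loss.backward()
            for p in m.net.params():
                flat = p.data.ravel()
                grad = p.grad.ravel() if p.grad is not None else np.zeros(flat.size)
                for i in rng.choice(flat.size, size=min(3, flat.size), replace=False):
                    eps, orig = 1e-6, flat[i]
                    flat[i] = orig + eps
                    lp = float(nn.mse_loss(m.net.forward(nn.Tensor(x)), y).data)
                    flat[i] = orig - eps
                    lm = float(nn.mse_loss(m.net.forward(nn.Tensor(x)), y).data)
                    flat[i] = orig
                    num = (lp - lm) / (2 * eps)
                    assert grad[i] == pytest.approx(num, rel=1e-4, abs=1e-7)
        finally:
            nn.DTYPE = old


class TestNormalize:
    def test_full_range_maps_to_unit(self):
        img = np.linspace(0, 1, 10_000).reshape(100, 100)
        out = normalize(img)
        assert out.min() == 0.0 and out.max() == 1.0

    def test_constant_image_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            normalize(np.full((32, 32), 0.7))

    def test_hot_pixel_clipped(self):
        img = np.linspace(0, 1, 10_000).reshape(100, 100).copy()
        img[50, 50] = 1e6
        out = normalize(img)
        assert out[50, 50] == 1.0
        assert out.max() == 1.0

    def test_invalid_percentiles(self):
        with pytest.raises(ValueError):
            normalize(np.random.default_rng(0).random((8, 8)), 99, 1)


class TestTraining:
    def test_identity_task_reduces_loss_tenfold(self):
        cfg = ModelConfig(**SMALL, epochs=5, batch_size=8, seed=1, augment=False)
        rng = np.random.default_rng(2)
        pairs = [(im := rng.random((32, 32)), im) for _ in range(50)]
        _, hist = train(build_model(cfg), pairs)
        assert len(hist.train_loss) == 5
        assert np.isfinite(hist.train_loss).all()
        assert hist.train_loss[-1] < 0.1 * hist.train_loss[0]

    def test_empty_pairs_raise(self):
        with pytest.raises(ValueError):
            train(build_model(ModelConfig(**SMALL)), [])

    def test_shape_mismatch_raises(self):
        rng = np.random.default_rng(3)
        with pytest.raises(ValueError, match="mismatch"):
            train(build_model(ModelConfig(**SMALL)),
                  [(rng.random((32, 32)), rng.random((32, 33)))])

    def test_image_smaller_than_patch_raises(self):
        rng = np.random.default_rng(4)
        with pytest.raises(ValueError, match="patch"):
            train(build_model(ModelConfig(**SMALL)),
                  [(rng.random((16, 16)), rng.random((16, 16)))])


class TestPredict:
    def test_output_shape_and_finiteness(self, membrane_model):
        rng = np.random.default_rng(5)
        out = predict(membrane_model, rng.random((200, 180)))
        assert out.shape == (200, 180)
        assert np.isfinite(out).all()

    def test_tiled_matches_whole_image(self, membrane_model):
        sc = generate_scene(SceneSpec(width_px=256, height_px=256, n_cells=16,
                                      shape_model="pavement", seed=123))
        whole = predict(membrane_model, sc.brightfield)
        tiled = predict(membrane_model, sc.brightfield, tile=128, overlap=64)
        assert np.abs(whole - tiled).max() <= 1e-3

    def test_too_small_image_raises(self, membrane_model):
        with pytest.raises(ValueError, match="smaller"):
            predict(membrane_model, np.zeros((2, 2)))

    def test_multiplex_stacks_one_page_per_model(self, membrane_model, nucleus_model):
        sc = generate_scene(SceneSpec(width_px=64, height_px=64, n_cells=2,
                                      shape_model="by2_file", seed=55))
        stack = predict_multiplex([membrane_model, nucleus_model], sc.brightfield)
        assert stack.shape == (2, 64, 64)
        assert np.isfinite(stack).all()


class TestSerialization:
    def test_save_load_predicts_bit_identically(self, membrane_model, tmp_path):
        rng = np.random.default_rng(6)
        img = rng.random((96, 96))
        before = predict(membrane_model, img)
        save_model(membrane_model, tmp_path / "m")
        reloaded = load_model(tmp_path / "m")
        assert reloaded.channel_name == membrane_model.channel_name
        assert reloaded.trained
        after = predict(reloaded, img)
        assert np.array_equal(before, after)
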