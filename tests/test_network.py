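"""Architecture census, parameter counts, forward contracts, loss arithmetic."""

import numpy as np
import pytest

from mito3d import _nn
from mito3d.network import (
    NetworkConfig,
    build_model,
    count_parameters,
    deep_supervision_loss,
    forward,
    load_checkpoint,
    save_checkpoint,
    training_loss_tensors,
)


@pytest.fixture(scope="module")
def default_model():
    return build_model(NetworkConfig(), seed=0)


@pytest.fixture(scope="module")
def tiny_model():
    return build_model(NetworkConfig.tiny(4), seed=1)


class TestArchitecture:
    def test_default_parameter_count_near_1_1m(self, default_model):
        n = count_parameters(default_model)
        assert 0.88e6 <= n <= 1.32e6

    def test_layer_census_13_contracting_15_expansive(self, default_model):
        assert default_model.layer_census() == (13, 15)

    def test_single_conv_parameter_count(self):
        w = _nn.Parameter(np.zeros((8, 1, 3, 3, 3)))
        b = _nn.Parameter(np.zeros(8))
        assert w.size + b.size == 224  # 27*8 + 8

    def test_doubling_widths_quadruples_parameters(self):
        small = count_parameters(build_model(NetworkConfig.tiny(8)))
        big = count_parameters(build_model(NetworkConfig.tiny(16)))
        # convolution-dominated: ratio close to 4 (biases/BN scale linearly)
        assert 3.5 <= big / small <= 4.1

    def test_no_aux_heads_config(self):
        cfg = NetworkConfig(aux_levels=(), aux_weights=(), lambda_reg=0.0)
        model = build_model(cfg, seed=0)
        x = _nn.Tensor(np.random.default_rng(0).normal(size=(1, 1, 1, 8, 8)))
        labels = np.random.default_rng(1).integers(0, 2, size=(1, 1, 8, 8))
        main, auxes = model.forward_tensors(x, train=True)
        assert auxes == []
        total = training_loss_tensors(model, main, auxes, labels)
        plain = _nn.softmax_cross_entropy(main, labels)
        assert total.data == pytest.approx(plain.data, abs=1e-12)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            NetworkConfig(aux_levels=(0,), aux_weights=(0.1, 0.2))
        with pytest.raises(ValueError):
            NetworkConfig(widths=(8,))
        with pytest.raises(ValueError):
            NetworkConfig(lambda_reg=-1.0)

    def test_isotropic_preset_strides(self):
        cfg = NetworkConfig.isotropic()
        assert cfg.pool_strides == ((1, 2, 2), (2, 2, 2), (2, 2, 2))


class TestForward:
    def test_output_shape_matches_input_and_probabilities_normalize(self, tiny_model):
        patch = np.random.default_rng(0).random((8, 16, 16))
        probs = forward(tiny_model, patch, mode="infer")
        assert probs.shape == (2, 8, 16, 16)
        np.testing.assert_allclose(probs.sum(axis=0), 1.0, atol=1e-5)
        assert probs.min() >= 0

    def test_infer_mode_returns_single_map_train_returns_aux(self, tiny_model):
        patch = np.zeros((4, 8, 8))
        out = forward(tiny_model, patch, mode="infer")
        assert isinstance(out, np.ndarray)
        main, auxes = forward(tiny_model, patch, mode="train")
        assert len(auxes) == len(tiny_model.config.aux_levels)
        for a in auxes:
            assert a.shape == main.shape

    def test_zeroed_classifier_gives_uniform_half(self, tiny_model):
        saved = (tiny_model.classifier.w.data.copy(), tiny_model.classifier.b.data.copy())
        tiny_model.classifier.w.data[:] = 0
        tiny_model.classifier.b.data[:] = 0
        try:
            probs = forward(tiny_model, np.random.rand(4, 8, 8), mode="infer")
            np.testing.assert_allclose(probs, 0.5, atol=1e-12)
        finally:
            tiny_model.classifier.w.data, tiny_model.classifier.b.data = saved

    def test_incompatible_shape_names_axis(self, tiny_model):
        with pytest.raises(ValueError, match="axis y"):
            forward(tiny_model, np.zeros((4, 9, 16)))

    def test_z_extent_preserved_at_every_level_with_inplane_strides(self, tiny_model):
        # with 2x2x1 pooling a z-odd input passes; only y/x must divide
        probs = forward(tiny_model, np.random.rand(3, 8, 8))
        assert probs.shape[1] == 3

    def test_xy_flip_equivariance_with_symmetric_weights(self):
        model = build_model(NetworkConfig.tiny(4), seed=0)
        for p in model.parameters():
            if p.data.ndim == 5:  # conv kernels -> spatially constant
                p.data[:] = 0.01
        patch = np.random.default_rng(3).random((2, 8, 8))
        direct = forward(model, patch[:, ::-1].copy(), mode="infer")
        flipped = forward(model, patch, mode="infer")[:, :, ::-1]
        np.testing.assert_allclose(direct, flipped, atol=1e-10)


class TestLoss:
    def test_single_voxel_half_probability_is_ln2(self):
        cfg = NetworkConfig.tiny(4)
        val = deep_supervision_loss(
            np.full((1, 1, 1), 0.5), [], np.ones((1, 1, 1), dtype=int), cfg
        )
        assert val == pytest.approx(np.log(2), abs=1e-12)

    def test_zero_aux_weights_equal_plain_cross_entropy(self, rng):
        cfg = NetworkConfig(aux_levels=(0,), aux_weights=(0.0,), lambda_reg=0.0)
        p = rng.uniform(0.05, 0.95, size=(2, 4, 4))
        y = rng.integers(0, 2, size=(2, 4, 4))
        with_aux = deep_supervision_loss(p, [p.copy()], y, cfg)
        plain = deep_supervision_loss(p, [], y, cfg)
        assert with_aux == pytest.approx(plain, abs=1e-12)

    def test_hand_computed_weighted_example(self):
        # probabilities {0.9, 0.8, 0.3, 0.6}, labels {1,1,0,1}, aux = main,
        # w = [0.3] -> total = 1.3 * mean CE
        p = np.array([0.9, 0.8, 0.3, 0.6]).reshape(1, 2, 2)
        y = np.array([1, 1, 0, 1]).reshape(1, 2, 2)
        ce = -np.mean(
            [np.log(0.9), np.log(0.8), np.log(1 - 0.3), np.log(0.6)]
        )
        cfg = NetworkConfig(aux_levels=(0,), aux_weights=(0.3,), lambda_reg=0.0)
        val = deep_supervision_loss(p, [p.copy()], y, cfg)
        assert val == pytest.approx(1.3 * ce, abs=1e-12)

    def test_loss_decomposition_identity(self, tiny_model, rng):
        patch = rng.random((4, 8, 8))
        y = rng.integers(0, 2, size=(4, 8, 8))
        main, auxes = forward(tiny_model, patch, mode="train")
        cfg = tiny_model.config
        total = deep_supervision_loss(main, auxes, y, cfg, model=tiny_model)
        parts = deep_supervision_loss(main, [], y, cfg)
        for w, a in zip(cfg.aux_weights, auxes):
            parts += w * deep_supervision_loss(a, [], y, cfg)
        sq = sum(float((p.data**2).sum()) for p in tiny_model.parameters())
        parts += 0.5 * cfg.lambda_reg * sq
        assert total == pytest.approx(parts, abs=1e-6)

    def test_non_binary_labels_rejected(self):
        cfg = NetworkConfig.tiny(4)
        with pytest.raises(ValueError, match="binary"):
            deep_supervision_loss(np.full((1, 1, 1), 0.5), [], np.full((1, 1, 1), 2), cfg)

    def test_gradient_matches_finite_differences(self):
        # analytic gradient of the full objective w.r.t. weights on a 2x2x2 patch
        model = build_model(NetworkConfig.tiny(2), seed=5)
        rng = np.random.default_rng(7)
        x = _nn.Tensor(rng.normal(size=(1, 1, 2, 2, 2)))
        y = rng.integers(0, 2, size=(1, 2, 2, 2))

        def objective():
            main, auxes = model.forward_tensors(x, train=False)
            return training_loss_tensors(model, main, auxes, y)

        loss = None
        main, auxes = model.forward_tensors(x, train=False)
        loss = training_loss_tensors(model, main, auxes, y)
        for p in model.parameters():
            p.grad = None
        _nn.backward(loss)
        eps = 1e-6
        for p in [model.stem.w, model.classifier.w, model.stem.bn.gamma]:
            idx = tuple(0 for _ in p.data.shape)
            orig = p.data[idx]
            p.data[idx] = orig + eps
            up = float(objective().data)
            p.data[idx] = orig - eps
            down = float(objective().data)
            p.data[idx] = orig
            fd = (up - down) / (2 * eps)
            assert fd == pytest.approx(float(p.grad[idx]), abs=1e-4)


class TestCheckpoint:
    def test_round_trip_identical_outputs(self, tmp_path, tiny_model):
        patch = np.random.default_rng(0).random((4, 8, 8))
        before = forward(tiny_model, patch, mode="infer")
        path = tmp_path / "model.npz"
        save_checkpoint(tiny_model, path)
        restored = load_checkpoint(path)
        after = forward(restored, patch, mode="infer")
        np.testing.assert_array_equal(before, after)
        assert restored.config == tiny_model.config
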