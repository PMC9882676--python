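"""Architecture contracts: data-flow shapes, element conservation, gradients."""

import numpy as np
import pytest

from surview3d import nn
from surview3d.networks import (
    DualViewNetwork,
    LatentTensor,
    NetworkScaleConfig,
    SingleViewNetwork,
    build_network,
    generation_forward,
    representation_forward,
    single_view_forward,
    transform_dual,
    transform_single,
)

FULL_REPRESENTATION_FLOW = [
    (1024, 1024, 32),
    (512, 512, 64),
    (256, 256, 128),
    (128, 128, 256),
    (64, 64, 512),
    (32, 32, 1024),
]
FULL_GENERATION_FLOW = [
    (8, 8, 8, 512),
    (16, 16, 16, 256),
    (32, 32, 32, 128),
    (64, 64, 64, 64),
    (128, 128, 128, 1),
]


class TestScaleConfig:
    def test_full_scale_trace_reproduces_stated_flows(self):
        trace = dict(NetworkScaleConfig.full_scale().shape_trace(dual=False))
        assert trace["input"] == (1024, 1024, 1)
        for i, shape in enumerate(FULL_REPRESENTATION_FLOW, 1):
            assert trace[f"representation_block{i}"] == shape
        assert trace["transform_reshape"] == (4, 4, 4, 16384)
        assert trace["transform_conv1x1x1"] == (4, 4, 4, 1024)
        for i, shape in enumerate(FULL_GENERATION_FLOW, 1):
            assert trace[f"generation_block{i}"] == shape

    def test_dual_reshape_doubles_channels(self):
        trace = dict(NetworkScaleConfig.full_scale().shape_trace(dual=True))
        assert trace["transform_reshape"] == (4, 4, 4, 32768)

    def test_element_conservation_through_reshape(self):
        for cfg, dual in [
            (NetworkScaleConfig.full_scale(), False),
            (NetworkScaleConfig.full_scale(), True),
            (NetworkScaleConfig.desk_scale(), False),
        ]:
            latent_elems = cfg.latent_elements * (2 if dual else 1)
            e = cfg.gen_entry_size
            assert e**3 * cfg.reshaped_channels(dual) == latent_elems

    def test_desk_scale_divisor8_shapes(self):
        trace = dict(NetworkScaleConfig.desk_scale().shape_trace(dual=False))
        assert trace["representation_block6"] == (4, 4, 128)
        assert trace["transform_reshape"] == (2, 2, 2, 256)
        assert trace["transform_conv1x1x1"] == (2, 2, 2, 128)
        assert trace["generation_block4"] == (32, 32, 32, 1)

    def test_parameter_scaling_quadratic_in_divisor(self):
        full = NetworkScaleConfig.full_scale()
        desk = NetworkScaleConfig(input_size=1024, output_size=128, channel_divisor=8, gen_entry_size=4)
        assert desk.parameter_count(dual=True) < full.parameter_count(dual=True) / 16

    def test_analytic_count_matches_actual(self, desk_net_config):
        for arch in ("single", "dual"):
            net = build_network(arch, desk_net_config)
            assert net.n_parameters() == desk_net_config.parameter_count(dual=(arch == "dual"))

    def test_invalid_configs_listed(self):
        assert NetworkScaleConfig(input_size=64).validate()  # latent < 4
        assert NetworkScaleConfig(channel_divisor=16).validate()  # < 4 channels
        assert NetworkScaleConfig(output_size=48).validate()  # not a power-of-2 multiple


class TestForwardContracts:
    def test_single_view_shape_and_range(self, desk_net_config):
        net = SingleViewNetwork(desk_net_config)
        x = np.random.default_rng(0).random((2, 1, 128, 128), dtype=np.float32)
        y = net.forward(x)
        assert y.shape == (2, 1, 32, 32, 32)
        assert y.min() >= 0.0 and y.max() <= 1.0

    def test_dual_view_shape(self, desk_net_config):
        net = DualViewNetwork(desk_net_config)
        rng = np.random.default_rng(0)
        x1 = rng.random((1, 1, 128, 128), dtype=np.float32)
        x2 = rng.random((1, 1, 128, 128), dtype=np.float32)
        assert net.forward(x1, x2).shape == (1, 1, 32, 32, 32)
        with pytest.raises(ValueError, match="mismatch"):
            net.forward(x1, x2[:, :, :64, :64])

    def test_inference_deterministic(self, desk_net_config):
        net = SingleViewNetwork(desk_net_config)
        x = np.random.default_rng(1).random((1, 1, 128, 128), dtype=np.float32)
        a = net.forward(x)
        b = net.forward(x)
        assert a.tobytes() == b.tobytes()

    def test_same_seed_same_weights(self, desk_net_config):
        a = DualViewNetwork(desk_net_config)
        b = DualViewNetwork(desk_net_config)
        for la, lb in zip(a.layers(), b.layers()):
            for k in la.params:
                np.testing.assert_array_equal(la.params[k], lb.params[k])

    def test_dual_has_more_parameters_than_single(self, desk_net_config):
        assert (
            DualViewNetwork(desk_net_config).n_parameters()
            > SingleViewNetwork(desk_net_config).n_parameters()
        )

    def test_zero_input_zero_biases_gives_zero_latent(self, desk_net_config):
        net = SingleViewNetwork(desk_net_config)
        # zero biases and inference-mode batchnorm with zero running mean
        for layer in net.layers():
            if "b" in layer.params:
                layer.params["b"][...] = 0.0
            if isinstance(layer, nn.BatchNorm):
                layer.params["beta"][...] = 0.0
        latent = representation_forward(np.zeros((128, 128), dtype=np.float32), net)
        np.testing.assert_array_equal(latent.grid, 0.0)

    def test_checkpoint_round_trip(self, desk_net_config, tmp_path):
        net = DualViewNetwork(desk_net_config)
        x1 = np.random.default_rng(2).random((1, 1, 128, 128), dtype=np.float32)
        x2 = np.random.default_rng(3).random((1, 1, 128, 128), dtype=np.float32)
        y = net.forward(x1, x2)
        p = tmp_path / "model.npz"
        net.save(p)
        from surview3d.networks import load_network

        net2 = load_network(p)
        np.testing.assert_array_equal(net2.forward(x1, x2), y)


class TestTransformation:
    def test_identity_conv_on_constant_latent_is_constant(self, desk_net_config):
        net = SingleViewNetwork(desk_net_config)
        c_in = desk_net_config.reshaped_channels(False)
        c_out = desk_net_config.latent_channels
        # identity-like 1x1x1 conv: each output channel copies input channel i
        w = np.zeros((c_out, c_in), dtype=np.float32)
        w[np.arange(c_out), np.arange(c_out)] = 1.0
        net.transform_conv.params["w"][...] = w
        net.transform_conv.params["b"][...] = 0.0
        latent = LatentTensor(np.full((4, 4, 128), 0.7, dtype=np.float32))
        z = transform_single(latent, net)
        assert z.shape == (2, 2, 2, 128)
        np.testing.assert_allclose(z.grid, 0.7, rtol=1e-6)

    def test_dual_duplicate_input_with_averaging_weights_matches_single(self, desk_net_config):
        single = SingleViewNetwork(desk_net_config)
        dual = DualViewNetwork(desk_net_config)
        c = desk_net_config.reshaped_channels(False)
        w = single.transform_conv.params["w"]
        dual.transform_conv.params["w"][...] = np.concatenate([w / 2, w / 2], axis=1)
        dual.transform_conv.params["b"][...] = single.transform_conv.params["b"]
        latent = LatentTensor(np.random.default_rng(5).random((4, 4, 128)).astype(np.float32))
        np.testing.assert_allclose(
            transform_dual(latent, latent, dual).grid,
            transform_single(latent, single).grid,
            rtol=1e-5, atol=1e-7,
        )

    def test_latent_order_matters_for_random_weights(self, desk_net_config):
        dual = DualViewNetwork(desk_net_config)
        rng = np.random.default_rng(6)
        l1 = LatentTensor(rng.random((4, 4, 128)).astype(np.float32))
        l2 = LatentTensor(rng.random((4, 4, 128)).astype(np.float32))
        a = transform_dual(l1, l2, dual).grid
        b = transform_dual(l2, l1, dual).grid
        assert np.max(np.abs(a - b)) > 1e-4

    def test_zeroed_sagittal_branch_ignores_x2(self, desk_net_config):
        dual = DualViewNetwork(desk_net_config)
        c = desk_net_config.reshaped_channels(False)
        dual.transform_conv.params["w"][:, c:] = 0.0
        rng = np.random.default_rng(7)
        x1 = rng.random((1, 1, 128, 128), dtype=np.float32)
        x2a = rng.random((1, 1, 128, 128), dtype=np.float32)
        x2b = rng.random((1, 1, 128, 128), dtype=np.float32)
        np.testing.assert_array_equal(dual.forward(x1, x2a), dual.forward(x1, x2b))

    def test_functional_composition_matches_model_forward(self, desk_net_config):
        net = SingleViewNetwork(desk_net_config)
        x = np.random.default_rng(8).random((128, 128)).astype(np.float32)
        via_parts = generation_forward(transform_single(representation_forward(x, net), net), net)
        np.testing.assert_allclose(via_parts, single_view_forward(x, net), rtol=1e-6, atol=1e-7)


class TestGradients:
    """Analytic backward passes against central finite differences (float64)."""

    @staticmethod
    def _gradcheck(layer, x, training=True, rtol=1e-5):
        rng = np.random.default_rng(0)
        y = layer.forward(x, training)
        gy = rng.standard_normal(y.shape)
        gx = layer.backward(gy)

        def loss(xv):
            return float(np.sum(layer.forward(xv, training) * gy))

        eps = 1e-6
        for _ in range(5):
            idx = tuple(rng.integers(0, s) for s in x.shape)
            xp, xm = x.copy(), x.copy()
            xp[idx] += eps
            xm[idx] -= eps
            num = (loss(xp) - loss(xm)) / (2 * eps)
            assert gx[idx] == pytest.approx(num, rel=rtol, abs=1e-7)
        # parameter gradients
        layer.forward(x, training)
        layer.backward(gy)
        for k, p in layer.params.items():
            g_analytic = layer.grads[k].copy()
            for _ in range(3):
                idx = tuple(rng.integers(0, s) for s in p.shape)
                orig = p[idx]
                p[idx] = orig + eps
                lp = loss(x)
                p[idx] = orig - eps
                lm = loss(x)
                p[idx] = orig
                assert g_analytic[idx] == pytest.approx((lp - lm) / (2 * eps), rel=rtol, abs=1e-7)

    def _f64(self, layer):
        for k in layer.params:
            layer.params[k] = layer.params[k].astype(np.float64)
        return layer

    def test_conv2d_gradient(self):
        rng = np.random.default_rng(1)
        layer = self._f64(nn.Conv(rng, 2, 3, (3, 3), stride=1, pad=1))
        self._gradcheck(layer, rng.standard_normal((2, 2, 6, 6)))

    def test_strided_conv2d_gradient(self):
        rng = np.random.default_rng(2)
        layer = self._f64(nn.Conv(rng, 2, 4, (4, 4), stride=2, pad=1))
        self._gradcheck(layer, rng.standard_normal((2, 2, 8, 8)))

    def test_conv_transpose3d_gradient(self):
        rng = np.random.default_rng(3)
        layer = self._f64(nn.ConvTranspose(rng, 2, 2, (4, 4, 4), stride=2, pad=1))
        self._gradcheck(layer, rng.standard_normal((1, 2, 3, 3, 3)))

    def test_pointwise_conv3d_gradient(self):
        rng = np.random.default_rng(4)
        layer = self._f64(nn.Conv(rng, 4, 3, (1, 1, 1)))
        self._gradcheck(layer, rng.standard_normal((2, 4, 2, 2, 2)))

    def test_batchnorm_gradient(self):
        rng = np.random.default_rng(5)
        layer = self._f64(nn.BatchNorm(3))
        layer.running_mean = layer.running_mean.astype(np.float64)
        layer.running_var = layer.running_var.astype(np.float64)
        self._gradcheck(layer, rng.standard_normal((4, 3, 5, 5)), rtol=1e-4)

    def test_conv_transpose_doubles_spatial_side(self):
        rng = np.random.default_rng(6)
        layer = nn.ConvTranspose(rng, 3, 2, (4, 4, 4), stride=2, pad=1)
        y = layer.forward(np.zeros((1, 3, 5, 5, 5), dtype=np.float32), training=False)
        assert y.shape == (1, 2, 10, 10, 10)
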