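"""Layers, architectures, parameter accounting and gradient flow."""

import numpy as np
import pytest

import ivuscaps.autodiff as ad
from conftest import ref_conv_capsule_layer

from ivuscaps.autodiff import Tensor
from ivuscaps.capsule_math import PoseTreatment, RoutingSpec
from ivuscaps.capsule_network import (ArchitectureConfig, CapsuleGrid,
                                      CapsuleUNet, UNetRes, UNetResConfig,
                                      capsule_presets, class_activations,
                                      concat_types, conv_capsule_layer,
                                      count_parameters, initial_embedding,
                                      matched_pairs, upsample_capsule_layer)
from ivuscaps.losses import spread_loss


def random_grid(rng, h, w, types, p=2, q=3):
    return CapsuleGrid(rng.normal(size=(h, w, types, p, p)),
                       rng.normal(size=(h, w, types, q, q)))


class TestConvCapsuleLayer:
    @pytest.mark.parametrize("algorithm", ["dual", "dynamic"])
    @pytest.mark.parametrize("treatment", ["normalize_pose_with_coords",
                                           "normalize_transform_with_coords",
                                           "none"])
    def test_matches_quadruple_loop_reference(self, algorithm, treatment, rng):
        h = w = 3
        ti, to, p, q = 2, 2, 2, 3
        pose = rng.normal(size=(h, w, ti, p, p))
        app = rng.normal(size=(h, w, ti, q, q))
        wp = rng.normal(size=(ti, to, p, p))
        wa = rng.normal(size=(ti, to, q, q))
        bias = rng.normal(size=(ti, to))
        spec = RoutingSpec(algorithm=algorithm, iterations=2, window=3)
        out = conv_capsule_layer(CapsuleGrid(pose, app), wp, wa, bias, spec,
                                 PoseTreatment(mode=treatment))
        ref_p, ref_a = ref_conv_capsule_layer(
            pose, app, wp, wa, bias, window=3, iterations=2,
            algorithm=algorithm, treatment=treatment)
        np.testing.assert_allclose(out.pose.data, ref_p, atol=1e-5)
        np.testing.assert_allclose(out.appearance.data, ref_a, atol=1e-5)

    def test_stride_two_matches_reference_and_halves_grid(self, rng):
        h = w = 4
        pose = rng.normal(size=(h, w, 2, 2, 2))
        app = rng.normal(size=(h, w, 2, 3, 3))
        wp = rng.normal(size=(2, 2, 2, 2))
        wa = rng.normal(size=(2, 2, 3, 3))
        bias = rng.normal(size=(2, 2))
        spec = RoutingSpec(algorithm="dual", iterations=2, window=3, stride=2)
        out = conv_capsule_layer(CapsuleGrid(pose, app), wp, wa, bias, spec)
        assert (out.height, out.width) == (2, 2)
        ref_p, ref_a = ref_conv_capsule_layer(pose, app, wp, wa, bias,
                                              window=3, iterations=2, stride=2)
        np.testing.assert_allclose(out.pose.data, ref_p, atol=1e-5)
        np.testing.assert_allclose(out.appearance.data, ref_a, atol=1e-5)

    def test_degenerate_window_equals_plain_routing(self, rng):
        from ivuscaps.capsule_math import route_dual

        pose = rng.normal(size=(1, 1, 1, 2, 2))
        app = rng.normal(size=(1, 1, 1, 3, 3))
        wp = np.eye(2)[None, None]
        wa = np.eye(3)[None, None]
        spec = RoutingSpec(algorithm="dual", iterations=3, window=1)
        out = conv_capsule_layer(CapsuleGrid(pose, app), wp, wa,
                                 np.zeros((1, 1)), spec,
                                 PoseTreatment(mode="none"))
        po, ao, _ = route_dual(pose[0, 0, :, None], app[0, 0, :, None], spec)
        np.testing.assert_allclose(out.pose.data[0, 0], po, atol=1e-6)
        np.testing.assert_allclose(out.appearance.data[0, 0], ao, atol=1e-6)

    def test_upsample_doubles_grid(self, rng):
        grid = random_grid(rng, 4, 4, 2)
        wp = rng.normal(size=(2, 2, 2, 2))
        wa = rng.normal(size=(2, 2, 3, 3))
        spec = RoutingSpec(algorithm="dual", iterations=2, window=3)
        out = upsample_capsule_layer(grid, wp, wa, np.zeros((2, 2)), spec)
        assert (out.height, out.width, out.types) == (8, 8, 2)

    def test_upsample_routes_dilated_children(self, rng):
        """Each upsampled parent aggregates exactly the children whose
        dilated positions fall in its window (loop-checked)."""
        h = w = 2
        pose = rng.normal(size=(h, w, 1, 2, 2))
        app = rng.normal(size=(h, w, 1, 2, 2))
        wp = np.eye(2)[None, None]
        wa = np.eye(2)[None, None]
        spec = RoutingSpec(algorithm="dual", iterations=1, window=3)
        out = upsample_capsule_layer(CapsuleGrid(pose, app), wp, wa,
                                     np.zeros((1, 1)), spec,
                                     PoseTreatment(mode="none"))
        # place children on the dilated (2h, 2w) grid and route by loop
        dil_p = np.zeros((2 * h, 2 * w, 1, 2, 2))
        dil_a = np.zeros((2 * h, 2 * w, 1, 2, 2))
        dil_p[::2, ::2] = pose
        dil_a[::2, ::2] = app
        ref_p, ref_a = ref_conv_capsule_layer(dil_p, dil_a, wp, wa,
                                              np.zeros((1, 1)), window=3,
                                              iterations=1, treatment="none")
        np.testing.assert_allclose(out.pose.data, ref_p, atol=1e-6)
        np.testing.assert_allclose(out.appearance.data, ref_a, atol=1e-6)


class TestGridOps:
    def test_concat_types_counts_and_order(self, rng):
        a = random_grid(rng, 4, 4, 3)
        b = random_grid(rng, 4, 4, 3)
        out = concat_types(a, b)
        assert out.types == 6
        np.testing.assert_array_equal(out.pose.data[:, :, :3], a.pose.data)
        np.testing.assert_array_equal(out.pose.data[:, :, 3:], b.pose.data)

    def test_concat_spatial_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            concat_types(random_grid(rng, 4, 4, 2), random_grid(rng, 2, 2, 2))

    def test_class_activations_worked_example(self):
        pose = np.zeros((1, 1, 1, 4, 4))
        pose[0, 0, 0] = np.eye(4)                    # Frobenius norm 2
        app = np.zeros((1, 1, 1, 5, 5))
        app[0, 0, 0, 0, 0] = 0.5                     # Frobenius norm 0.5
        acts = class_activations(CapsuleGrid(pose, app))
        assert acts.data[0, 0, 0] == pytest.approx(1.0, abs=1e-6)

    def test_class_activations_zero_appearance(self, rng):
        pose = rng.normal(size=(2, 2, 3, 4, 4))
        app = np.zeros((2, 2, 3, 5, 5))
        acts = class_activations(CapsuleGrid(pose, app))
        np.testing.assert_allclose(acts.data, 0.0, atol=1e-5)

    def test_class_activations_sign_invariant(self, rng):
        pose = rng.normal(size=(2, 2, 3, 4, 4))
        app = rng.normal(size=(2, 2, 3, 5, 5))
        a1 = class_activations(CapsuleGrid(pose, app)).data
        a2 = class_activations(CapsuleGrid(-pose, -app)).data
        np.testing.assert_allclose(a1, a2, rtol=1e-6)

    def test_class_count_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            class_activations(random_grid(rng, 2, 2, 4), classes=3)


class TestInitialEmbedding:
    def test_zero_conv_gives_zero_appearance_identity_pose(self, toy_config):
        image = np.zeros((8, 8), dtype=np.float32)
        k = toy_config.initial_kernel
        feats = toy_config.features()
        grid = initial_embedding(image, toy_config,
                                 weight=np.zeros((k, k, feats)),
                                 bias=np.zeros(feats))
        np.testing.assert_array_equal(grid.appearance.data, 0.0)
        np.testing.assert_array_equal(grid.pose.data[3, 5, 0], np.eye(2))

    def test_spatial_size_and_type_count(self, rng):
        cfg = ArchitectureConfig(shape=(3, 6, 12, 24, 48))
        grid = initial_embedding(rng.random((16, 16)).astype(np.float32), cfg,
                                 rng=np.random.default_rng(0))
        assert (grid.height, grid.width, grid.types) == (16, 16, 3)

    def test_multichannel_image_rejected(self, toy_config, rng):
        with pytest.raises(ValueError):
            initial_embedding(rng.random((8, 8, 3)), toy_config)


class TestArchitectures:
    def test_capsule_unet_shape_contract(self, toy_config, rng):
        net = CapsuleUNet(toy_config, seed=0)
        acts = net(rng.random((16, 16)).astype(np.float32))
        assert acts.shape == (16, 16, 3)
        assert np.all(acts.data >= 0)

    def test_capsule_unet_rejects_indivisible_size(self, toy_config, rng):
        net = CapsuleUNet(toy_config, seed=0)
        with pytest.raises(ValueError):
            net(rng.random((15, 15)).astype(np.float32))

    def test_forward_deterministic(self, toy_config, rng):
        net = CapsuleUNet(toy_config, seed=0)
        img = rng.random((16, 16)).astype(np.float32)
        a1 = net(img).data
        a2 = net(img).data
        np.testing.assert_array_equal(a1, a2)

    def test_optimized_preset_structure(self):
        cfg = capsule_presets()["large"]
        assert cfg.shape == (3, 6, 12, 24, 48)
        assert cfg.window == 5
        assert cfg.pose_size == 4 and cfg.appearance_size == 5
        assert cfg.routing.algorithm == "dual" and cfg.routing.iterations == 3
        net = CapsuleUNet(cfg, seed=0)
        assert [blk[0].out_types for blk in net.encoder] == [3, 6, 12, 24, 48]
        assert [lyr.out_types for lyr in net.down] == [6, 12, 24, 48]

    def test_invalid_config_messages_name_field(self):
        with pytest.raises(ValueError, match="shape"):
            ArchitectureConfig(shape=(3,))
        with pytest.raises(ValueError, match="window"):
            ArchitectureConfig(window=4)

    def test_unet_res_shape_contract(self, rng):
        net = UNetRes(UNetResConfig(base_channels=4, depth=2), seed=0)
        probs = net(rng.random((16, 16)).astype(np.float32))
        assert probs.shape == (16, 16, 3)
        np.testing.assert_allclose(probs.data.sum(axis=-1), 1.0, atol=1e-5)

    def test_unet_res_channels_double(self):
        assert UNetResConfig(base_channels=8, depth=4).channels() == \
            [8, 16, 32, 64]

    def test_residual_block_zero_convs_pass_through(self, rng):
        from ivuscaps.capsule_network import ResBlock

        block = ResBlock(4, 4, np.random.default_rng(0))
        for p in (block.conv1.weight, block.conv1.bias,
                  block.conv2.weight, block.conv2.bias):
            p.data = np.zeros_like(p.data)
        block.norm2.gamma.data = np.zeros_like(block.norm2.gamma.data)
        x = np.abs(rng.normal(size=(6, 6, 4))).astype(np.float32)
        out = block(Tensor(x))
        np.testing.assert_allclose(out.data, x, atol=1e-6)


class TestParameterCounts:
    def test_single_pair_transform_block(self):
        cfg = ArchitectureConfig(shape=(1, 1), layers_per_level=1, window=1,
                                 pose_size=2, appearance_size=2,
                                 routing=RoutingSpec(iterations=1, window=1))
        from ivuscaps.capsule_network import ConvCapsuleLayer

        layer = ConvCapsuleLayer(1, 1, cfg, rng=np.random.default_rng(0))
        # pose 2x2 + appearance 2x2 + scalar bias
        assert count_parameters(layer) == 4 + 4 + 1

    def test_counts_increase_with_shape(self):
        counts = [count_parameters(CapsuleUNet(ArchitectureConfig(shape=s)))
                  for s in [(3, 4, 5, 6), (3, 5, 7, 9), (3, 6, 12, 24, 48)]]
        assert counts[0] < counts[1] < counts[2]

    def test_pose_block_scales_quadratically(self):
        def pose_params(p):
            cfg = ArchitectureConfig(shape=(1, 1), layers_per_level=1,
                                     window=1, pose_size=p, appearance_size=2,
                                     routing=RoutingSpec(iterations=1, window=1))
            from ivuscaps.capsule_network import ConvCapsuleLayer

            layer = ConvCapsuleLayer(1, 1, cfg, rng=np.random.default_rng(0))
            return layer.pose_w.size

        assert pose_params(4) == 4 * pose_params(2)

    def test_budget_tiers_match_within_five_percent(self):
        pairs = matched_pairs()
        assert set(pairs) == {"small", "medium", "large"}
        for caps_cfg, unet_cfg in pairs.values():
            c = count_parameters(CapsuleUNet(caps_cfg))
            u = count_parameters(UNetRes(unet_cfg))
            assert abs(u - c) / c < 0.05


class TestGradientFlow:
    def test_analytic_gradient_matches_finite_difference(self, toy_config, rng):
        """Finite differences through the full network, routing unrolled."""
        net = CapsuleUNet(toy_config, seed=3)
        for p in net.parameters():
            p.data = p.data.astype(np.float64)
        img = rng.random((8, 8))
        target = rng.integers(0, 3, size=(8, 8))

        def loss_value():
            return spread_loss(net(img), target, 0.5).item()

        loss = spread_loss(net(img), target, 0.5)
        net.zero_grad()
        loss.backward()
        params = net.parameters()
        sampler = np.random.default_rng(7)
        checked = 0
        for _ in range(8):
            p = params[int(sampler.integers(len(params)))]
            idx = np.unravel_index(int(sampler.integers(p.size)), p.shape)
            eps = 1e-6
            orig = p.data[idx]
            p.data[idx] = orig + eps
            up = loss_value()
            p.data[idx] = orig - eps
            down = loss_value()
            p.data[idx] = orig
            fd = (up - down) / (2 * eps)
            analytic = p.grad[idx]
            assert abs(fd - analytic) <= 1e-3 * max(1.0, abs(fd)), \
                f"param {idx}: fd {fd} vs analytic {analytic}"
            checked += 1
        assert checked == 8
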