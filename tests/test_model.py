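"""Generator/discriminator architecture contracts and the attention oracle."""

import time

import numpy as np
import pytest

from stainshift import autodiff as ad
from stainshift.autodiff import Tensor, no_grad
from stainshift.model import (AttentionMerge, DiscriminatorConfig,
                              GeneratorConfig, build_models, gaussian_blur,
                              guided_postprocess, joint_bilateral_blur)


class TestGeneratorConfig:
    def test_default_attention_bottleneck_is_four_channels(self):
        cfg = GeneratorConfig()
        assert cfg.widths[-1] == 256 and cfg.widths[-2] == 128
        assert cfg.attention_reductions == (64, 32)
        assert cfg.attention_channels == (4, 4)

    def test_tiny_config_keeps_four_attention_channels(self):
        assert GeneratorConfig.tiny().attention_channels == (4, 4)

    def test_indivisible_reduction_rejected(self):
        with pytest.raises(ValueError):
            GeneratorConfig(widths=(8, 12, 100),
                            attention_reductions=(64, 3)).validate()


class TestAttentionMerge:
    def _brute_force(self, dec, skip, merge):
        """Dense attention evaluated with explicit loops."""
        def conv1x1(x, layer):
            w = layer.w.data[:, :, 0, 0]
            b = layer.b.data if layer.b is not None else 0.0
            return np.einsum("oc,chw->ohw", w, x) + (
                np.asarray(b)[:, None, None] if layer.b is not None else 0.0)

        q = conv1x1(dec, merge.query)
        k = conv1x1(skip, merge.key)
        v = conv1x1(skip, merge.value)
        C, H, W = dec.shape
        N = H * W
        qf, kf, vf = (a.reshape(-1, N) for a in (q, k, v))
        out = np.zeros((C, N))
        for i in range(N):
            e = np.array([qf[:, i] @ kf[:, j] for j in range(N)])
            e = np.exp(e - e.max())
            attn = e / e.sum()
            out[:, i] = sum(attn[j] * vf[:, j] for j in range(N))
        o = np.einsum("oc,chw->ohw", merge.out.w.data[:, :, 0, 0], out.reshape(C, H, W))
        return dec + o + merge.skip_weight.item() * skip

    @pytest.mark.parametrize("spatial", [2, 4, 8])
    def test_matches_dense_attention_oracle(self, spatial, rng):
        merge = AttentionMerge(4, 2, np.random.default_rng(3))
        dec = rng.standard_normal((4, spatial, spatial)).astype(np.float32)
        skip = rng.standard_normal((4, spatial, spatial)).astype(np.float32)
        with no_grad():
            got = merge(Tensor(dec[None]), Tensor(skip[None])).data[0]
        want = self._brute_force(dec, skip, merge)
        assert np.allclose(got, want, atol=1e-5)

    def test_identity_limit_when_value_path_and_skip_are_zero(self, rng):
        merge = AttentionMerge(4, 2, np.random.default_rng(4))
        merge.skip_weight.data = np.float32(0.0)
        merge.value.w.data[:] = 0.0
        merge.value.b.data[:] = 0.0
        dec = Tensor(rng.standard_normal((1, 4, 3, 3)).astype(np.float32))
        skip = Tensor(rng.standard_normal((1, 4, 3, 3)).astype(np.float32))
        with no_grad():
            assert np.allclose(merge(dec, skip).data, dec.data, atol=1e-7)

    def test_indivisible_channels_rejected(self):
        with pytest.raises(ValueError):
            AttentionMerge(6, 4, np.random.default_rng(0))


class TestGenerator:
    def test_latent_spatial_size_follows_depth(self, tiny_bundle, tiny_batches):
        arr_a, _, _ = tiny_batches
        g = tiny_bundle.g_ab
        factor = g.config.downsample_factor
        with no_grad():
            out = g.forward(arr_a[:1])
        assert out.encoder_latent.shape[2] == 32 // factor
        assert out.encoder_latent.shape == out.transformed_latent.shape

    def test_both_generators_latents_share_shape(self, tiny_bundle, tiny_batches):
        """The context loss pairs latents across generators; shapes must agree."""
        arr_a, arr_b, _ = tiny_batches
        with no_grad():
            ab = tiny_bundle.g_ab.forward(arr_a[:1])
            ba = tiny_bundle.g_ba.forward(arr_b[:1])
        shapes = {ab.encoder_latent.shape, ab.transformed_latent.shape,
                  ba.encoder_latent.shape, ba.transformed_latent.shape}
        assert len(shapes) == 1

    def test_mask_channel_is_consumed(self, tiny_bundle, tiny_batches):
        arr_a, _, _ = tiny_batches
        g = tiny_bundle.g_ab
        ones = np.ones((1, 1, 32, 32), np.float32)
        with no_grad():
            lat1, _ = g.encode(arr_a[:1], mask=ones)
            lat0, _ = g.encode(arr_a[:1], mask=np.zeros_like(ones))
        assert not np.allclose(lat1.activations.data, lat0.activations.data)

    def test_forward_is_deterministic(self, tiny_bundle, tiny_batches):
        arr_a, _, _ = tiny_batches
        with no_grad():
            f1 = tiny_bundle.g_ab.forward(arr_a[:1]).fake.data
            f2 = tiny_bundle.g_ab.forward(arr_a[:1]).fake.data
        assert np.array_equal(f1, f2)

    def test_interpretable_layer_retrievable_by_name(self, tiny_bundle):
        g = tiny_bundle.g_ab
        layer = g.layer_by_name("latent.0.conv1")
        assert layer is g.interpretable_layer
        assert layer.w.data.ndim == 4

    def test_zeroed_transform_passes_residual_through(self, tiny_bundle, tiny_batches):
        arr_a, _, _ = tiny_batches
        g = tiny_bundle.g_ab
        saved = {n: p.data.copy() for n, p in g.named_parameters()
                 if n.startswith("latent.")}
        try:
            for n, p in g.named_parameters():
                if n.startswith("latent."):
                    p.data = np.zeros_like(p.data)
            with no_grad():
                enc, _ = g.encode(arr_a[:1])
                zt = g.transform_latent(enc)
            assert np.allclose(zt.activations.data, enc.activations.data, atol=1e-6)
        finally:
            for n, p in g.named_parameters():
                if n in saved:
                    p.data = saved[n]

    def test_output_shape_and_tanh_bound(self, tiny_bundle, tiny_batches):
        arr_a, _, _ = tiny_batches
        with no_grad():
            fake = tiny_bundle.g_ab.forward(arr_a[:1]).fake.data
        assert fake.shape == (1, 3, 32, 32)
        lum = tiny_bundle.g_ab.lum_mult.item()
        assert np.all(np.abs(fake[:, 0]) <= abs(lum) + 1e-6)
        assert np.all(np.abs(fake[:, 1:]) <= 1.0 + 1e-6)

    def test_wrong_tile_size_rejected(self, tiny_bundle):
        with pytest.raises(ValueError):
            tiny_bundle.g_ab.encode(np.zeros((1, 3, 16, 16), np.float32))

    def test_tiny_generator_under_100k_params_and_1s_forward(self):
        bundle = build_models(GeneratorConfig.tiny(64),
                              DiscriminatorConfig.tiny(64), seed=0)
        assert bundle.g_ab.n_parameters() <= 100_000
        x = np.zeros((1, 3, 64, 64), np.float32)
        with no_grad():
            bundle.g_ab.forward(x)   # warm caches
            t0 = time.perf_counter()
            bundle.g_ab.forward(x)
            assert time.perf_counter() - t0 < 1.0


class TestDiscriminator:
    def test_score_map_shape_and_finiteness(self, tiny_bundle, rng):
        x = rng.standard_normal((2, 3, 32, 32)).astype(np.float32)
        with no_grad():
            s = tiny_bundle.d_a(x).data
        # two stride-2 convolutions: 32 -> 8 patch grid
        assert s.shape == (2, 1, 8, 8)
        assert np.all(np.isfinite(s))

    def test_determinism(self, tiny_bundle, rng):
        x = rng.standard_normal((1, 3, 32, 32)).astype(np.float32)
        with no_grad():
            assert np.array_equal(tiny_bundle.d_a(x).data, tiny_bundle.d_a(x).data)


class TestGuidedPostprocess:
    def test_identity_when_kernel_one_and_no_unsharp(self, rng):
        img = rng.standard_normal((1, 3, 8, 8)).astype(np.float32)
        out = guided_postprocess(img, img, kernel_size=1, unsharp_amount=0.0)
        assert np.array_equal(out.data, img)

    def test_constant_image_is_fixed_point(self):
        img = np.full((1, 3, 8, 8), 0.3, np.float32)
        guide = np.linspace(0, 1, 8 * 8 * 3, dtype=np.float32).reshape(1, 3, 8, 8)
        out = guided_postprocess(img, guide, kernel_size=3, unsharp_amount=0.5)
        assert np.allclose(out.data, 0.3, atol=1e-6)

    def test_gradient_is_finite_and_nonzero(self, rng):
        img = Tensor(rng.standard_normal((1, 3, 8, 8)).astype(np.float32),
                     requires_grad=True)
        guide = rng.standard_normal((1, 3, 8, 8)).astype(np.float32)
        out = guided_postprocess(img, guide, kernel_size=3, unsharp_amount=0.5)
        ad.mean(out * out).backward()
        assert np.all(np.isfinite(img.grad))
        assert np.any(img.grad != 0)

    def test_bilateral_smooths_noise_but_respects_guide_edges(self, rng):
        # noisy two-level image; guide has a sharp vertical edge
        guide = np.zeros((1, 3, 8, 8), np.float32)
        guide[..., 4:] = 1.0
        img = guide + rng.normal(0, 0.05, guide.shape).astype(np.float32)
        out = joint_bilateral_blur(img, guide, kernel_size=3,
                                   sigma_range=0.05).data
        # variance within each flat region shrinks
        assert out[..., :4].std() < img[..., :4].std()
        # the edge survives (means of the two sides stay far apart)
        assert out[..., 4:].mean() - out[..., :4].mean() > 0.8

    def test_gaussian_blur_preserves_mean_of_constant(self):
        img = np.full((1, 1, 6, 6), 2.0, np.float32)
        assert np.allclose(gaussian_blur(img, 5, 1.0).data, 2.0, atol=1e-6)
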