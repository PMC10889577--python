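"""Tiling, entropy, downscaling, CIELAB and model-range mapping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from skimage.measure import shannon_entropy as skimage_entropy

from stainshift import preprocessing as pp


def _img(h, w, value=0.5):
    return np.full((h, w, 3), value)


class TestTileGrid:
    @pytest.mark.parametrize("h,w,size,expected", [
        (1024, 1024, 1024, 1),
        (2048, 3072, 1024, 6),
        (1000, 1024, 1024, 0),
        (64, 96, 32, 6),
    ])
    def test_tile_counts(self, h, w, size, expected):
        if expected == 0:
            with pytest.warns(UserWarning):
                tiles = pp.tile_grid(_img(h, w), size)
        else:
            tiles = pp.tile_grid(_img(h, w), size)
        assert len(tiles) == expected

    def test_row_major_positions_and_partition(self, rng):
        img = rng.random((64, 96, 3))
        tiles = pp.tile_grid(img, 32)
        assert [t.grid_position for t in tiles] == [
            (0, 0), (0, 1), (0, 2), (1, 0), (1, 1), (1, 2)]
        # tiles reassemble the covered area exactly (partition, no overlap)
        recon = np.zeros_like(img)
        for t in tiles:
            r, c = t.grid_position
            recon[r * 32:(r + 1) * 32, c * 32:(c + 1) * 32] = t.pixels.transpose(1, 2, 0)
        assert np.allclose(recon, img)


class TestShannonEntropy:
    def test_constant_tile_is_zero_bits(self):
        t = pp.TileRecord(np.full((3, 16, 16), 0.4))
        assert pp.shannon_entropy(t) == 0.0

    def test_half_black_half_white_is_one_bit(self):
        px = np.zeros((3, 16, 16))
        px[:, :8, :] = 1.0
        assert pp.shannon_entropy(pp.TileRecord(px)) == pytest.approx(1.0)

    def test_uniform_random_approaches_eight_bits(self, rng):
        px = np.repeat(rng.random((1, 256, 256)), 3, axis=0)
        ent = pp.shannon_entropy(pp.TileRecord(px))
        assert 7.9 < ent <= 8.0

    def test_matches_skimage_on_grayscale(self, rng):
        """Independent oracle: skimage entropy of the same 8-bit luma image."""
        gray = (rng.random((64, 64)) * 255).round().astype(np.uint8)
        px = np.repeat(gray[None] / 255.0, 3, axis=0)
        ours = pp.shannon_entropy(pp.TileRecord(px))
        assert ours == pytest.approx(skimage_entropy(gray), abs=1e-9)

    def test_permutation_invariance(self, rng):
        px = rng.random((3, 16, 16))
        perm = rng.permutation(16 * 16)
        px_perm = px.reshape(3, -1)[:, perm].reshape(3, 16, 16)
        # luma permutes with the pixels, so the histogram is unchanged
        a = pp.shannon_entropy(pp.TileRecord(px))
        b = pp.shannon_entropy(pp.TileRecord(px_perm))
        assert a == pytest.approx(b, abs=1e-12)


class TestEntropyFilter:
    @pytest.mark.parametrize("entropy,threshold,expected", [
        (0.0, 2.0, False),
        (5.1, 2.0, True),
        (2.0, 2.0, True),   # inclusive boundary
    ])
    def test_threshold_rule(self, entropy, threshold, expected):
        t = pp.TileRecord(np.zeros((3, 4, 4)), entropy_bits=entropy)
        assert pp.passes_entropy_filter(t, threshold) is expected


class TestDownscale:
    def test_quarter_downscale_shape(self):
        t = pp.TileRecord(np.random.default_rng(0).random((3, 1024, 1024)))
        assert pp.downscale(t, 256).pixels.shape == (3, 256, 256)

    def test_identity_when_target_equals_size(self):
        px = np.random.default_rng(1).random((3, 32, 32))
        out = pp.downscale(pp.TileRecord(px), 32)
        assert np.array_equal(out.pixels, px)

    def test_checkerboard_averages_to_half(self):
        px = np.indices((4, 4)).sum(axis=0) % 2
        t = pp.TileRecord(np.repeat(px[None].astype(float), 3, axis=0))
        out = pp.downscale(t, 2)
        assert np.allclose(out.pixels, 0.5)

    def test_chained_equals_direct_for_powers_of_two(self, rng):
        px = rng.random((3, 64, 64))
        once = pp.downscale(pp.TileRecord(px), 16).pixels
        twice = pp.downscale(pp.downscale(pp.TileRecord(px), 32), 16).pixels
        assert np.allclose(once, twice, atol=1e-6)

    def test_upscale_rejected(self):
        with pytest.raises(ValueError):
            pp.downscale(pp.TileRecord(np.zeros((3, 16, 16))), 32)


class TestLabConversion:
    def test_white_and_black_anchor_points(self):
        white = pp.rgb_to_lab(np.ones((1, 1, 3)))
        assert white[0, 0, 0] == pytest.approx(100.0, abs=1e-3)
        assert np.allclose(white[0, 0, 1:], 0.0, atol=0.02)
        black = pp.rgb_to_lab(np.zeros((1, 1, 3)))
        assert black[0, 0, 0] == pytest.approx(0.0, abs=1e-6)

    def test_roundtrip_on_random_colors(self, rng):
        rgb = rng.random((10, 10, 3))
        back = pp.lab_to_rgb(pp.rgb_to_lab(rgb))
        assert np.max(np.abs(back - rgb)) < 1e-3

    def test_channels_first_layout_roundtrip(self, rng):
        rgb = rng.random((3, 8, 8))
        lab = pp.rgb_to_lab(rgb)
        assert lab.shape == (3, 8, 8)
        assert np.max(np.abs(pp.lab_to_rgb(lab) - rgb)) < 1e-3

    def test_out_of_range_clamps_with_warning(self):
        with pytest.warns(UserWarning):
            pp.rgb_to_lab(np.full((2, 2, 3), 1.5))


class TestChannelStats:
    def test_constant_tile(self):
        t = pp.TileRecord(np.full((3, 8, 8), 0.25))
        s = pp.compute_channel_stats([t], space="rgb")
        assert np.allclose(s.mean, 0.25) and np.allclose(s.std, 0.0)
        assert np.allclose(s.min, 0.25) and np.allclose(s.max, 0.25)

    def test_two_constant_tiles_average(self):
        t1 = pp.TileRecord(np.full((3, 8, 8), 0.2))
        t2 = pp.TileRecord(np.full((3, 8, 8), 0.6))
        s = pp.compute_channel_stats([t1, t2], space="rgb")
        assert np.allclose(s.mean, 0.4)

    def test_matches_bruteforce_accumulation(self, rng):
        """Oracle: naive per-pixel two-pass loop over the concatenated data."""
        tiles = [pp.TileRecord(rng.random((3, 8, 8))) for _ in range(4)]
        s = pp.compute_channel_stats(tiles, space="lab")
        all_px = np.concatenate(
            [pp.rgb_to_lab(t.pixels).reshape(3, -1) for t in tiles], axis=1)
        assert np.allclose(s.mean, all_px.mean(axis=1), atol=1e-6)
        assert np.allclose(s.std, all_px.std(axis=1), atol=1e-6)
        assert np.allclose(s.min, all_px.min(axis=1), atol=1e-12)
        assert np.allclose(s.max, all_px.max(axis=1), atol=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            pp.compute_channel_stats([])

    def test_json_roundtrip(self, rng):
        tiles = [pp.TileRecord(rng.random((3, 4, 4)))]
        s = pp.compute_channel_stats(tiles)
        s2 = pp.ChannelStats.from_json(s.to_json())
        assert np.allclose(s.mean, s2.mean) and np.allclose(s.max, s2.max)


class TestModelRange:
    STATS = pp.ChannelStats(mean=np.array([50.0, 0.0, 0.0]),
                            std=np.ones(3),
                            min=np.array([0.0, -40.0, -50.0]),
                            max=np.array([100.0, 60.0, 50.0]))

    def test_endpoints_and_midpoint(self):
        img = np.stack([np.full((2, 2), v) for v in self.STATS.min])
        assert np.allclose(pp.to_model_range(img, self.STATS), -1.0)
        img = np.stack([np.full((2, 2), v) for v in self.STATS.max])
        assert np.allclose(pp.to_model_range(img, self.STATS), 1.0)
        mid = np.stack([np.full((2, 2), (lo + hi) / 2)
                        for lo, hi in zip(self.STATS.min, self.STATS.max)])
        assert np.allclose(pp.to_model_range(mid, self.STATS), 0.0)

    def test_degenerate_channel_rejected(self):
        bad = pp.ChannelStats(mean=np.zeros(3), std=np.zeros(3),
                              min=np.zeros(3), max=np.zeros(3))
        with pytest.raises(ValueError):
            pp.to_model_range(np.zeros((3, 2, 2)), bad)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_roundtrip_and_range_property(self, seed):
        r = np.random.default_rng(seed)
        span = self.STATS.max - self.STATS.min
        img = (self.STATS.min[:, None, None]
               + span[:, None, None] * r.random((3, 4, 4)))
        norm = pp.to_model_range(img, self.STATS)
        assert norm.min() >= -1.0 and norm.max() <= 1.0
        back = pp.from_model_range(norm, self.STATS)
        assert np.max(np.abs(back - img)) < 1e-6


class TestPreprocessImage:
    def test_pipeline_keeps_tissue_drops_blank(self, rng):
        from stainshift.synthetic_data import (SyntheticDatasetSpec, render_he,
                                               sample_structure)
        spec = SyntheticDatasetSpec(tile_size=64)
        tissue = render_he(sample_structure(64, 64, spec, 1), 2)
        blank = np.ones((64, 64, 3)) * 0.99
        img = np.concatenate([tissue, blank], axis=1)   # 64 x 128
        tiles = pp.preprocess_image(img, tile_size=64, train_size=32,
                                    entropy_min=3.0)
        assert len(tiles) == 1
        assert tiles[0].pixels.shape == (3, 32, 32)
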