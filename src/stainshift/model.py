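"""Generators, discriminators and differentiable post-processing.

Each generator is an encoder -> latent-transform -> decoder network. The
encoder consumes the image plus an interpretable hard-mask channel (all-ones
at inference) and produces skip features at every level; the latent transform
is a stack of residual blocks whose *first convolution* is the designated
interpretable latent layer — its weights feed the closed-form editing module.
The decoder merges its two bottom-most levels with the encoder skips through
convolutional (non-local) attention with aggressive channel reduction, keeps
a learnable-weight additive skip everywhere, and ends in tanh scaled by a
trainable luminance multiplier so outputs live in the tanh-normalised CIELAB
model range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from . import nn
from .autodiff import Tensor


@dataclass
class GeneratorConfig:
    """Architecture of one generator.

    ``widths`` are the encoder channel counts from the full-resolution level
    down to the bottom; the two bottom-most decoder merges use attention with
    ``attention_reductions`` = (bottom, second-bottom) channel reductions.
    Defaults follow the full-scale network: bottom widths 256/128 with
    reductions 64/32, i.e. 4 attention channels at both levels.
    """

    widths: tuple[int, ...] = (64, 128, 256)
    latent_blocks: int = 2
    attention_reductions: tuple[int, int] = (64, 32)
    skip_weight_init: float = 1.0
    luminance_multiplier_init: float = 1.0
    mask_channel: bool = True
    tile_size: int = 256

    def validate(self):
        if len(self.widths) < 3:
            raise ValueError("need at least 3 encoder levels")
        r0, r1 = self.attention_reductions
        if self.widths[-1] % r0 != 0:
            raise ValueError(
                f"bottom width {self.widths[-1]} not divisible by reduction {r0}")
        if self.widths[-2] % r1 != 0:
            raise ValueError(
                f"second-bottom width {self.widths[-2]} not divisible by reduction {r1}")
        if self.tile_size % self.downsample_factor != 0:
            raise ValueError("tile size must be divisible by the downsample factor")
        return self

    @property
    def downsample_factor(self) -> int:
        return 2 ** (len(self.widths) - 1)

    @property
    def attention_channels(self) -> tuple[int, int]:
        """Internal attention channel count at (bottom, second-bottom) merges."""
        return (self.widths[-1] // self.attention_reductions[0],
                self.widths[-2] // self.attention_reductions[1])

    @classmethod
    def tiny(cls, tile_size: int = 64) -> "GeneratorConfig":
        """Desk-scale configuration for CPU smoke training (< 100k parameters)."""
        return cls(widths=(6, 8, 12, 16), latent_blocks=1,
                   attention_reductions=(4, 3), tile_size=tile_size)


@dataclass
class DiscriminatorConfig:
    widths: tuple[int, ...] = (64, 128, 256)
    tile_size: int = 256

    @classmethod
    def tiny(cls, tile_size: int = 64) -> "DiscriminatorConfig":
        return cls(widths=(8, 16), tile_size=tile_size)


@dataclass
class LatentTensor:
    """Activations from a generator stage, tagged with provenance."""

    activations: Tensor
    stage: str       # "encoder" | "latent-transform"
    direction: str   # "AB" | "BA"

    @property
    def shape(self):
        return self.activations.shape


@dataclass
class GeneratorOutputs:
    fake: Tensor
    encoder_latent: LatentTensor
    transformed_latent: LatentTensor
    attention_maps: list | None = None
    skips: list | None = None


class AttentionMerge(nn.Module):
    """Non-local attention merging of a decoder feature map with a skip.

    Query comes from the decoder path, key/value from the encoder skip;
    query/key are projected down to ``channels/reduction`` channels. The
    attention output (1x1 output projection, no bias) is added to the decoder
    path together with a learnable-scalar-weighted plain skip:

        out = dec + out_proj(attn(q(dec), k(skip)) @ v(skip)) + w_skip * skip
    """

    def __init__(self, channels: int, reduction: int, rng,
                 skip_weight_init: float = 1.0):
        if channels % reduction != 0:
            raise ValueError(f"channels {channels} not divisible by reduction {reduction}")
        inner = channels // reduction
        self.inner = inner
        self.query = nn.Conv2d(channels, inner, 1, rng, bias=True)
        self.key = nn.Conv2d(channels, inner, 1, rng, bias=True)
        self.value = nn.Conv2d(channels, channels, 1, rng, bias=True)
        self.out = nn.Conv2d(channels, channels, 1, rng, bias=False)
        self.skip_weight = ad.parameter(skip_weight_init)

    def forward(self, dec, skip, return_map: bool = False):
        B, C, H, W = dec.shape
        N = H * W
        q = ad.reshape(self.query(dec), (B, self.inner, N))
        k = ad.reshape(self.key(skip), (B, self.inner, N))
        energy = ad.matmul(ad.transpose(q, (0, 2, 1)), k)       # [B, N, N]
        attn = ad.softmax(energy, axis=-1)
        v = ad.reshape(self.value(skip), (B, C, N))
        o = ad.matmul(v, ad.transpose(attn, (0, 2, 1)))          # [B, C, N]
        o = self.out(ad.reshape(o, (B, C, H, W)))
        merged = dec + o + self.skip_weight * skip
        if return_map:
            return merged, attn
        return merged


class ConvBlock(nn.Module):
    def __init__(self, c_in, c_out, rng, stride=1, kernel=3):
        self.conv = nn.Conv2d(c_in, c_out, kernel, rng, stride=stride)
        self.norm = nn.InstanceNorm2d(c_out)
        self.act = nn.LeakyReLU(0.2)

    def forward(self, x):
        return self.act(self.norm(self.conv(x)))


class ResidualLatentBlock(nn.Module):
    """Residual block at the latent level; ``conv1`` is the interpretable layer
    of the first block in the stack."""

    def __init__(self, channels, rng):
        self.conv1 = nn.Conv2d(channels, channels, 3, rng)
        self.norm1 = nn.InstanceNorm2d(channels)
        self.act = nn.LeakyReLU(0.2)
        self.conv2 = nn.Conv2d(channels, channels, 3, rng)
        self.norm2 = nn.InstanceNorm2d(channels)

    def forward(self, x, edit_fn=None):
        h = self.conv1(x)
        if edit_fn is not None:
            h = edit_fn(h)   # activations "just past" the interpretable conv
        h = self.act(self.norm1(h))
        h = self.norm2(self.conv2(h))
        return x + h


class Generator(nn.Module):

    INTERPRETABLE_LAYER = "latent.0.conv1"

    def __init__(self, config: GeneratorConfig, rng: np.random.Generator,
                 direction: str = "AB"):
        config.validate()
        self.config = config
        self.direction = direction
        w = config.widths
        in_ch = 3 + (1 if config.mask_channel else 0)
        self.stem = ConvBlock(in_ch, w[0], rng)
        self.downs = [ConvBlock(w[i], w[i + 1], rng, stride=2)
                      for i in range(len(w) - 1)]
        self.latent = [ResidualLatentBlock(w[-1], rng)
                       for _ in range(config.latent_blocks)]
        r0, r1 = config.attention_reductions
        self.merge_bottom = AttentionMerge(w[-1], r0, rng, config.skip_weight_init)
        self.merge_second = AttentionMerge(w[-2], r1, rng, config.skip_weight_init)
        self.ups = [ConvBlock(w[i + 1], w[i], rng) for i in reversed(range(len(w) - 1))]
        self.plain_skip_weights = [ad.parameter(config.skip_weight_init)
                                   for _ in range(len(w) - 2)]
        self.out_conv = nn.Conv2d(w[0], 3, 3, rng)
        self.lum_mult = ad.parameter(config.luminance_multiplier_init)
        # constant selector for the L* channel
        self._lum_sel = np.zeros((1, 3, 1, 1), dtype=np.float32)
        self._lum_sel[0, 0] = 1.0

    # -- stages -----------------------------------------------------------

    def encode(self, image, mask=None):
        """G_enc: image (+ hard-mask channel) -> bottom latent + skips."""
        x = image if isinstance(image, Tensor) else Tensor(np.asarray(image, np.float32))
        if x.ndim != 4 or x.shape[1] != 3:
            raise ValueError(f"expected NCHW RGB-like input, got {x.shape}")
        if x.shape[2] != self.config.tile_size or x.shape[3] != self.config.tile_size:
            raise ValueError(
                f"expected {self.config.tile_size}px tiles, got {x.shape[2:]}")
        if self.config.mask_channel:
            if mask is None:
                mask = Tensor(np.ones((x.shape[0], 1, *x.shape[2:]), dtype=np.float32))
            elif not isinstance(mask, Tensor):
                mask = Tensor(np.asarray(mask, np.float32))
            x = ad.concat([x, mask], axis=1)
        skips = [self.stem(x)]
        for down in self.downs:
            skips.append(down(skips[-1]))
        latent = skips.pop()   # bottom representation
        return LatentTensor(latent, "encoder", self.direction), skips

    def transform_latent(self, latent: LatentTensor, edit_fn=None) -> LatentTensor:
        """G_conv: latent transformation (shape-preserving residual stack)."""
        h = latent.activations if isinstance(latent, LatentTensor) else latent
        for i, block in enumerate(self.latent):
            h = block(h, edit_fn=edit_fn if i == 0 else None)
        return LatentTensor(h, "latent-transform", self.direction)

    def decode(self, transformed: LatentTensor, encoder_latent: LatentTensor,
               skips: list, return_attention: bool = False):
        """Decoder with attention merges at the two bottom-most levels."""
        if len(skips) != len(self.config.widths) - 1:
            raise ValueError("missing skip features")
        zt = transformed.activations if isinstance(transformed, LatentTensor) else transformed
        z = encoder_latent.activations if isinstance(encoder_latent, LatentTensor) else encoder_latent
        maps = []
        h, m = self.merge_bottom(zt, z, return_map=True)
        maps.append(m)
        h = self.ups[0](ad.upsample2x(h))
        h, m = self.merge_second(h, skips[-1], return_map=True)
        maps.append(m)
        for i, up in enumerate(self.ups[1:]):
            h = up(ad.upsample2x(h))
            h = h + self.plain_skip_weights[i] * skips[-2 - i]
        out = ad.tanh(self.out_conv(h))
        # trainable luminance multiplier applied to the L* channel only
        scale = Tensor(self._lum_sel) * self.lum_mult + Tensor(1.0 - self._lum_sel)
        out = out * scale
        if return_attention:
            return out, maps
        return out

    def forward(self, image, mask=None, edit_fn=None,
                return_attention: bool = False) -> GeneratorOutputs:
        enc, skips = self.encode(image, mask)
        zt = self.transform_latent(enc, edit_fn=edit_fn)
        out = self.decode(zt, enc, skips, return_attention=return_attention)
        fake, maps = out if return_attention else (out, None)
        return GeneratorOutputs(fake=fake, encoder_latent=enc,
                                transformed_latent=zt,
                                attention_maps=maps, skips=skips)

    @property
    def interpretable_layer(self) -> nn.Conv2d:
        return self.layer_by_name(self.INTERPRETABLE_LAYER)


class Discriminator(nn.Module):
    """Patch-level least-squares discriminator producing a realness score map."""

    def __init__(self, config: DiscriminatorConfig, rng: np.random.Generator):
        self.config = config
        chans = [3, *config.widths]
        self.blocks = []
        for i in range(len(chans) - 1):
            self.blocks.append(nn.Conv2d(chans[i], chans[i + 1], 4, rng,
                                         stride=2, padding=1))
        self.act = nn.LeakyReLU(0.2)
        self.head = nn.Conv2d(chans[-1], 1, 3, rng)

    def forward(self, x):
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, np.float32))
        for blk in self.blocks:
            x = self.act(blk(x))
        return self.head(x)


@dataclass
class ModelBundle:
    """Both generators, both discriminators and their shared configs."""

    g_ab: Generator
    g_ba: Generator
    d_a: Discriminator
    d_b: Discriminator
    gen_config: GeneratorConfig = field(default=None)
    disc_config: DiscriminatorConfig = field(default=None)

    def networks(self) -> dict:
        return {"g_ab": self.g_ab, "g_ba": self.g_ba,
                "d_a": self.d_a, "d_b": self.d_b}


def build_models(gen_config: GeneratorConfig | None = None,
                 disc_config: DiscriminatorConfig | None = None,
                 seed: int = 0) -> ModelBundle:
    """Instantiate all four networks with seeded weights and check that the
    encoder / latent-transform outputs of both generators share one shape
    (required for the context loss to be well-formed)."""
    gen_config = (gen_config or GeneratorConfig()).validate()
    disc_config = disc_config or DiscriminatorConfig(tile_size=gen_config.tile_size)
    ss = np.random.SeedSequence(seed)
    rngs = [np.random.default_rng(s) for s in ss.spawn(4)]
    bundle = ModelBundle(
        g_ab=Generator(gen_config, rngs[0], "AB"),
        g_ba=Generator(gen_config, rngs[1], "BA"),
        d_a=Discriminator(disc_config, rngs[2]),
        d_b=Discriminator(disc_config, rngs[3]),
        gen_config=gen_config, disc_config=disc_config)
    s = gen_config.tile_size // gen_config.downsample_factor
    latent_shape = (gen_config.widths[-1], s, s)
    # identical by construction for both stages of both generators
    bundle.latent_shape = latent_shape
    return bundle


# ---------------------------------------------------------------------------
# differentiable guided post-processing
# ---------------------------------------------------------------------------

def _offsets(kernel_size: int):
    r = kernel_size // 2
    return [(dy, dx) for dy in range(-r, r + 1) for dx in range(-r, r + 1)]


def joint_bilateral_blur(image, guide: np.ndarray, kernel_size: int = 5,
                         sigma_space: float = 1.5, sigma_range: float = 0.15):
    """Edge-preserving blur of ``image`` with the range kernel driven by ``guide``.

    The guide is a constant (non-differentiated) NCHW array; with the guide
    fixed the filter is linear in the image, so gradients flow through plain
    shift-and-sum operations.
    """
    x = image if isinstance(image, Tensor) else Tensor(np.asarray(image, np.float32))
    g = np.asarray(guide, dtype=np.float32)
    if g.shape != x.shape:
        raise ValueError("image and guide must share shape")
    H, W = x.shape[-2:]
    num = None
    den = np.zeros((x.shape[0], 1, H, W), dtype=np.float32)
    for dy, dx in _offsets(kernel_size):
        ws = np.exp(-(dy * dy + dx * dx) / (2.0 * sigma_space ** 2)).astype(np.float32)
        gs = np.zeros_like(g)
        m = ad.shift2d_valid_mask((H, W), dy, dx)
        ys_d = slice(max(-dy, 0), H - max(dy, 0) or None)
        ys_s = slice(max(dy, 0), H - max(-dy, 0) or None)
        xs_d = slice(max(-dx, 0), W - max(dx, 0) or None)
        xs_s = slice(max(dx, 0), W - max(-dx, 0) or None)
        gs[..., ys_d, xs_d] = g[..., ys_s, xs_s]
        rdiff = ((g - gs) ** 2).sum(axis=1, keepdims=True)
        wgt = ws * np.exp(-rdiff / (2.0 * sigma_range ** 2)) * m
        term = ad.shift2d(x, dy, dx) * Tensor(wgt)
        num = term if num is None else num + term
        den += wgt
    return num * Tensor(1.0 / den)


def gaussian_blur(image, kernel_size: int = 5, sigma: float = 1.0):
    """Spatial Gaussian blur with border renormalisation (constant-preserving)."""
    x = image if isinstance(image, Tensor) else Tensor(np.asarray(image, np.float32))
    H, W = x.shape[-2:]
    num = None
    den = np.zeros((H, W), dtype=np.float32)
    for dy, dx in _offsets(kernel_size):
        ws = np.float32(np.exp(-(dy * dy + dx * dx) / (2.0 * sigma ** 2)))
        m = ad.shift2d_valid_mask((H, W), dy, dx) * ws
        term = ad.shift2d(x, dy, dx) * Tensor(m)
        num = term if num is None else num + term
        den += m
    return num * Tensor(1.0 / den)


def unsharp_mask(image, amount: float = 0.5, kernel_size: int = 5,
                 sigma: float = 1.0):
    """Sharpen: image + amount * (image - gaussian_blur(image))."""
    x = image if isinstance(image, Tensor) else Tensor(np.asarray(image, np.float32))
    if amount == 0.0 or kernel_size <= 1:
        return x
    return x + amount * (x - gaussian_blur(x, kernel_size, sigma))


def guided_postprocess(image, guide, kernel_size: int = 5,
                       sigma_space: float = 1.5, sigma_range: float = 0.15,
                       unsharp_amount: float = 0.5, unsharp_sigma: float = 1.0):
    """Joint-bilateral blur guided by the generator input, then unsharp mask.

    Fully differentiable with respect to ``image``; identity when
    ``kernel_size == 1`` and ``unsharp_amount == 0``.
    """
    x = image if isinstance(image, Tensor) else Tensor(np.asarray(image, np.float32))
    g = guide.data if isinstance(guide, Tensor) else np.asarray(guide, np.float32)
    if kernel_size > 1:
        x = joint_bilateral_blur(x, g, kernel_size, sigma_space, sigma_range)
    return unsharp_mask(x, unsharp_amount, kernel_size, unsharp_sigma)
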