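"""Training objectives.

The centrepiece is the context-preserving loss: four Huber penalties that tie
the *encoder* output of one generator to the *latent-transform* output of the
opposite-direction generator, evaluated on real and translated images. With
G_enc^AB / G_conv^AB the encoder and latent-transform of the A->B generator,
A a real domain-A image, B' = G^AB(A) the translated image (and symmetrically
for B, A'):

    C_alpha = H(G_enc^AB(A),  G_conv^BA(B'))
    C_beta  = H(G_conv^AB(A), G_enc^BA(B'))
    C_gamma = H(G_enc^BA(B),  G_conv^AB(A'))
    C_delta = H(G_conv^BA(B), G_enc^AB(A'))

    L_context = (C_alpha + C_beta)/2 * gamma_A + (C_gamma + C_delta)/2 * gamma_B

forcing all style change into the latent transformation while the encoders
agree on structure. Standard CycleGAN terms (least-squares adversarial, L1
cycle and identity) and the explainability mechanism — discriminator saliency
maps gating generator gradients — live here too.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


@dataclass
class LossWeights:
    """Loss weighting; gamma_a/gamma_b weight the two context-loss directions."""

    gamma_a: float = 5.0
    gamma_b: float = 5.0
    huber_delta: float = 1.0
    cycle: float = 10.0
    adversarial: float = 1.0
    identity: float = 5.0

    def validate(self):
        if min(self.gamma_a, self.gamma_b, self.cycle,
               self.adversarial, self.identity) < 0:
            raise ValueError("loss weights must be non-negative")
        if self.huber_delta <= 0:
            raise ValueError("huber_delta must be positive")
        return self


@dataclass
class ContextLossTerms:
    """The four Huber terms and their weighted total."""

    c_alpha: float | Tensor
    c_beta: float | Tensor
    c_gamma: float | Tensor
    c_delta: float | Tensor
    total: float | Tensor

    def as_floats(self) -> "ContextLossTerms":
        f = lambda v: v.item() if isinstance(v, Tensor) else float(v)
        return ContextLossTerms(*(f(getattr(self, k)) for k in
                                  ("c_alpha", "c_beta", "c_gamma", "c_delta", "total")))


def huber(x, y, delta: float = 1.0):
    """Mean elementwise Huber loss: 0.5 d^2 for |d| <= delta, else delta(|d| - delta/2).

    NumPy arrays in -> float out; Tensors in -> scalar Tensor (differentiable).
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    if isinstance(x, Tensor) or isinstance(y, Tensor):
        return ad.huber_mean(x, y, delta)
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch {x.shape} vs {y.shape}")
    d = x - y
    a = np.abs(d)
    return float(np.where(a <= delta, 0.5 * d * d, delta * (a - 0.5 * delta)).mean())


def context_loss(enc_ab_of_a, conv_ba_of_bfake,
                 conv_ab_of_a, enc_ba_of_bfake,
                 enc_ba_of_b, conv_ab_of_afake,
                 conv_ba_of_b, enc_ab_of_afake,
                 weights: LossWeights) -> ContextLossTerms:
    """Compute the four context terms and their gamma-weighted total."""
    shapes = {tuple(np.shape(t.data if isinstance(t, Tensor) else t)) for t in (
        enc_ab_of_a, conv_ba_of_bfake, conv_ab_of_a, enc_ba_of_bfake,
        enc_ba_of_b, conv_ab_of_afake, conv_ba_of_b, enc_ab_of_afake)}
    if len(shapes) != 1:
        raise ValueError(f"all eight latents must share one shape, got {shapes}")
    d = weights.huber_delta
    ca = huber(enc_ab_of_a, conv_ba_of_bfake, d)
    cb = huber(conv_ab_of_a, enc_ba_of_bfake, d)
    cg = huber(enc_ba_of_b, conv_ab_of_afake, d)
    cd = huber(conv_ba_of_b, enc_ab_of_afake, d)
    total = (ca + cb) * (0.5 * weights.gamma_a) + (cg + cd) * (0.5 * weights.gamma_b)
    return ContextLossTerms(ca, cb, cg, cd, total)


def cycle_loss(real, cycled):
    """L1 reconstruction penalty for A -> B -> A round trips."""
    if isinstance(real, Tensor) or isinstance(cycled, Tensor):
        return ad.l1_mean(real, cycled)
    real = np.asarray(real, dtype=np.float64)
    cycled = np.asarray(cycled, dtype=np.float64)
    if real.shape != cycled.shape:
        raise ValueError(f"shape mismatch {real.shape} vs {cycled.shape}")
    return float(np.abs(real - cycled).mean())


def identity_loss(real, same_domain_output):
    """L1 penalty for passing an image through its own-domain generator."""
    return cycle_loss(real, same_domain_output)


def adversarial_loss(scores, target_real: bool):
    """Least-squares GAN loss against a constant 1 (real) / 0 (fake) target."""
    t = 1.0 if target_real else 0.0
    if isinstance(scores, Tensor):
        d = scores - t
        return ad.mean(d * d)
    s = np.asarray(scores, dtype=np.float64)
    return float(((s - t) ** 2).mean())


@dataclass
class SaliencyMask:
    """Discriminator input-gradient magnitude, max-normalised to [0, 1]."""

    values: np.ndarray

    def validate(self):
        if self.values.min() < 0 or self.values.max() > 1:
            raise ValueError("saliency mask must lie in [0,1]")
        return self


def saliency_mask(discriminator, fake_image) -> SaliencyMask:
    """|d mean-score / d image|, normalised by its maximum (zero-safe)."""
    data = fake_image.data if isinstance(fake_image, Tensor) else np.asarray(fake_image)
    x = Tensor(np.asarray(data, dtype=np.float32), requires_grad=True)
    score = ad.mean(discriminator(x))
    score.backward()
    g = np.abs(x.grad)
    m = g.max()
    values = g / m if m > 0 else np.zeros_like(g)
    return SaliencyMask(values=values).validate()


def apply_gradient_mask(gradient: np.ndarray, mask: SaliencyMask | np.ndarray) -> np.ndarray:
    """Elementwise gate: masked-out (zero) positions carry exactly zero gradient."""
    m = mask.values if isinstance(mask, SaliencyMask) else np.asarray(mask)
    g = np.asarray(gradient)
    if g.shape != m.shape:
        raise ValueError(f"shape mismatch {g.shape} vs {m.shape}")
    return g * m
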