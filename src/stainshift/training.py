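"""Alternating GAN optimisation with saliency-masked generator gradients.

Each step updates the two discriminators on real/fake pairs (least-squares
targets), then jointly updates both generators on adversarial + cycle +
identity + context-preserving losses. Before the generator backward pass the
discriminators' input-saliency maps are attached as gradient gates on the
fake images, so generator learning concentrates on the regions the
discriminators actually attend to. The whole fit is a pure function of
(config, data): seeded weight init, seeded batch order, resumable
checkpoints.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import objectives as obj
from .autodiff import Tensor
from .model import (DiscriminatorConfig, GeneratorConfig, ModelBundle,
                    build_models, guided_postprocess)
from .nn import Adam


class TrainingDiverged(RuntimeError):
    pass


@dataclass
class TrainConfig:
    steps: int = 400
    batch_size: int = 1
    lr_generator: float = 2e-4
    lr_discriminator: float = 2e-4
    betas: tuple[float, float] = (0.5, 0.999)
    seed: int = 0
    checkpoint_every: int = 200
    tile_size: int = 64
    weights: obj.LossWeights = field(default_factory=obj.LossWeights)
    gen_config: GeneratorConfig = None
    disc_config: DiscriminatorConfig = None
    postprocess: bool = True
    pp_kernel: int = 3
    pp_sigma_space: float = 1.0
    pp_sigma_range: float = 0.3
    pp_unsharp_amount: float = 0.3
    context_detach_real: bool = False   # stop-gradient on the real-image latents

    def validate(self):
        if self.steps < 1 or self.batch_size < 1:
            raise ValueError("steps and batch size must be >= 1")
        if self.lr_generator <= 0 and self.lr_generator != 0:
            raise ValueError("learning rates must be non-negative")
        self.weights.validate()
        return self

    def resolved_gen_config(self) -> GeneratorConfig:
        return self.gen_config or GeneratorConfig.tiny(self.tile_size)

    def resolved_disc_config(self) -> DiscriminatorConfig:
        return self.disc_config or DiscriminatorConfig.tiny(self.tile_size)

    @classmethod
    def smoke(cls, seed: int = 0, steps: int = 400) -> "TrainConfig":
        """The desk-scale regime: 64px tiles, tiny nets, 400 steps."""
        return cls(steps=steps, seed=seed, tile_size=64)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["gen_config"] = dataclasses.asdict(self.resolved_gen_config())
        d["disc_config"] = dataclasses.asdict(self.resolved_disc_config())
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        d = dict(d)
        gc = d.pop("gen_config", None)
        dc = d.pop("disc_config", None)
        w = d.pop("weights", None)
        cfg = cls(**{k: (tuple(v) if k == "betas" else v) for k, v in d.items()})
        if gc:
            gc = {k: (tuple(v) if isinstance(v, list) else v) for k, v in gc.items()}
            cfg.gen_config = GeneratorConfig(**gc)
        if dc:
            dc = {k: (tuple(v) if isinstance(v, list) else v) for k, v in dc.items()}
            cfg.disc_config = DiscriminatorConfig(**dc)
        if w:
            cfg.weights = obj.LossWeights(**w)
        return cfg


@dataclass
class TrainState:
    step: int
    metrics: list[dict]
    checkpoint_paths: list[str]
    models: ModelBundle
    optimizers: dict
    rng: np.random.Generator


METRIC_KEYS = ("step", "loss_d_a", "loss_d_b", "loss_adv", "loss_cycle",
               "loss_identity", "c_alpha", "c_beta", "c_gamma", "c_delta",
               "context_total", "loss_g_total")


def _postprocess(cfg: TrainConfig, fake, guide):
    if not cfg.postprocess:
        return fake
    return guided_postprocess(fake, guide, kernel_size=cfg.pp_kernel,
                              sigma_space=cfg.pp_sigma_space,
                              sigma_range=cfg.pp_sigma_range,
                              unsharp_amount=cfg.pp_unsharp_amount)


def train_step(batch_a: np.ndarray, batch_b: np.ndarray, models: ModelBundle,
               optimizers: dict, weights: obj.LossWeights,
               cfg: TrainConfig | None = None,
               generator_directions=("AB", "BA")) -> dict:
    """One alternating update; returns a record of every loss term.

    ``generator_directions`` restricts which generators' optimizers step
    (debug aid for gradient-isolation checks); discriminators always update.
    """
    cfg = cfg or TrainConfig()
    w = weights.validate()
    g_ab, g_ba, d_a, d_b = models.g_ab, models.g_ba, models.d_a, models.d_b
    A = Tensor(np.asarray(batch_a, np.float32))
    B = Tensor(np.asarray(batch_b, np.float32))

    # -- forward translations -------------------------------------------
    out_ab = g_ab.forward(A)                         # A -> B'
    out_ba = g_ba.forward(B)                         # B -> A'
    fake_b = _postprocess(cfg, out_ab.fake, A.data)
    fake_a = _postprocess(cfg, out_ba.fake, B.data)

    # -- discriminators ---------------------------------------------------
    rec = {}
    for name, disc, real, fake in (("loss_d_a", d_a, A, fake_a),
                                   ("loss_d_b", d_b, B, fake_b)):
        opt = optimizers[name.replace("loss_", "")]
        loss = 0.5 * (obj.adversarial_loss(disc(real), True)
                      + obj.adversarial_loss(disc(fake.detach()), False))
        disc.zero_grad()
        loss.backward()
        opt.step()
        disc.zero_grad()
        rec[name] = loss.item()

    # -- saliency gates on the fake images --------------------------------
    fake_b.grad_hook = _make_hook(obj.saliency_mask(d_b, fake_b).values)
    fake_a.grad_hook = _make_hook(obj.saliency_mask(d_a, fake_a).values)

    # -- generator losses --------------------------------------------------
    adv = obj.adversarial_loss(d_b(fake_b), True) + obj.adversarial_loss(d_a(fake_a), True)
    cyc_ba = g_ba.forward(fake_b)                    # B' -> A_cyc
    cyc_ab = g_ab.forward(fake_a)                    # A' -> B_cyc
    cycle = obj.cycle_loss(A, cyc_ba.fake) + obj.cycle_loss(B, cyc_ab.fake)
    idt = obj.identity_loss(B, g_ab.forward(B).fake) + obj.identity_loss(A, g_ba.forward(A).fake)

    det = (lambda t: t.detach()) if cfg.context_detach_real else (lambda t: t)
    ctx = obj.context_loss(
        det(out_ab.encoder_latent.activations), cyc_ba.transformed_latent.activations,
        det(out_ab.transformed_latent.activations), cyc_ba.encoder_latent.activations,
        det(out_ba.encoder_latent.activations), cyc_ab.transformed_latent.activations,
        det(out_ba.transformed_latent.activations), cyc_ab.encoder_latent.activations,
        w)

    g_total = (w.adversarial * adv + w.cycle * cycle + w.identity * idt + ctx.total)
    g_ab.zero_grad()
    g_ba.zero_grad()
    g_total.backward()
    for direction in generator_directions:
        optimizers[f"g_{direction.lower()}"].step()
    g_ab.zero_grad()
    g_ba.zero_grad()

    ctx_f = ctx.as_floats()
    rec.update(loss_adv=adv.item(), loss_cycle=cycle.item(), loss_identity=idt.item(),
               c_alpha=ctx_f.c_alpha, c_beta=ctx_f.c_beta, c_gamma=ctx_f.c_gamma,
               c_delta=ctx_f.c_delta, context_total=ctx_f.total,
               loss_g_total=g_total.item())
    if not all(np.isfinite(v) for v in rec.values()):
        raise TrainingDiverged(f"non-finite loss encountered: {rec}")
    return rec


def _make_hook(mask: np.ndarray):
    def hook(g):
        return g * mask
    return hook


def _make_optimizers(cfg: TrainConfig, models: ModelBundle) -> dict:
    return {
        "g_ab": Adam(models.g_ab.parameters(), cfg.lr_generator, cfg.betas),
        "g_ba": Adam(models.g_ba.parameters(), cfg.lr_generator, cfg.betas),
        "d_a": Adam(models.d_a.parameters(), cfg.lr_discriminator, cfg.betas),
        "d_b": Adam(models.d_b.parameters(), cfg.lr_discriminator, cfg.betas),
    }


def fit(config: TrainConfig, dataset_a: np.ndarray, dataset_b: np.ndarray,
        out_dir=None, resume_from=None) -> TrainState:
    """Run ``config.steps`` alternating updates over model-range tile arrays.

    ``dataset_a`` / ``dataset_b`` are [N, 3, H, W] arrays in [-1, 1]. Writes
    ``metrics.tsv`` and periodic checkpoints when ``out_dir`` is given;
    ``resume_from`` restores weights, optimizer moments, step counter and the
    batch-sampling RNG so a resumed run continues bit-identically.
    """
    config.validate()
    a = np.asarray(dataset_a, np.float32)
    b = np.asarray(dataset_b, np.float32)
    if a.shape[0] == 0 or b.shape[0] == 0:
        raise ValueError("datasets must be non-empty")

    models = build_models(config.resolved_gen_config(),
                          config.resolved_disc_config(), seed=config.seed)
    optimizers = _make_optimizers(config, models)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    start_step = 0
    metrics: list[dict] = []
    if resume_from is not None:
        start_step, metrics = load_checkpoint(resume_from, models, optimizers, rng)

    paths = []
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    for step in range(start_step, config.steps):
        ia = rng.integers(0, a.shape[0], size=config.batch_size)
        ib = rng.integers(0, b.shape[0], size=config.batch_size)
        rec = train_step(a[ia], b[ib], models, optimizers, config.weights, config)
        rec = {"step": step, **rec}
        metrics.append(rec)
        if out is not None and ((step + 1) % config.checkpoint_every == 0
                                or step + 1 == config.steps):
            p = out / f"checkpoint_{step + 1:06d}.npz"
            save_checkpoint(p, models, optimizers, config, step + 1, rng, metrics)
            paths.append(str(p))
    if out is not None:
        write_metrics_tsv(out / "metrics.tsv", metrics)
    return TrainState(step=config.steps, metrics=metrics, checkpoint_paths=paths,
                      models=models, optimizers=optimizers, rng=rng)


def write_metrics_tsv(path, metrics: list[dict]):
    with open(path, "w") as fh:
        fh.write("\t".join(METRIC_KEYS) + "\n")
        for rec in metrics:
            fh.write("\t".join(f"{rec[k]:.8g}" if k != "step" else str(rec[k])
                               for k in METRIC_KEYS) + "\n")


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(path, models: ModelBundle, optimizers: dict,
                    config: TrainConfig, step: int, rng: np.random.Generator,
                    metrics: list[dict] | None = None,
                    channel_stats=None):
    arrays = {}
    for net_name, net in models.networks().items():
        for k, v in net.state_dict().items():
            arrays[f"net/{net_name}/{k}"] = v
    for opt_name, opt in optimizers.items():
        for k, v in opt.state_dict().items():
            arrays[f"opt/{opt_name}/{k}"] = v
    meta = {"step": step, "config": config.to_dict(),
            "rng_state": rng.bit_generator.state,
            "metrics": metrics or []}
    if channel_stats is not None:
        meta["channel_stats"] = json.loads(channel_stats.to_json())
    arrays["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path, models: ModelBundle, optimizers: dict | None = None,
                    rng: np.random.Generator | None = None):
    """Restore state in place; returns (step, metrics)."""
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(bytes(z["meta"]).decode())
        nets = models.networks()
        for net_name, net in nets.items():
            prefix = f"net/{net_name}/"
            net.load_state_dict({k[len(prefix):]: z[k] for k in z.files
                                 if k.startswith(prefix)})
        if optimizers is not None:
            for opt_name, opt in optimizers.items():
                prefix = f"opt/{opt_name}/"
                opt.load_state_dict({k[len(prefix):]: z[k] for k in z.files
                                     if k.startswith(prefix)})
    if rng is not None:
        rng.bit_generator.state = meta["rng_state"]
    return meta["step"], meta.get("metrics", [])


def load_models_from_checkpoint(path) -> tuple[ModelBundle, TrainConfig, int]:
    """Rebuild networks purely from a checkpoint file."""
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(bytes(z["meta"]).decode())
    config = TrainConfig.from_dict(meta["config"])
    models = build_models(config.resolved_gen_config(),
                          config.resolved_disc_config(), seed=config.seed)
    load_checkpoint(path, models)
    return models, config, meta["step"]


# ---------------------------------------------------------------------------
# data plumbing
# ---------------------------------------------------------------------------

def tiles_to_model_arrays(tiles_a, tiles_b):
    """RGB [0,1] tile lists -> (array_a, array_b, ChannelStats) in model range.

    Channel statistics are pooled over both domains so one tanh range serves
    the whole model.
    """
    from .preprocessing import compute_channel_stats, rgb_to_lab, to_model_range

    stats = compute_channel_stats(list(tiles_a) + list(tiles_b), space="lab")

    def conv(tiles):
        out = []
        for t in tiles:
            px = t if isinstance(t, np.ndarray) else t.pixels
            if px.ndim == 3 and px.shape[0] != 3:
                px = px.transpose(2, 0, 1)
            out.append(to_model_range(rgb_to_lab(px), stats))
        return np.asarray(out, dtype=np.float32)

    return conv(tiles_a), conv(tiles_b), stats
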