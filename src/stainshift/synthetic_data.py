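"""Synthetic unpaired H&E-like and p63-like stain tiles.

Real double-stained breast-tissue slides are not redistributable, so this
module emulates the features the transfer task depends on: a near-white
non-uniform background, smooth blob-shaped tissue regions, nuclei scattered
inside tissue, and the two stain palettes — pink-to-purple tissue with
dark-purple nuclei for H&E, blue counterstained tissue with brown
myoepithelial cells for p63. The two domains can share an underlying
structure field (paired mode, for cycle/context diagnostics) or use disjoint
structures (unpaired mode, the training regime).

Everything is a pure function of (parameters, seed).
"""

from __future__ import annotations

import csv
import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

# palette anchors (RGB in [0,1])
HE_TISSUE_PINK = np.array([0.93, 0.68, 0.80])
HE_TISSUE_PURPLE = np.array([0.55, 0.35, 0.65])
HE_NUCLEUS = np.array([0.28, 0.13, 0.38])
P63_TISSUE_BLUE = np.array([0.55, 0.66, 0.86])
P63_TISSUE_BLUE_DEEP = np.array([0.35, 0.45, 0.75])
P63_NUCLEUS_BLUE = np.array([0.30, 0.38, 0.66])
P63_MYOEP_BROWN = np.array([0.47, 0.29, 0.12])


@dataclass(frozen=True)
class SyntheticDatasetSpec:
    """Parameters of one synthetic dataset draw."""

    n_tiles_per_domain: int = 10
    tile_size: int = 64
    tissue_fraction_range: tuple[float, float] = (0.35, 0.75)
    myoepithelial_fraction: float = 0.3
    background_intensity_jitter: float = 0.02
    nucleus_density: float = 0.004   # nuclei per tissue pixel
    nucleus_radius: float = 2.5
    seed: int = 0
    paired: bool = False

    def validate(self):
        if self.n_tiles_per_domain < 1:
            raise ValueError("n_tiles_per_domain must be >= 1")
        if self.tile_size < 16:
            raise ValueError("tile_size must be >= 16")
        for lo, hi in [self.tissue_fraction_range]:
            if not (0.0 <= lo <= hi <= 1.0):
                raise ValueError("tissue_fraction_range must be an interval in [0,1]")
        if not 0.0 <= self.myoepithelial_fraction <= 1.0:
            raise ValueError("myoepithelial_fraction must lie in [0,1]")
        return self


@dataclass
class StructureField:
    """Stain-independent tissue structure shared by paired renders."""

    width: int
    height: int
    nucleus_centers: np.ndarray      # [N,2] (row, col)
    cell_labels: np.ndarray          # [N] bool, True = myoepithelial
    tissue_mask: np.ndarray          # [H,W] bool
    background_mask: np.ndarray      # [H,W] bool
    seed: int = 0

    @property
    def tissue_fraction(self) -> float:
        return float(self.tissue_mask.mean())


def sample_structure(width: int, height: int, params: SyntheticDatasetSpec,
                     seed: int) -> StructureField:
    """Draw a random structure field: blob tissue mask plus nucleus positions.

    The tissue mask is a smoothed Gaussian noise field thresholded at the
    exact pixel count matching a tissue fraction drawn uniformly from
    ``params.tissue_fraction_range``, which keeps the fraction inside the
    configured interval by construction.
    """
    if width < 16 or height < 16:
        raise ValueError("width and height must be >= 16")
    params.validate()
    rng = np.random.default_rng(seed)
    lo, hi = params.tissue_fraction_range
    target = rng.uniform(lo, hi)
    n_tissue = int(round(target * width * height))

    noise = rng.standard_normal((height, width))
    smooth = ndimage.gaussian_filter(noise, sigma=max(width, height) / 8.0)
    tissue = np.zeros((height, width), dtype=bool)
    if n_tissue > 0:
        order = np.argsort(smooth, axis=None)[::-1][:n_tissue]
        tissue.reshape(-1)[order] = True
    background = ~tissue

    tissue_idx = np.flatnonzero(tissue)
    n_nuclei = int(round(params.nucleus_density * tissue_idx.size))
    if tissue_idx.size > 0 and n_nuclei == 0:
        n_nuclei = 1  # any tissue patch carries at least one nucleus
    if n_nuclei > 0:
        chosen = rng.choice(tissue_idx, size=min(n_nuclei, tissue_idx.size), replace=False)
        centers = np.stack([chosen // width, chosen % width], axis=1)
        labels = rng.random(centers.shape[0]) < params.myoepithelial_fraction
    else:
        centers = np.zeros((0, 2), dtype=np.int64)
        labels = np.zeros(0, dtype=bool)
    return StructureField(width, height, centers, labels, tissue, background, seed)


def _disk_mask(shape, centers, radius) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    if len(centers) == 0:
        return mask
    mask[centers[:, 0], centers[:, 1]] = True
    dist = ndimage.distance_transform_edt(~mask)
    return dist <= radius


def _background(field: StructureField, rng, jitter: float) -> np.ndarray:
    """Near-white background with smooth non-uniform intensity."""
    h, w = field.tissue_mask.shape
    low = ndimage.gaussian_filter(rng.standard_normal((h, w)), sigma=w / 4.0)
    rngspan = low.max() - low.min()
    low = (low - low.min()) / (rngspan if rngspan > 0 else 1.0)
    intensity = 1.0 - jitter * low
    return np.repeat(intensity[:, :, None], 3, axis=2)


def _mix_field(rng, shape, sigma) -> np.ndarray:
    m = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma)
    span = m.max() - m.min()
    return (m - m.min()) / (span if span > 0 else 1.0)


def render_he(field: StructureField, seed: int,
              background_jitter: float = 0.02) -> np.ndarray:
    """Render the field in an H&E-like palette -> RGB float image in [0,1]."""
    rng = np.random.default_rng(seed)
    h, w = field.tissue_mask.shape
    img = _background(field, rng, background_jitter)
    mix = _mix_field(rng, (h, w), sigma=w / 10.0)[:, :, None]
    tissue_color = HE_TISSUE_PINK * (1 - mix) + HE_TISSUE_PURPLE * mix
    t = field.tissue_mask[:, :, None]
    img = np.where(t, tissue_color, img)
    nuc = _disk_mask((h, w), field.nucleus_centers, radius=2.5)[:, :, None]
    img = np.where(nuc & t.astype(bool), HE_NUCLEUS, img)
    img += rng.normal(0.0, 0.008, size=img.shape)  # sensor-like grain
    return np.clip(img, 0.0, 1.0)


def render_p63(field: StructureField, seed: int,
               background_jitter: float = 0.02) -> np.ndarray:
    """Render the field in a p63-like palette: blue tissue, brown myoepithelium."""
    rng = np.random.default_rng(seed)
    h, w = field.tissue_mask.shape
    img = _background(field, rng, background_jitter)
    mix = _mix_field(rng, (h, w), sigma=w / 10.0)[:, :, None]
    tissue_color = P63_TISSUE_BLUE * (1 - mix) + P63_TISSUE_BLUE_DEEP * mix
    t = field.tissue_mask[:, :, None]
    img = np.where(t, tissue_color, img)
    myo = field.nucleus_centers[field.cell_labels]
    other = field.nucleus_centers[~field.cell_labels]
    nuc_other = _disk_mask((h, w), other, radius=2.5)[:, :, None]
    img = np.where(nuc_other & t, P63_NUCLEUS_BLUE, img)
    nuc_myo = _disk_mask((h, w), myo, radius=3.0)[:, :, None]
    img = np.where(nuc_myo & t, P63_MYOEP_BROWN, img)
    img += rng.normal(0.0, 0.008, size=img.shape)
    return np.clip(img, 0.0, 1.0)


@dataclass
class SyntheticDataset:
    tiles_a: list[np.ndarray] = field(default_factory=list)   # H&E-like
    tiles_b: list[np.ndarray] = field(default_factory=list)   # p63-like
    structure_seeds_a: list[int] = field(default_factory=list)
    structure_seeds_b: list[int] = field(default_factory=list)
    pairing: list[int] | None = None


def make_dataset(spec: SyntheticDatasetSpec) -> SyntheticDataset:
    """Generate the two tile sets; paired mode shares structure per index."""
    spec.validate()
    ss = np.random.SeedSequence(spec.seed)
    n = spec.n_tiles_per_domain
    # independent 31-bit seeds for structures and renders
    seeds = ss.generate_state(4 * n) % (2 ** 31)
    struct_a = seeds[0:n]
    struct_b = struct_a if spec.paired else seeds[n:2 * n]
    render_a, render_b = seeds[2 * n:3 * n], seeds[3 * n:4 * n]

    ds = SyntheticDataset(pairing=list(range(n)) if spec.paired else None)
    for i in range(n):
        fa = sample_structure(spec.tile_size, spec.tile_size, spec, int(struct_a[i]))
        ds.tiles_a.append(render_he(fa, int(render_a[i]), spec.background_intensity_jitter))
        ds.structure_seeds_a.append(int(struct_a[i]))
        fb = fa if spec.paired else sample_structure(
            spec.tile_size, spec.tile_size, spec, int(struct_b[i]))
        ds.tiles_b.append(render_p63(fb, int(render_b[i]), spec.background_intensity_jitter))
        ds.structure_seeds_b.append(int(struct_b[i]))
    return ds


def write_dataset(ds: SyntheticDataset, spec: SyntheticDatasetSpec, out_dir) -> Path:
    """Write tiles as PNG plus a TSV manifest; returns the manifest path."""
    import imageio.v3 as iio

    from .preprocessing import shannon_entropy_image

    out = Path(out_dir)
    (out / "A").mkdir(parents=True, exist_ok=True)
    (out / "B").mkdir(parents=True, exist_ok=True)
    manifest = out / "manifest.tsv"
    with open(manifest, "w", newline="") as fh:
        wr = csv.writer(fh, delimiter="\t")
        wr.writerow(["filename", "domain", "structure_seed", "tissue_fraction", "entropy"])
        for domain, tiles, seeds in [("A", ds.tiles_a, ds.structure_seeds_a),
                                     ("B", ds.tiles_b, ds.structure_seeds_b)]:
            for i, (tile, sd) in enumerate(zip(tiles, seeds)):
                name = f"{domain}/{domain}_{i:04d}.png"
                iio.imwrite(out / name, (tile * 255).round().astype(np.uint8))
                fld = sample_structure(spec.tile_size, spec.tile_size, spec, sd)
                wr.writerow([name, domain, sd,
                             f"{fld.tissue_fraction:.4f}",
                             f"{shannon_entropy_image(tile):.4f}"])
    with open(out / "spec.json", "w") as fh:
        import json
        json.dump(dataclasses.asdict(spec), fh, indent=1)
    return manifest
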