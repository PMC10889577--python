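"""Tiling, entropy filtering, CIELAB conversion and tanh-range normalisation.

Whole-slide sources are cut into non-overlapping square tiles; tiles whose
grayscale Shannon entropy falls below a threshold (mostly-background regions)
are discarded; surviving tiles are area-average downscaled, converted to
L*a*b*, and affinely mapped per channel into [-1, 1] using dataset channel
statistics so that a tanh-bounded model output covers exactly the observed
data range.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage import color as skcolor

DEFAULT_TILE_SIZE = 1024
DEFAULT_TRAIN_SIZE = 256
DEFAULT_ENTROPY_MIN_BITS = 4.0

# Rec. 601 luma weights for the entropy histogram
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class TileRecord:
    """One training tile with provenance.

    ``pixels`` is channels-first [3, H, W], RGB in [0, 1].
    """

    pixels: np.ndarray
    source_id: str = ""
    grid_position: tuple[int, int] = (0, 0)
    entropy_bits: float = 0.0
    domain: str = "A"

    @property
    def size(self) -> int:
        return self.pixels.shape[-1]


@dataclass
class ChannelStats:
    """Per-channel L*, a*, b* statistics of a tile collection."""

    mean: np.ndarray = field(default_factory=lambda: np.zeros(3))
    std: np.ndarray = field(default_factory=lambda: np.zeros(3))
    min: np.ndarray = field(default_factory=lambda: np.zeros(3))
    max: np.ndarray = field(default_factory=lambda: np.ones(3))

    def validate(self):
        for c in range(3):
            if not (self.min[c] <= self.mean[c] <= self.max[c]):
                raise ValueError("channel stats must satisfy min <= mean <= max")
            if self.std[c] < 0:
                raise ValueError("std must be non-negative")
        return self

    def to_json(self) -> str:
        return json.dumps({k: np.asarray(getattr(self, k)).tolist()
                           for k in ("mean", "std", "min", "max")}, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ChannelStats":
        d = json.loads(text)
        return cls(**{k: np.asarray(d[k], dtype=np.float64) for k in d})


# ---------------------------------------------------------------------------
# tiling
# ---------------------------------------------------------------------------

def tile_grid(image: np.ndarray, tile_size: int = DEFAULT_TILE_SIZE,
              source_id: str = "", domain: str = "A") -> list[TileRecord]:
    """Cut an H×W×3 image into non-overlapping tiles, row-major.

    Partial tiles at the right/bottom edge are dropped. Tile (r, c) covers
    the half-open pixel block [r*size, (r+1)*size) × [c*size, (c+1)*size).
    """
    img = _to_float(image)
    h, w = img.shape[:2]
    nr, nc = h // tile_size, w // tile_size
    if nr == 0 or nc == 0:
        warnings.warn(f"image {h}x{w} smaller than tile size {tile_size}; no tiles emitted")
        return []
    records = []
    for r in range(nr):
        for c in range(nc):
            block = img[r * tile_size:(r + 1) * tile_size,
                        c * tile_size:(c + 1) * tile_size]
            rec = TileRecord(pixels=np.ascontiguousarray(block.transpose(2, 0, 1)),
                             source_id=source_id, grid_position=(r, c), domain=domain)
            rec.entropy_bits = shannon_entropy(rec)
            records.append(rec)
    return records


# ---------------------------------------------------------------------------
# entropy filter
# ---------------------------------------------------------------------------

def shannon_entropy_image(image: np.ndarray) -> float:
    """Shannon entropy (bits) of the 256-bin grayscale intensity histogram.

    ``image`` is RGB (H×W×3 or 3×H×W) in [0, 1]; intensities are Rec. 601
    luma quantised to 8 bits.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim == 3 and img.shape[0] == 3:
        img = img.transpose(1, 2, 0)
    luma = img @ _LUMA if img.ndim == 3 else img
    bins = np.clip(np.round(luma * 255.0), 0, 255).astype(np.int64)
    counts = np.bincount(bins.reshape(-1), minlength=256)
    p = counts[counts > 0] / bins.size
    return float(-(p * np.log2(p)).sum())


def shannon_entropy(tile: TileRecord) -> float:
    if tile.pixels.size == 0:
        raise ValueError("empty tile")
    return shannon_entropy_image(tile.pixels)


def passes_entropy_filter(tile: TileRecord,
                          threshold: float = DEFAULT_ENTROPY_MIN_BITS) -> bool:
    """True iff the tile's entropy is at or above the threshold (inclusive)."""
    return tile.entropy_bits >= threshold


# ---------------------------------------------------------------------------
# downscaling
# ---------------------------------------------------------------------------

def downscale(tile: TileRecord, target: int = DEFAULT_TRAIN_SIZE) -> TileRecord:
    """Area-average downscale to ``target`` pixels per side.

    Only integer shrink factors are supported (exact block means, associative
    across power-of-two chains). Upscaling is an error.
    """
    size = tile.size
    if target > size:
        raise ValueError(f"cannot upscale {size} -> {target}")
    if target == size:
        return TileRecord(tile.pixels.copy(), tile.source_id, tile.grid_position,
                          tile.entropy_bits, tile.domain)
    if size % target != 0:
        raise ValueError(f"downscale factor {size}/{target} is not an integer")
    f = size // target
    px = tile.pixels.reshape(3, target, f, target, f).mean(axis=(2, 4))
    rec = TileRecord(px.astype(tile.pixels.dtype, copy=False), tile.source_id,
                     tile.grid_position, 0.0, tile.domain)
    rec.entropy_bits = shannon_entropy(rec)
    return rec


# ---------------------------------------------------------------------------
# colour space
# ---------------------------------------------------------------------------

def rgb_to_lab(image: np.ndarray) -> np.ndarray:
    """sRGB in [0,1] -> CIE L*a*b* (D65). Accepts H×W×3 or 3×H×W."""
    img, chw = _as_hwc(image)
    if img.min() < 0 or img.max() > 1:
        warnings.warn("RGB input outside [0,1]; clamping")
        img = np.clip(img, 0.0, 1.0)
    lab = skcolor.rgb2lab(img)
    return lab.transpose(2, 0, 1) if chw else lab


def lab_to_rgb(image: np.ndarray) -> np.ndarray:
    """CIE L*a*b* -> sRGB in [0,1] (out-of-gamut values clipped)."""
    img, chw = _as_hwc(image)
    rgb = np.clip(skcolor.lab2rgb(img), 0.0, 1.0)
    return rgb.transpose(2, 0, 1) if chw else rgb


def _as_hwc(image):
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 3:
        raise ValueError("expected a 3-channel image")
    if img.shape[0] == 3 and img.shape[2] != 3:
        return img.transpose(1, 2, 0), True
    return img, False


def _to_float(image) -> np.ndarray:
    img = np.asarray(image)
    if img.dtype == np.uint8:
        img = img.astype(np.float64) / 255.0
    return img.astype(np.float64, copy=False)


# ---------------------------------------------------------------------------
# statistics & model-range mapping
# ---------------------------------------------------------------------------

def compute_channel_stats(tiles: list[TileRecord] | list[np.ndarray],
                          space: str = "lab") -> ChannelStats:
    """Exact per-channel statistics over every pixel of every tile.

    Tiles are RGB records/arrays; with ``space='lab'`` (default) statistics are
    taken after CIELAB conversion, matching the model's working space.
    """
    if len(tiles) == 0:
        raise ValueError("need at least one tile")
    n = 0
    s = np.zeros(3)
    s2 = np.zeros(3)
    mn = np.full(3, np.inf)
    mx = np.full(3, -np.inf)
    for t in tiles:
        px = t.pixels if isinstance(t, TileRecord) else np.asarray(t)
        if px.ndim == 3 and px.shape[0] != 3:
            px = px.transpose(2, 0, 1)
        if space == "lab":
            px = rgb_to_lab(px)
        flat = px.reshape(3, -1).astype(np.float64)
        n += flat.shape[1]
        s += flat.sum(axis=1)
        s2 += (flat ** 2).sum(axis=1)
        mn = np.minimum(mn, flat.min(axis=1))
        mx = np.maximum(mx, flat.max(axis=1))
    mean = s / n
    var = np.maximum(s2 / n - mean ** 2, 0.0)
    return ChannelStats(mean=mean, std=np.sqrt(var), min=mn, max=mx).validate()


def to_model_range(lab_image: np.ndarray, stats: ChannelStats) -> np.ndarray:
    """Affine per-channel map sending [min, max] -> [-1, +1] (tanh range)."""
    if np.any(stats.max <= stats.min):
        raise ValueError("degenerate channel: max must exceed min")
    img = np.asarray(lab_image, dtype=np.float64)
    shape = _stat_shape(img)
    mn, mx = stats.min.reshape(shape), stats.max.reshape(shape)
    return 2.0 * (img - mn) / (mx - mn) - 1.0


def from_model_range(normalized: np.ndarray, stats: ChannelStats) -> np.ndarray:
    """Exact inverse of :func:`to_model_range`."""
    if np.any(stats.max <= stats.min):
        raise ValueError("degenerate channel: max must exceed min")
    img = np.asarray(normalized, dtype=np.float64)
    shape = _stat_shape(img)
    mn, mx = stats.min.reshape(shape), stats.max.reshape(shape)
    return (img + 1.0) / 2.0 * (mx - mn) + mn


def _stat_shape(img: np.ndarray):
    if img.ndim == 4:           # NCHW
        return (1, 3, 1, 1)
    if img.ndim == 3 and img.shape[0] == 3:   # CHW
        return (3, 1, 1)
    return (1, 1, 3)            # HWC


# ---------------------------------------------------------------------------
# end-to-end helper
# ---------------------------------------------------------------------------

def preprocess_image(image: np.ndarray, tile_size: int = DEFAULT_TILE_SIZE,
                     train_size: int = DEFAULT_TRAIN_SIZE,
                     entropy_min: float = DEFAULT_ENTROPY_MIN_BITS,
                     source_id: str = "", domain: str = "A") -> list[TileRecord]:
    """tile -> entropy-filter -> downscale, returning accepted tiles."""
    tiles = tile_grid(image, tile_size, source_id=source_id, domain=domain)
    return [downscale(t, train_size) for t in tiles
            if passes_entropy_filter(t, entropy_min)]
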