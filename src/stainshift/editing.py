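"""Closed-form latent editing (modified SeFa).

Semantic edit directions are recovered without any extra training, directly
from the weights W of the generator's interpretable latent convolution:

    W_norm = W / ||W||_2                  (global L2 norm of the flattened matrix)
    lambda_i, v_i = eig(W_norm W_norm^T)  (symmetric PSD, eigenvalues descending)
    V_i = v_i v_i^T                       (channel-space direction matrices)

Editing adds alpha-scaled channel-space rotations of the feature map X taken
just past that convolution:

    X_mod = X + sum_i  (V_i * alpha_i) X      (applied at every spatial position)

and the rest of the generator runs unchanged on X_mod. Larger eigenvalues
give directions with more visible, more interpretable effect; the advisory
stable range for each modifier is |alpha| <= 3.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, no_grad
from .model import Generator

ALPHA_ADVISORY_LIMIT = 3.0


@dataclass
class EditBasis:
    """Edit directions extracted from one convolution's weights."""

    source_layer: str
    w: np.ndarray              # [C_out, C_in*k*k]
    w_norm: np.ndarray         # same shape, unit Frobenius norm
    eigenvalues: np.ndarray    # descending
    eigenvectors: np.ndarray   # [C_out, C_out], column i <-> eigenvalues[i]

    @property
    def n_directions(self) -> int:
        return self.eigenvalues.size

    def direction(self, i: int) -> np.ndarray:
        v = self.eigenvectors[:, i]
        return np.outer(v, v)

    @property
    def directions(self) -> list[np.ndarray]:
        return [self.direction(i) for i in range(self.n_directions)]


@dataclass
class EditRequest:
    """r directions with one modifier alpha_i each."""

    r: int
    alpha: list[float]

    def validate(self, available: int | None = None):
        if len(self.alpha) != self.r:
            raise ValueError(f"need {self.r} modifiers, got {len(self.alpha)}")
        if available is not None and not (1 <= self.r <= available):
            raise ValueError(f"r={self.r} outside 1..{available}")
        for a in self.alpha:
            if abs(a) > ALPHA_ADVISORY_LIMIT:
                warnings.warn(
                    f"alpha={a} outside the advisory stable range "
                    f"(-{ALPHA_ADVISORY_LIMIT}; {ALPHA_ADVISORY_LIMIT}); "
                    "expect unstable edits", stacklevel=2)
        return self


def flatten_conv_weight(w: np.ndarray) -> np.ndarray:
    """[C_out, C_in, k, k] -> [C_out, C_in*k*k] (2-D weights pass through)."""
    w = np.asarray(w, dtype=np.float64)
    if w.ndim == 4:
        return w.reshape(w.shape[0], -1)
    if w.ndim == 2:
        return w
    raise ValueError(f"expected a conv or matrix weight, got ndim={w.ndim}")


def normalize_weights(w: np.ndarray, per_row: bool = False) -> np.ndarray:
    """W / ||W||_2 with a single global (Frobenius) norm by default.

    ``per_row=True`` switches to per-output-channel row normalisation (a
    SeFa-variant reading).
    """
    w = flatten_conv_weight(w)
    if not np.all(np.isfinite(w)):
        raise ValueError("non-finite weights")
    if per_row:
        norms = np.linalg.norm(w, axis=1, keepdims=True)
        if np.any(norms == 0):
            raise ValueError("zero row in weight matrix")
        return w / norms
    norm = np.linalg.norm(w)
    if norm == 0:
        raise ValueError("all-zero weight matrix")
    return w / norm


def compute_basis(w_norm: np.ndarray, layer_id: str = "",
                  w: np.ndarray | None = None) -> EditBasis:
    """Eigendecomposition of W_norm W_norm^T, sorted by descending eigenvalue."""
    w_norm = np.asarray(w_norm, dtype=np.float64)
    if not np.all(np.isfinite(w_norm)):
        raise ValueError("non-finite weights")
    gram = w_norm @ w_norm.T
    lam, vec = np.linalg.eigh(gram)            # ascending
    order = np.argsort(lam)[::-1]
    return EditBasis(source_layer=layer_id,
                     w=w_norm if w is None else flatten_conv_weight(w),
                     w_norm=w_norm,
                     eigenvalues=lam[order],
                     eigenvectors=vec[:, order])


def basis_from_generator(generator: Generator,
                         layer_id: str | None = None,
                         per_row: bool = False) -> EditBasis:
    layer_id = layer_id or Generator.INTERPRETABLE_LAYER
    layer = generator.layer_by_name(layer_id)
    w = layer.w.data
    return compute_basis(normalize_weights(w, per_row=per_row), layer_id, w=w)


def select_top(basis: EditBasis, r: int) -> list[np.ndarray]:
    """The r direction matrices with the largest eigenvalues."""
    if not 1 <= r <= basis.n_directions:
        raise ValueError(f"r={r} outside 1..{basis.n_directions}")
    return [basis.direction(i) for i in range(r)]


def apply_edit(x: np.ndarray | Tensor, directions: list[np.ndarray],
               alpha: list[float]):
    """X + sum_i (V_i * alpha_i) X, acting on channels at each pixel.

    Accepts [C, h, w] or [B, C, h, w]; Tensor input stays in the autodiff
    graph (the combined channel matrix is a constant).
    """
    if len(directions) != len(alpha):
        raise ValueError("one alpha per direction required")
    c = (x.shape[1] if (hasattr(x, "ndim") and x.ndim == 4) else x.shape[0])
    m = np.zeros((c, c))
    for v, a in zip(directions, alpha):
        v = np.asarray(v)
        if v.shape != (c, c):
            raise ValueError(f"direction shape {v.shape} incompatible with {c} channels")
        m = m + a * v
    if not np.any(m):
        # identity edit: return the feature map itself so the edited forward
        # pass is bit-for-bit the unedited one
        return x if isinstance(x, Tensor) else np.asarray(x, dtype=np.float64)
    if isinstance(x, Tensor):
        if x.ndim != 4:
            raise ValueError("Tensor input must be NCHW")
        b, _, h, w = x.shape
        xr = x.reshape((b, c, h * w))
        mod = (Tensor(m.astype(np.float32)) @ xr).reshape((b, c, h, w))
        return x + mod
    xa = np.asarray(x, dtype=np.float64)
    if xa.ndim == 3:
        return xa + np.einsum("oc,chw->ohw", m, xa)
    if xa.ndim == 4:
        return xa + np.einsum("oc,bchw->bohw", m, xa)
    raise ValueError("expected [C,h,w] or [B,C,h,w] feature map")


def edit_image(generator: Generator, image, request: EditRequest,
               basis: EditBasis | None = None, mask=None) -> np.ndarray:
    """Convert ``image`` with the edit inserted just past the interpretable layer.

    With all alpha = 0 the output is pixel-identical to the plain conversion.
    Returns the fake image in model range as a NumPy array.
    """
    if basis is None:
        basis = basis_from_generator(generator)
    request.validate(available=basis.n_directions)
    directions = select_top(basis, request.r)

    def edit_fn(h):
        return apply_edit(h, directions, list(request.alpha))

    x = np.asarray(image, dtype=np.float32)
    if x.ndim == 3:
        x = x[None]
    with no_grad():
        out = generator.forward(x, mask=mask, edit_fn=edit_fn)
    return out.fake.data


def edit_grid(generator: Generator, image, r_values, alpha_values,
              basis: EditBasis | None = None) -> dict:
    """One edited image per (r, alpha) combination, the same alpha applied to
    all r selected directions. Returns {(r, alpha): image} row-major."""
    if basis is None:
        basis = basis_from_generator(generator)
    r_values = list(r_values)
    alpha_values = list(alpha_values)
    if not r_values or not alpha_values:
        raise ValueError("r_values and alpha_values must be non-empty")
    grid = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # sweeps intentionally exceed advisory range
        for r in r_values:
            for a in alpha_values:
                req = EditRequest(r=r, alpha=[float(a)] * r)
                grid[(r, float(a))] = edit_image(generator, image, req, basis=basis)
    return grid


def save_basis(basis: EditBasis, path):
    np.savez(path, source_layer=np.array(basis.source_layer), w=basis.w,
             w_norm=basis.w_norm, eigenvalues=basis.eigenvalues,
             eigenvectors=basis.eigenvectors)


def load_basis(path) -> EditBasis:
    with np.load(path, allow_pickle=False) as z:
        return EditBasis(source_layer=str(z["source_layer"]), w=z["w"],
                         w_norm=z["w_norm"], eigenvalues=z["eigenvalues"],
                         eigenvectors=z["eigenvectors"])
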