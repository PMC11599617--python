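"""Patch tokenization: tiling volumes and matrices into token sequences.

A 3D gray-matter volume (e.g. 128x128x128) is cut into non-overlapping cubic
patches (default 16x16x16 -> 512 tokens); a padded connectivity matrix
(54x54) is cut into 27x27 patches (-> 4 tokens). The :class:`PatchGrid`
records, for every token, exactly which voxel block it came from; the
interpretability code uses this to project token attention weights back into
voxel space, so both directions must share one token ordering (row-major
over grid axes, coordinates 0-based, extents half-open).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor
from .nn import Linear, Module

__all__ = ["PatchGrid", "pad_to_patch_multiple", "patchify", "unpatchify",
           "PatchEmbedding"]


@dataclass(frozen=True)
class PatchGrid:
    """Geometry of a non-overlapping patch tiling of a (padded) array."""

    original_shape: tuple[int, ...]
    padded_shape: tuple[int, ...]
    patch_shape: tuple[int, ...]
    grid_shape: tuple[int, ...] = field(init=False)

    def __post_init__(self):
        if any(p <= 0 for p in self.patch_shape):
            raise ValueError("patch sides must be positive")
        if len(self.patch_shape) != len(self.padded_shape):
            raise ValueError("patch and array dimensionality differ")
        if any(s % p for s, p in zip(self.padded_shape, self.patch_shape)):
            raise ValueError("padded shape must be a multiple of the patch shape")
        object.__setattr__(
            self, "grid_shape",
            tuple(s // p for s, p in zip(self.padded_shape, self.patch_shape)))

    @property
    def n_tokens(self) -> int:
        return int(np.prod(self.grid_shape))

    @property
    def patch_size(self) -> int:
        return int(np.prod(self.patch_shape))

    def token_extents(self) -> list[tuple[tuple[int, int], ...]]:
        """Half-open voxel index ranges covered by each token, in token order."""
        out = []
        for idx in np.ndindex(*self.grid_shape):
            out.append(tuple(
                (i * p, (i + 1) * p) for i, p in zip(idx, self.patch_shape)))
        return out

    def token_centers(self) -> np.ndarray:
        """(T, ndim) array of patch center coordinates, 0-based voxel units."""
        centers = []
        for ext in self.token_extents():
            centers.append([(lo + hi - 1) / 2.0 for lo, hi in ext])
        return np.asarray(centers)

    def token_slices(self) -> list[tuple[slice, ...]]:
        return [tuple(slice(lo, hi) for lo, hi in ext)
                for ext in self.token_extents()]

    def to_dict(self) -> dict:
        return {"original_shape": list(self.original_shape),
                "padded_shape": list(self.padded_shape),
                "patch_shape": list(self.patch_shape)}

    @classmethod
    def from_dict(cls, d: dict) -> "PatchGrid":
        return cls(tuple(d["original_shape"]), tuple(d["padded_shape"]),
                   tuple(d["patch_shape"]))


def pad_to_patch_multiple(array: np.ndarray,
                          patch_shape: tuple[int, ...]) -> tuple[np.ndarray, PatchGrid]:
    """Zero-pad each axis at the trailing edge up to the next patch multiple.

    A 53x53 connectivity matrix under 27x27 patches becomes 54x54; an input
    already aligned to the patch lattice is returned unchanged (as a copy-free
    view when no padding is needed).
    """
    array = np.asarray(array)
    if any(p <= 0 for p in patch_shape):
        raise ValueError("patch sides must be positive")
    if array.ndim != len(patch_shape):
        raise ValueError(
            f"array is {array.ndim}D but patch shape has {len(patch_shape)} axes")
    padded_shape = tuple(-(-s // p) * p for s, p in zip(array.shape, patch_shape))
    grid = PatchGrid(array.shape, padded_shape, tuple(patch_shape))
    if padded_shape == array.shape:
        return array, grid
    pad = [(0, ps - s) for s, ps in zip(array.shape, padded_shape)]
    return np.pad(array, pad, mode="constant"), grid


def patchify(array: np.ndarray, grid: PatchGrid) -> np.ndarray:
    """Flatten each patch into a token row: (T, patch_size), token order row-major."""
    array = np.asarray(array)
    if array.shape != grid.padded_shape:
        raise ValueError(
            f"array shape {array.shape} != grid padded shape {grid.padded_shape}")
    nd = array.ndim
    g, p = grid.grid_shape, grid.patch_shape
    # split every axis into (blocks, within-block), then bring block axes first
    shaped = array.reshape([v for i in range(nd) for v in (g[i], p[i])])
    order = [2 * i for i in range(nd)] + [2 * i + 1 for i in range(nd)]
    return shaped.transpose(order).reshape(grid.n_tokens, grid.patch_size)


def unpatchify(tokens: np.ndarray, grid: PatchGrid) -> np.ndarray:
    """Inverse of :func:`patchify`; returns the padded array."""
    tokens = np.asarray(tokens)
    if tokens.shape != (grid.n_tokens, grid.patch_size):
        raise ValueError("token matrix shape does not match grid")
    nd = len(grid.grid_shape)
    g, p = grid.grid_shape, grid.patch_shape
    shaped = tokens.reshape(list(g) + list(p))
    order = [v for i in range(nd) for v in (i, nd + i)]
    return shaped.transpose(order).reshape(grid.padded_shape)


class PatchEmbedding(Module):
    """Linear patch projection plus a learned per-token position table."""

    def __init__(self, grid: PatchGrid, d_model: int, rng: np.random.Generator,
                 name: str = "embed"):
        self.grid = grid
        self.projection = Linear(grid.patch_size, d_model, rng,
                                 name=f"{name}.projection")
        self.position_table = Tensor(
            0.02 * rng.standard_normal((grid.n_tokens, d_model)),
            requires_grad=True, name=f"{name}.position")
        self.d_model = d_model

    def __call__(self, tokens: Tensor | np.ndarray) -> Tensor:
        """(B, T, patch_size) or (T, patch_size) -> (B, T, d) or (T, d)."""
        if not isinstance(tokens, Tensor):
            tokens = Tensor(tokens)
        if tokens.shape[-1] != self.grid.patch_size:
            raise ValueError(
                f"token width {tokens.shape[-1]} != patch size {self.grid.patch_size}")
        if tokens.shape[-2] != self.grid.n_tokens:
            raise ValueError(
                f"token count {tokens.shape[-2]} != grid tokens {self.grid.n_tokens}")
        return self.projection(tokens) + self.position_table
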