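"""Curriculum schedule and patch decomposition.

The curriculum drives a global-vs-local consistency constraint: an image is
split into a grid of m non-overlapping patches, and m grows at trigger epochs
so the consistency task moves from easy (few large patches) to hard (many
small patches).  The schedule m(t) is piecewise constant over half-open
epoch phases:

    [0, stage1)            -> 0   (consistency inactive)
    [stage1, t_1)          -> n_1
    [t_1, t_2)             -> n_2
    ...
    [t_{K-1}, total)       -> n_K

Patch counts are perfect squares; a count m tiles the image with a
sqrt(m) x sqrt(m) grid in row-major order.  When a grid does not divide the
image dims, callers reflect-pad to the next multiple first (see
`pad_to_grid`) and crop predictions back afterwards.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class CurriculumSchedule:
    """Stage boundary plus the trigger epochs and patch counts of m(t)."""

    stage1_epochs: int = 70
    patch_counts: tuple[int, ...] = (4, 16, 25)
    trigger_epochs: tuple[int, ...] = (80, 160, 300)
    total_epochs: int = 300

    def __post_init__(self):
        object.__setattr__(self, "patch_counts", tuple(self.patch_counts))
        object.__setattr__(self, "trigger_epochs", tuple(self.trigger_epochs))
        if len(self.patch_counts) != len(self.trigger_epochs):
            raise ValueError(
                f"patch_counts ({len(self.patch_counts)}) and trigger_epochs "
                f"({len(self.trigger_epochs)}) must have equal length")
        for n in self.patch_counts:
            g = math.isqrt(n)
            if g * g != n:
                raise ValueError(f"patch count {n} is not a perfect square")
        if list(self.trigger_epochs) != sorted(set(self.trigger_epochs)):
            raise ValueError(f"trigger_epochs must be strictly increasing, "
                             f"got {self.trigger_epochs}")
        if self.trigger_epochs[-1] > self.total_epochs:
            raise ValueError(f"last trigger {self.trigger_epochs[-1]} exceeds "
                             f"total_epochs {self.total_epochs}")
        if not 0 <= self.stage1_epochs <= self.trigger_epochs[0]:
            raise ValueError(
                f"stage1_epochs {self.stage1_epochs} must lie in "
                f"[0, first trigger {self.trigger_epochs[0]}]")


def patch_count_at(epoch: int, schedule: CurriculumSchedule) -> int:
    """Number of patches m(t) at a given epoch.

    Returns 0 during stage 1 (consistency off); afterwards the patch count
    of the phase containing the epoch under the half-open convention
    [phase_start, next_trigger).  Non-decreasing in `epoch`.
    """
    if not 0 <= epoch < schedule.total_epochs:
        raise ValueError(
            f"epoch {epoch} out of range [0, {schedule.total_epochs})")
    if epoch < schedule.stage1_epochs:
        return 0
    for count, trigger in zip(schedule.patch_counts, schedule.trigger_epochs):
        if epoch < trigger:
            return count
    return schedule.patch_counts[-1]


@dataclass
class PatchSet:
    """The m patches of one image, row-major over a g x g grid."""

    patches: list
    grid_shape: tuple[int, int]
    cell_size: tuple[int, int]
    source_dims: tuple[int, int]

    def __len__(self) -> int:
        return len(self.patches)


def _grid_side(m: int) -> int:
    g = math.isqrt(m)
    if g * g != m:
        raise ValueError(f"patch count m={m} is not a perfect square")
    return g


def decompose(image: np.ndarray, m: int) -> PatchSet:
    """Split a [C, H, W] array into a sqrt(m) x sqrt(m) grid of patches.

    Patches tile the source exactly (non-overlapping, union = image) in
    row-major order.
    """
    g = _grid_side(m)
    C, H, W = image.shape
    if H % g or W % g:
        raise ValueError(
            f"grid {g}x{g} (m={m}) does not divide image dims {H}x{W}")
    ph, pw = H // g, W // g
    patches = [image[:, r * ph:(r + 1) * ph, c * pw:(c + 1) * pw]
               for r in range(g) for c in range(g)]
    return PatchSet(patches=patches, grid_shape=(g, g),
                    cell_size=(ph, pw), source_dims=(H, W))


def reassemble(patch_set: PatchSet) -> np.ndarray:
    """Inverse of `decompose`; bit-exact round trip."""
    g_r, g_c = patch_set.grid_shape
    if len(patch_set.patches) != g_r * g_c:
        raise ValueError(f"expected {g_r * g_c} patches for grid "
                         f"{patch_set.grid_shape}, got {len(patch_set.patches)}")
    ph, pw = patch_set.cell_size
    H, W = patch_set.source_dims
    if (g_r * ph, g_c * pw) != (H, W):
        raise ValueError(f"grid {patch_set.grid_shape} x cell {patch_set.cell_size}"
                         f" inconsistent with source dims {patch_set.source_dims}")
    C = patch_set.patches[0].shape[0]
    out = np.empty((C, H, W), dtype=patch_set.patches[0].dtype)
    for idx, patch in enumerate(patch_set.patches):
        if patch.shape != (C, ph, pw):
            raise ValueError(f"patch {idx} has shape {patch.shape}, "
                             f"expected {(C, ph, pw)}")
        r, c = divmod(idx, g_c)
        out[:, r * ph:(r + 1) * ph, c * pw:(c + 1) * pw] = patch
    return out


def crop_like(full_map, patch_index: int, grid_shape: tuple[int, int]):
    """Crop of `full_map` aligned with patch `patch_index` of the grid.

    Works on any array-like supporting [..., h0:h1, w0:w1] slicing (numpy
    arrays and autodiff tensors), so gradients flow through crops of
    predicted probability maps.
    """
    g_r, g_c = grid_shape
    m = g_r * g_c
    if not 0 <= patch_index < m:
        raise IndexError(f"patch_index {patch_index} out of range for grid "
                         f"{grid_shape} ({m} patches)")
    H, W = full_map.shape[-2], full_map.shape[-1]
    if H % g_r or W % g_c:
        raise ValueError(f"grid {grid_shape} does not divide dims {H}x{W}")
    ph, pw = H // g_r, W // g_c
    r, c = divmod(patch_index, g_c)
    return full_map[..., r * ph:(r + 1) * ph, c * pw:(c + 1) * pw]


def pad_to_grid(image: np.ndarray, g: int) -> np.ndarray:
    """Reflect-pad [..., H, W] so both spatial dims are multiples of g."""
    H, W = image.shape[-2], image.shape[-1]
    pad_h = (-H) % g
    pad_w = (-W) % g
    if pad_h == 0 and pad_w == 0:
        return image
    spec = [(0, 0)] * (image.ndim - 2) + [(0, pad_h), (0, pad_w)]
    return np.pad(image, spec, mode="reflect")
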