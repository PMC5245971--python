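"""Spatial and temporal summation: what a voxel can and cannot see.

The BOLD signal sums neural activity over space (a voxel's volume) and
time (the sluggish haemodynamic window).  These demonstrations parallel
neurons with pixels and voxels with non-overlapping blocks of a 2-D grid:
a smooth activity gradient survives block summation, a fine-scale
alternating pattern sums to identical ("homogeneous") voxels, and a spike
train's burstiness vanishes under window summation.  Summation conserves
total activity exactly, so the information loss is purely a sampling
limit, not an amplitude one.

Blocks are non-overlapping, 0-based, row-major, half-open ranges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .stimuli import DegenerateInputError

__all__ = [
    "ActivityField",
    "VoxelGrid",
    "spatial_summate",
    "voxel_inhomogeneity",
    "temporal_summate",
    "gradient_field",
    "alternating_field",
]


@dataclass(frozen=True)
class ActivityField:
    """A 2-D field of non-negative neural activity ("pixels" as neurons)."""

    grid: np.ndarray

    def __post_init__(self) -> None:
        g = np.asarray(self.grid, dtype=float)
        if g.ndim != 2 or g.size == 0:
            raise ValueError("activity field must be a non-empty 2-D array")
        if not np.all(np.isfinite(g)) or np.any(g < 0):
            raise ValueError("activity values must be finite and non-negative")
        object.__setattr__(self, "grid", g)

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape


@dataclass(frozen=True)
class VoxelGrid:
    """Block-summed activity: each voxel is the sum of its pixel block."""

    voxels: np.ndarray
    voxel_size: tuple[int, int]

    def total(self) -> float:
        return float(self.voxels.sum())


def spatial_summate(
    field: ActivityField, voxel_size: tuple[int, int], *, edge: str = "error"
) -> VoxelGrid:
    """Sum a field into non-overlapping voxel blocks.

    ``voxel_size`` is (height, width) in pixels.  If the field dimensions
    are not divisible by the voxel size the default is to raise (partial
    voxels would break conservation); ``edge="truncate"`` drops the
    trailing partial rows/columns instead.
    """
    vh, vw = voxel_size
    if vh < 1 or vw < 1:
        raise ValueError("voxel size must be positive")
    rows, cols = field.shape
    if vh > rows or vw > cols:
        raise ValueError(f"voxel size {voxel_size} exceeds field shape {field.shape}")
    if rows % vh or cols % vw:
        if edge == "error":
            raise ValueError(
                f"field shape {field.shape} not divisible by voxel size {voxel_size}; "
                "use edge='truncate' to drop partial voxels"
            )
        if edge != "truncate":
            raise ValueError(f"unknown edge policy {edge!r}")
        rows -= rows % vh
        cols -= cols % vw
    g = field.grid[:rows, :cols]
    voxels = g.reshape(rows // vh, vh, cols // vw, vw).sum(axis=(1, 3))
    return VoxelGrid(voxels=voxels, voxel_size=(vh, vw))


def voxel_inhomogeneity(voxels: VoxelGrid) -> float:
    """Population standard deviation of voxel values.

    Zero exactly when all voxels sum to the same value — the regime in
    which the scan is blind to the underlying pattern.
    """
    v = voxels.voxels
    if v.size < 2:
        raise DegenerateInputError("inhomogeneity needs at least 2 voxels")
    return float(v.std())


def temporal_summate(spike_train, window: int) -> np.ndarray:
    """Sum event counts over non-overlapping time windows.

    Two trains with equal totals but different burst structure produce
    identical sums once the window covers them, so temporal codes based on
    firing variance are invisible to the summed signal.  Trailing bins
    that do not fill a window are dropped only if empty of information
    (i.e. the train length must be divisible by ``window``).
    """
    train = np.asarray(spike_train, dtype=float)
    if train.ndim != 1 or train.size == 0:
        raise ValueError("spike train must be a non-empty 1-D sequence")
    if window < 1 or window > train.size:
        raise ValueError(f"window must be in 1..{train.size}, got {window}")
    if train.size % window:
        raise ValueError(f"train length {train.size} not divisible by window {window}")
    return train.reshape(-1, window).sum(axis=1)


# ---------------------------------------------------------------------------
# field constructors for the sampling-limit demonstrations


def gradient_field(rows: int = 8, cols: int = 64, high: float = 1.0) -> ActivityField:
    """Smooth left-to-right linear activity gradient (the decodable case)."""
    ramp = np.linspace(0.0, high, cols)
    return ActivityField(grid=np.tile(ramp, (rows, 1)))


def alternating_field(
    rows: int = 8, cols: int = 64, period: int = 2, low: float = 0.0, high: float = 1.0
) -> ActivityField:
    """Fine-scale alternation along columns with the given period.

    Voxels whose width is a multiple of ``period`` cover equal counts of
    the two values and all sum identically — the homogeneous, invisible
    regime.
    """
    if period < 2 or period % 2:
        raise ValueError("period must be an even integer >= 2")
    pattern = np.where((np.arange(cols) // (period // 2)) % 2 == 0, high, low)
    return ActivityField(grid=np.tile(pattern, (rows, 1)))
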