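"""Common voxel-grid definition shared by every volumetric object in a run."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class VoxelGrid:
    """A regular 3-D sampling grid.

    Parameters
    ----------
    shape : tuple of int
        Number of voxels along each axis.
    voxel_size : tuple of float
        Voxel edge length in mm along each axis.
    origin : str
        Origin convention tag; volumes in one run must agree.
    """

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)
    origin: str = "corner"

    def __post_init__(self):
        if len(self.shape) != 3 or any(int(s) < 1 for s in self.shape):
            raise ValueError(f"grid shape must be three positive integers, got {self.shape}")
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel sizes must be positive, got {self.voxel_size}")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "voxel_size", tuple(float(v) for v in self.voxel_size))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size))

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        return tuple(s * v for s, v in zip(self.shape, self.voxel_size))

    def coordinates_mm(self):
        """Voxel-center coordinates, three broadcastable arrays in mm."""
        axes = [
            (np.arange(n) + 0.5) * v
            for n, v in zip(self.shape, self.voxel_size)
        ]
        return np.meshgrid(*axes, indexing="ij", sparse=True)

    def check_volume(self, vol: np.ndarray, name: str = "volume") -> None:
        if tuple(vol.shape[:3]) != self.shape:
            raise ValueError(
                f"{name} has shape {tuple(vol.shape[:3])} but the run grid is {self.shape}"
            )


def check_same_grid(a: VoxelGrid, b: VoxelGrid) -> None:
    if a.shape != b.shape or not np.allclose(a.voxel_size, b.voxel_size):
        raise ValueError(
            f"grid mismatch: {a.shape} @ {a.voxel_size} mm vs {b.shape} @ {b.voxel_size} mm"
        )
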