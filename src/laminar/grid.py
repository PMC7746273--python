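"""Regular voxel grids in world (mm) coordinates.

A :class:`Grid` couples an integer array shape with an affine mapping voxel
indices to scanner/world millimetres, the same convention NIfTI uses.  Voxel
centre ``(i, j, k)`` maps to ``origin + (ijk + 0.5) * voxel_size``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class Grid:
    """A regular, axis-aligned voxel grid."""

    shape: tuple[int, int, int]
    voxel_size_mm: float = 0.8
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(s) < 1 for s in self.shape):
            raise ValueError(f"grid shape must be three positive ints, got {self.shape}")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel size must be positive")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-index -> world-mm affine (centre-of-voxel convention)."""
        a = np.eye(4)
        a[:3, :3] = np.eye(3) * self.voxel_size_mm
        a[:3, 3] = np.asarray(self.origin_mm) + 0.5 * self.voxel_size_mm
        return a

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(self.voxel_size_mm**3)

    def voxel_centers(self) -> np.ndarray:
        """World coordinates of every voxel centre, shape (n_voxels, 3), C order."""
        idx = np.indices(self.shape).reshape(3, -1).T.astype(float)
        return self.index_to_world(idx)

    def index_to_world(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        return ijk * self.voxel_size_mm + np.asarray(self.origin_mm) + 0.5 * self.voxel_size_mm

    def world_to_index(self, xyz: np.ndarray) -> np.ndarray:
        """Continuous voxel indices (no rounding) of world points."""
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        return (xyz - np.asarray(self.origin_mm)) / self.voxel_size_mm - 0.5

    @staticmethod
    def centered(shape: tuple[int, int, int], voxel_size_mm: float = 0.8,
                 center_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)) -> "Grid":
        """Grid whose bounding box is centred on ``center_mm``."""
        shape = tuple(int(s) for s in shape)
        extent = np.asarray(shape) * voxel_size_mm
        origin = np.asarray(center_mm) - extent / 2.0
        return Grid(shape=shape, voxel_size_mm=voxel_size_mm, origin_mm=tuple(origin))
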