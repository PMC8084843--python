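"""Voxel grids with world-affine geometry.

All cross-grid operations in this package are carried out in world
coordinates (millimetres).  Voxel indices are 0-based; the affine maps
voxel index -> world position of the voxel centre.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Grid", "Volume", "centered_grid"]


@dataclass(frozen=True)
class Grid:
    """A regular 3-D voxel grid embedded in world space."""

    shape: tuple[int, int, int]
    affine: np.ndarray  # 4x4, voxel index -> world mm

    def __post_init__(self) -> None:
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError(f"affine must be 4x4, got {affine.shape}")
        if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise ValueError("singular affine")
        object.__setattr__(self, "affine", affine)
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))

    @property
    def spacing(self) -> np.ndarray:
        """Voxel edge lengths in mm (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        inv = np.linalg.inv(self.affine)
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    def voxel_centers_world(self) -> np.ndarray:
        """World coordinates of every voxel centre, shape (*grid, 3)."""
        idx = np.indices(self.shape, dtype=float).reshape(3, -1).T
        return self.voxel_to_world(idx).reshape(self.shape + (3,))

    def same_geometry(self, other: "Grid", atol: float = 1e-6) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )


@dataclass
class Volume:
    """A scalar field (3-D, or 4-D with a trailing frame axis) on a Grid."""

    data: np.ndarray
    grid: Grid = field(repr=False)

    def __post_init__(self) -> None:
        self.data = np.asanyarray(self.data)
        if self.data.ndim not in (3, 4):
            raise ValueError(f"expected 3-D or 4-D data, got ndim={self.data.ndim}")
        if tuple(self.data.shape[:3]) != self.grid.shape:
            raise ValueError(
                f"data spatial shape {self.data.shape[:3]} != grid shape {self.grid.shape}"
            )

    @property
    def n_frames(self) -> int:
        return 1 if self.data.ndim == 3 else self.data.shape[3]


def centered_grid(shape: tuple[int, int, int], fov_mm: tuple[float, float, float]) -> Grid:
    """Axis-aligned grid covering ``fov_mm`` with the world origin at its centre."""
    shape = tuple(int(s) for s in shape)
    spacing = np.asarray(fov_mm, dtype=float) / np.asarray(shape, dtype=float)
    affine = np.eye(4)
    affine[:3, :3] = np.diag(spacing)
    affine[:3, 3] = -(np.asarray(shape) / 2.0 - 0.5) * spacing
    return Grid(shape=shape, affine=affine)
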