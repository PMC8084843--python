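"""Dynamic metabolite series, AUC maps and world-coordinate resampling."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates

from .grid import Grid, Volume

__all__ = [
    "METABOLITES",
    "DynamicMetaboliteSeries",
    "MetaboliteAUCMap",
    "compute_auc_map",
    "resample_to_grid",
]

METABOLITES = ("pyruvate", "lactate", "bicarbonate")


@dataclass
class DynamicMetaboliteSeries:
    """4-D voxel time-series for one metabolite (x, y, z, frame)."""

    metabolite: str
    data: np.ndarray
    frame_interval: float  # seconds
    grid: Grid = field(repr=False)

    def __post_init__(self) -> None:
        if self.metabolite not in METABOLITES:
            raise ValueError(f"unknown metabolite {self.metabolite!r}")
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"expected 4-D data, got ndim={self.data.ndim}")
        if self.data.shape[3] < 1:
            raise ValueError("series must have at least one frame")
        if tuple(self.data.shape[:3]) != self.grid.shape:
            raise ValueError("spatial shape does not match grid")
        if not np.isfinite(self.data).all():
            raise ValueError("series contains non-finite voxels")
        if (self.data < 0).any():
            raise ValueError("series contains negative voxels")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if (self.grid.spacing <= 0).any():
            raise ValueError("voxel spacing must be > 0")

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]


@dataclass
class MetaboliteAUCMap:
    """3-D per-voxel frame-sum of a dynamic series.

    NaN voxels mean "outside the source field of view" after resampling
    and are excluded from all downstream means.
    """

    metabolite: str
    data: np.ndarray
    grid: Grid = field(repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3-D data, got ndim={self.data.ndim}")
        if tuple(self.data.shape) != self.grid.shape:
            raise ValueError("shape does not match grid")
        finite = self.data[~np.isnan(self.data)]
        if not np.isfinite(finite).all():
            raise ValueError("map contains infinite voxels")


def compute_auc_map(series: DynamicMetaboliteSeries) -> MetaboliteAUCMap:
    """Collapse a dynamic series to its per-voxel sum over frames.

    This is a plain frame sum, not a trapezoid with the frame interval:
    with uniform frame spacing the two differ only by edge weights and a
    global factor that the downstream z-score normalization cancels.
    """
    auc = series.data.sum(axis=3)
    return MetaboliteAUCMap(metabolite=series.metabolite, data=auc, grid=series.grid)


def resample_to_grid(aucmap: MetaboliteAUCMap, target: Grid) -> MetaboliteAUCMap:
    """Trilinearly resample a map onto ``target`` in world coordinates.

    Target voxels whose world position falls outside the convex hull of
    source voxel centres are marked missing (NaN).
    """
    if aucmap.grid.same_geometry(target):
        return MetaboliteAUCMap(aucmap.metabolite, aucmap.data.copy(), aucmap.grid)

    # target voxel index -> world -> source voxel (fractional) index
    xform = np.linalg.inv(aucmap.grid.affine) @ target.affine
    idx = np.indices(target.shape, dtype=float).reshape(3, -1)
    src = xform[:3, :3] @ idx + xform[:3, 3:4]

    vals = map_coordinates(aucmap.data, src, order=1, mode="constant", cval=np.nan)
    # map_coordinates pads by half a voxel; mark anything outside the
    # voxel-centre hull as missing explicitly
    upper = (np.asarray(aucmap.grid.shape, dtype=float) - 1.0).reshape(3, 1)
    outside = (src < -1e-9).any(axis=0) | (src > upper + 1e-9).any(axis=0)
    vals[outside] = np.nan
    return MetaboliteAUCMap(
        metabolite=aucmap.metabolite,
        data=vals.reshape(target.shape),
        grid=target,
    )


def resample_labels_nearest(labels: Volume, target: Grid) -> Volume:
    """Nearest-neighbour label lookup on ``target`` (0 outside the source)."""
    xform = np.linalg.inv(labels.grid.affine) @ target.affine
    idx = np.indices(target.shape, dtype=float).reshape(3, -1)
    src = np.rint(xform[:3, :3] @ idx + xform[:3, 3:4]).astype(int)
    out = np.zeros(idx.shape[1], dtype=labels.data.dtype)
    inside = np.ones(idx.shape[1], dtype=bool)
    for ax in range(3):
        inside &= (src[ax] >= 0) & (src[ax] < labels.grid.shape[ax])
    out[inside] = labels.data[tuple(src[:, inside])]
    return Volume(data=out.reshape(target.shape), grid=target)
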