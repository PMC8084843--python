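"""Atlas-region z-score normalization of metabolite maps.

The signal strength of a hyperpolarized substrate at detection time
varies over a wide range between subjects (polarization level, timing),
which would confound any absolute comparison of lesion signal.  The
normalization implemented here expresses every region's and lesion's
signal in units of the spread of the 56 atlas-region means *within the
same subject*:

    z_i      = (x_i      - mu) / sigma
    z_lesion = (x_lesion - mu) / sigma

where mu and sigma are the mean and standard deviation of the 56
atlas-region mean signals for that subject.  Any subject-level
multiplicative factor cancels exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .grid import Volume
from .maps import MetaboliteAUCMap

logger = logging.getLogger(__name__)

__all__ = [
    "RegionSignalProfile",
    "LesionScoreRecord",
    "region_means",
    "profile_zscores",
    "lesion_mean",
    "lesion_zscore",
]


@dataclass
class RegionSignalProfile:
    """Per-subject region means with their z-score normalization.

    ``sigma`` uses the sample (n-1) convention by default; any fixed
    convention rescales all z by the same subject-level factor.
    """

    subject_id: str
    region_means: np.ndarray
    mu: float
    sigma: float
    z: np.ndarray
    ddof: int = 1

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        # contract: z re-standardizes to mean 0, spread 1 under the same estimator
        if abs(float(np.mean(self.z))) > 1e-10:
            raise ValueError("z-scores do not have mean 0")
        if abs(float(np.std(self.z, ddof=self.ddof)) - 1.0) > 1e-10:
            raise ValueError("z-scores do not have unit spread")


@dataclass
class LesionScoreRecord:
    """One scored lesion: mean signal, z-score, optional prediction score."""

    lesion_id: str
    subject_id: str
    primary_type: str
    x_lesion: float
    z_lesion: float
    outcome: str = "unknown"
    prior_srs: bool = False
    prediction_score: float | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.z_lesion):
            raise ValueError("z_lesion must be finite")
        if self.prediction_score is not None and not (
            0.0 <= self.prediction_score <= 1.0
        ):
            raise ValueError("prediction_score must lie in [0, 1]")


def region_means(
    aucmap: MetaboliteAUCMap,
    atlas: Volume,
    n_regions: int = 56,
    roi_exclude: Volume | None = None,
    return_coverage: bool = False,
):
    """Mean map value per atlas label (1..n_regions).

    Missing (NaN) map voxels — i.e. voxels outside the metabolite field
    of view — are excluded; the fraction of covered voxels per region is
    logged.  ``roi_exclude`` optionally removes lesion voxels from their
    host region.
    """
    if tuple(atlas.data.shape) != tuple(aucmap.data.shape):
        raise ValueError(
            f"atlas grid {atlas.data.shape} != map grid {aucmap.data.shape}"
        )
    if not aucmap.grid.same_geometry(atlas.grid):
        raise ValueError("atlas and map geometries differ")
    labels = atlas.data
    data = aucmap.data
    keep = ~np.isnan(data)
    if roi_exclude is not None:
        keep &= ~(roi_exclude.data.astype(bool))

    x = np.empty(n_regions, dtype=float)
    coverage = np.empty(n_regions, dtype=float)
    for label in range(1, n_regions + 1):
        in_region = labels == label
        n_total = int(in_region.sum())
        if n_total == 0:
            raise ValueError(f"atlas region {label} is empty")
        usable = in_region & keep
        n_used = int(usable.sum())
        coverage[label - 1] = n_used / n_total
        if n_used == 0:
            raise ValueError(
                f"atlas region {label} has no coverage in the metabolite field of view"
            )
        x[label - 1] = float(data[usable].mean())
    if (coverage < 1.0).any():
        logger.info(
            "partial 13C coverage in %d region(s); min fraction %.3f",
            int((coverage < 1.0).sum()), float(coverage.min()),
        )
    if return_coverage:
        return x, coverage
    return x


def profile_zscores(
    x: np.ndarray, subject_id: str = "", ddof: int = 1
) -> RegionSignalProfile:
    """Convert region means to a within-subject z-score profile.

    mu is the arithmetic mean and sigma the sample (n-1 by default)
    standard deviation of the region means; z_i = (x_i - mu) / sigma.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need a 1-D vector of at least 2 region means")
    if np.unique(x).size < 2:
        raise ValueError("all region means identical: sigma = 0, profile unusable")
    mu = float(np.mean(x))
    sigma = float(np.std(x, ddof=ddof))
    z = (x - mu) / sigma
    return RegionSignalProfile(
        subject_id=subject_id, region_means=x, mu=mu, sigma=sigma, z=z, ddof=ddof
    )


def lesion_mean(aucmap: MetaboliteAUCMap, roi: Volume) -> float:
    """Mean map value over the in-mask, non-missing voxels of a lesion ROI."""
    if tuple(roi.data.shape) != tuple(aucmap.data.shape):
        raise ValueError("ROI and map grids differ in shape")
    if not aucmap.grid.same_geometry(roi.grid):
        raise ValueError("ROI and map geometries differ")
    mask = roi.data.astype(bool)
    if not mask.any():
        raise ValueError("lesion ROI mask is empty")
    vals = aucmap.data[mask]
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ValueError("lesion ROI lies entirely outside the metabolite field of view")
    return float(vals.mean())


def lesion_zscore(x_lesion: float, profile: RegionSignalProfile) -> float:
    """z-score a lesion's mean signal against its subject's region profile."""
    return (float(x_lesion) - profile.mu) / profile.sigma
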