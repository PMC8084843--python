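"""Synthetic multi-subject dynamic-metabolite phantom.

Generates datasets with the statistical structure the scoring analysis
assumes: a canonical cross-region lactate pattern shared by all
subjects, subject-level multiplicative signal-strength variability,
gamma-variate voxel kinetics rendered on a coarse metabolite grid, and
spherical lesions whose lactate elevation is linked to a binary outcome
through a logistic model.  A ground-truth table accompanies every
cohort for parameter-recovery tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.special import expit

from .grid import Grid, Volume, centered_grid
from .io import PRIMARY_TYPES, CohortTable, save_volume
from .maps import DynamicMetaboliteSeries, resample_labels_nearest

logger = logging.getLogger(__name__)

__all__ = [
    "CANONICAL_PATTERN",
    "PhantomConfig",
    "SubjectData",
    "CohortDataset",
    "generate_atlas",
    "generate_subject",
    "generate_lesion",
    "generate_cohort",
]

# Fixed 56-region canonical lactate pattern (arbitrary signal units,
# versioned library constant).  Its own z-scores span [-3, 2], matching
# the consistent cross-region range the analysis relies on.
CANONICAL_PATTERN = np.array([
    46.0000, 67.0155, 69.1754, 71.3353, 73.4951, 75.6550, 77.8148,
    79.9747, 82.1345, 83.6464, 84.5872, 85.5279, 86.4687, 87.4094,
    88.3501, 89.2909, 90.2316, 91.1723, 92.1131, 93.0538, 93.9946,
    94.9353, 95.8760, 96.8168, 97.7575, 98.6982, 99.6390, 100.5797,
    101.5205, 102.4612, 103.4019, 104.3427, 105.2834, 106.2241, 107.1649,
    108.1056, 109.0464, 109.9871, 110.9278, 111.8686, 112.8093, 113.7500,
    114.6908, 115.6315, 116.5723, 117.5130, 118.4537, 119.3945, 120.3352,
    121.2759, 122.2167, 123.1574, 124.0982, 125.0389, 125.9796, 136.0000,
])

# relative signal strength of each metabolite's rendered pattern
_METABOLITE_SCALE = {"pyruvate": 5.0, "lactate": 1.0, "bicarbonate": 0.25}


@dataclass
class PhantomConfig:
    """Generative parameters for a synthetic cohort."""

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    c13_grid_shape: tuple[int, int, int] = (16, 16, 24)
    fov_mm: tuple[float, float, float] = (240.0, 240.0, 360.0)
    n_regions: int = 56
    canonical_pattern: np.ndarray = field(
        default_factory=lambda: CANONICAL_PATTERN.copy()
    )
    brain_fraction: float = 0.42  # ellipsoid semi-axes as a fraction of FOV/2
    subject_scale_mu: float = 0.0  # log-normal parameters of the scale s_j
    subject_scale_sigma: float = 0.5
    region_noise_sd: float = 2.0
    n_subjects_per_type: dict = field(
        default_factory=lambda: {"NSCLC": 4, "RCC": 2, "breast": 4, "colorectal": 1}
    )
    lesions_per_subject: int = 1
    prior_srs_lesions: int = 0
    lesion_radius_mm: float = 20.0
    lesion_z_target_range: tuple[float, float] = (-2.0, 4.0)
    outcome_alpha: float = -1.0
    outcome_beta: float = 2.0
    frames: int = 12
    frame_interval_s: float = 5.0
    # gamma-variate (shape, timescale seconds) per metabolite
    kinetic_params: dict = field(
        default_factory=lambda: {
            "pyruvate": (2.0, 8.0),
            "lactate": (3.0, 10.0),
            "bicarbonate": (3.0, 12.0),
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        self.canonical_pattern = np.asarray(self.canonical_pattern, dtype=float)
        if self.n_regions < 1 or self.frames < 1 or self.lesions_per_subject < 0:
            raise ValueError("counts must be positive")
        if self.canonical_pattern.size != self.n_regions:
            raise ValueError(
                f"canonical_pattern has {self.canonical_pattern.size} entries, "
                f"expected n_regions={self.n_regions}"
            )
        if self.subject_scale_sigma < 0:
            raise ValueError("subject_scale_sigma must be >= 0")
        if self.region_noise_sd < 0:
            raise ValueError("region_noise_sd must be >= 0")
        if any(n <= 0 for n in self.n_subjects_per_type.values()):
            raise ValueError("subject counts must be positive")
        if set(self.n_subjects_per_type) - set(PRIMARY_TYPES):
            raise ValueError("unknown primary type in n_subjects_per_type")
        if self.lesion_radius_mm >= min(self.brain_semi_axes()):
            raise ValueError("lesion radius exceeds brain mask extent")

    @property
    def n_subjects(self) -> int:
        return sum(self.n_subjects_per_type.values())

    def anatomical_grid(self) -> Grid:
        return centered_grid(self.grid_shape, self.fov_mm)

    def c13_grid(self) -> Grid:
        return centered_grid(self.c13_grid_shape, self.fov_mm)

    def brain_semi_axes(self) -> np.ndarray:
        return self.brain_fraction * np.asarray(self.fov_mm) / 2.0


@dataclass
class SubjectData:
    """One simulated subject: per-metabolite series and generative truth."""

    subject_id: str
    scale: float
    region_amplitudes: np.ndarray  # true lactate frame-sum amplitude per region
    series: dict  # metabolite -> DynamicMetaboliteSeries


@dataclass
class CohortDataset:
    config: PhantomConfig
    atlas: Volume
    subjects: dict  # subject_id -> SubjectData
    lesion_masks: dict  # lesion_id -> Volume (anatomical grid, uint8)
    cohort: CohortTable
    truth: pd.DataFrame

    def write(self, out_dir: str | Path) -> Path:
        """Write the dataset (NIfTI + CSV) under a directory layout."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        save_volume(self.atlas, out / "atlas.nii.gz")
        for sid, subj in self.subjects.items():
            sdir = out / "subjects" / sid
            for met, series in subj.series.items():
                save_volume(
                    Volume(series.data, series.grid), sdir / f"{met}_dynamic.nii.gz"
                )
        for lid, roi in self.lesion_masks.items():
            save_volume(roi, out / "lesions" / f"{lid}_mask.nii.gz")
        self.cohort.to_csv(out / "cohort.csv")
        self.truth.to_csv(out / "truth.csv", index=False)
        return out


def _brain_mask(grid: Grid, semi_axes: np.ndarray) -> np.ndarray:
    xyz = grid.voxel_centers_world()
    return ((xyz / semi_axes) ** 2).sum(axis=-1) <= 1.0


def generate_atlas(config: PhantomConfig, seed: int) -> Volume:
    """Parcellate an ellipsoid brain mask into ``n_regions`` Voronoi cells.

    Cells are Voronoi regions (in world metric) of random in-mask seed
    points; each cell is convex intersected with the ellipsoid, hence
    connected, and contains at least its own seed voxel.
    """
    grid = config.anatomical_grid()
    mask = _brain_mask(grid, config.brain_semi_axes())
    n_in = int(mask.sum())
    if n_in < config.n_regions:
        raise ValueError(
            f"grid too small: {n_in} in-mask voxels for {config.n_regions} regions"
        )
    rng = np.random.default_rng(seed)
    xyz = grid.voxel_centers_world()
    in_mask_xyz = xyz[mask]
    pick = rng.choice(n_in, size=config.n_regions, replace=False)
    tree = cKDTree(in_mask_xyz[pick])
    _, nearest = tree.query(in_mask_xyz)
    labels = np.zeros(grid.shape, dtype=np.int16)
    labels[mask] = nearest.astype(np.int16) + 1
    return Volume(data=labels, grid=grid)


def _gamma_variate(config: PhantomConfig, metabolite: str) -> np.ndarray:
    """Normalized per-frame kinetic weights (sum = 1)."""
    shape, tau = config.kinetic_params[metabolite]
    t = (np.arange(config.frames) + 0.5) * config.frame_interval_s
    c = t**shape * np.exp(-t / tau)
    return c / c.sum()


def generate_subject(
    config: PhantomConfig,
    atlas: Volume,
    seed: int,
    subject_id: str = "S00",
    scale: float | None = None,
) -> SubjectData:
    """Render one subject's dynamic metabolite series on the coarse grid.

    Region i of the lactate series carries a steady frame-sum amplitude
    x_i = s_j * (p_i + eps_i) with eps_i ~ Normal(0, region_noise_sd)
    and the subject's scale s_j ~ LogNormal(mu_s, sigma_s) (or the
    explicit ``scale`` override).  Voxel time-courses are gamma-variate
    curves scaled so the frame sum equals the region amplitude.
    """
    rng = np.random.default_rng(seed)
    # noise draws come first so a scale override leaves them unchanged
    eps = {
        met: rng.normal(0.0, config.region_noise_sd, config.n_regions)
        for met in ("lactate", "pyruvate", "bicarbonate")
    }
    if scale is None:
        scale = float(rng.lognormal(config.subject_scale_mu, config.subject_scale_sigma))
    if scale <= 0:
        raise ValueError("subject scale must be > 0")

    c13 = config.c13_grid()
    atlas_c13 = resample_labels_nearest(atlas, c13)
    lab = atlas_c13.data.astype(int)

    series: dict[str, DynamicMetaboliteSeries] = {}
    region_amp_lac = None
    for met in ("lactate", "pyruvate", "bicarbonate"):
        amp_region = scale * _METABOLITE_SCALE[met] * np.clip(
            config.canonical_pattern + eps[met], 0.0, None
        )
        if met == "lactate":
            region_amp_lac = amp_region
        amp_map = np.zeros(c13.shape, dtype=float)
        inside = lab > 0
        amp_map[inside] = amp_region[lab[inside] - 1]
        curve = _gamma_variate(config, met)
        data = amp_map[..., None] * curve
        series[met] = DynamicMetaboliteSeries(
            metabolite=met, data=data,
            frame_interval=config.frame_interval_s, grid=c13,
        )
    return SubjectData(
        subject_id=subject_id, scale=float(scale),
        region_amplitudes=region_amp_lac, series=series,
    )


def _sphere_fraction(grid: Grid, center: np.ndarray, radius: float, sub: int = 4):
    """Per-voxel fraction of volume inside a world-space sphere.

    Returns (index tuple of touched voxels, fractions).  Fractions are
    estimated by regular sub-voxel sampling, giving fractional weights
    at boundary voxels.
    """
    vox_c = grid.world_to_voxel(center)[0]
    reach = radius / grid.spacing + 1.0
    lo = np.maximum(np.floor(vox_c - reach).astype(int), 0)
    hi = np.minimum(np.ceil(vox_c + reach).astype(int) + 1, np.asarray(grid.shape))
    if (lo >= hi).any():
        return (np.empty(0, int),) * 3, np.empty(0)
    idx = np.stack(
        np.meshgrid(*[np.arange(lo[a], hi[a]) for a in range(3)], indexing="ij"), -1
    ).reshape(-1, 3)
    offs = (np.arange(sub) + 0.5) / sub - 0.5
    sub_offsets = np.stack(np.meshgrid(offs, offs, offs, indexing="ij"), -1).reshape(-1, 3)
    pts = idx[:, None, :] + sub_offsets[None, :, :]
    world = grid.voxel_to_world(pts.reshape(-1, 3)).reshape(len(idx), -1, 3)
    inside = ((world - center) ** 2).sum(axis=-1) <= radius**2
    frac = inside.mean(axis=1)
    keep = frac > 0
    idx = idx[keep]
    return (idx[:, 0], idx[:, 1], idx[:, 2]), frac[keep]


def generate_lesion(
    config: PhantomConfig,
    atlas: Volume,
    subject: SubjectData,
    seed: int,
    lesion_id: str = "L0",
):
    """Inject one spherical lesion into a subject's lactate series.

    The lesion's frame-sum amplitude is set to mu + z* sigma of the
    subject's own region-amplitude distribution, with the target z*
    drawn uniformly from the configured range.  Injection happens on
    the coarse metabolite grid with fractional-volume weighting at
    boundary voxels, mirroring partial-volume contamination.  The
    6-month outcome is Bernoulli(logistic(alpha + beta z*)).

    Returns ``(roi_mask, modified_lactate_series, truth_row)``.
    """
    rng = np.random.default_rng(seed)
    semi = config.brain_semi_axes()
    r = config.lesion_radius_mm
    # centre must leave the whole sphere inside the brain ellipsoid
    inner = semi - r
    if (inner <= 0).any():
        raise ValueError("lesion radius exceeds brain mask extent")
    center = None
    for _ in range(100):
        cand = rng.uniform(-inner, inner)
        if ((cand / inner) ** 2).sum() <= 1.0:
            center = cand
            break
    if center is None:
        raise RuntimeError("failed to sample a lesion centre after 100 tries")

    z_target = float(rng.uniform(*config.lesion_z_target_range))
    mu = float(subject.region_amplitudes.mean())
    sigma = float(subject.region_amplitudes.std(ddof=1))
    amp_lesion = max(mu + z_target * sigma, 0.0)

    # ROI mask on the anatomical grid
    xyz = atlas.grid.voxel_centers_world()
    roi = (((xyz - center) ** 2).sum(axis=-1) <= r**2).astype(np.uint8)
    roi_vol = Volume(data=roi, grid=atlas.grid)

    lac = subject.series["lactate"]
    curve = _gamma_variate(config, "lactate")
    amp_map = lac.data.sum(axis=3)
    idx, frac = _sphere_fraction(lac.grid, center, r)
    new_amp = (1.0 - frac) * amp_map[idx] + frac * amp_lesion
    data = lac.data.copy()
    data[idx] = new_amp[:, None] * curve
    new_series = DynamicMetaboliteSeries(
        metabolite="lactate", data=data,
        frame_interval=lac.frame_interval, grid=lac.grid,
    )

    p = float(expit(config.outcome_alpha + config.outcome_beta * z_target))
    outcome = "progressed" if rng.random() < p else "stable"
    truth = {
        "lesion_id": lesion_id,
        "subject_id": subject.subject_id,
        "z_target": z_target,
        "lesion_amplitude": amp_lesion,
        "progression_prob": p,
        "outcome": outcome,
        "center_x_mm": float(center[0]),
        "center_y_mm": float(center[1]),
        "center_z_mm": float(center[2]),
    }
    return roi_vol, new_series, truth


def generate_cohort(config: PhantomConfig, out_dir: str | Path | None = None) -> CohortDataset:
    """Generate a full synthetic cohort (shared atlas geometry).

    One atlas is shared by all subjects; each subject receives its own
    scale factor, region noise and >= 1 lesion.  Optionally the first
    ``prior_srs_lesions`` subjects carry one extra previously-treated
    lesion (flagged, excluded from ROC by default downstream).
    """
    ss = np.random.SeedSequence(config.seed)
    seeds = ss.generate_state(1 + config.n_subjects * (1 + config.lesions_per_subject)
                              + config.prior_srs_lesions).tolist()
    next_seed = iter(seeds).__next__

    atlas = generate_atlas(config, next_seed())

    subjects: dict[str, SubjectData] = {}
    lesion_masks: dict[str, Volume] = {}
    cohort_rows, truth_rows = [], []
    sid_types: list[tuple[str, str]] = []
    i = 0
    for ptype, count in config.n_subjects_per_type.items():
        for _ in range(count):
            i += 1
            sid_types.append((f"S{i:02d}", ptype))

    for sid, ptype in sid_types:
        subj = generate_subject(config, atlas, next_seed(), subject_id=sid)
        for k in range(config.lesions_per_subject):
            lid = f"{sid}_L{k + 1}"
            roi, new_lac, truth = generate_lesion(
                config, atlas, subj, next_seed(), lesion_id=lid
            )
            subj.series["lactate"] = new_lac
            lesion_masks[lid] = roi
            truth_rows.append(truth)
            cohort_rows.append({
                "subject_id": sid, "lesion_id": lid, "primary_type": ptype,
                "prior_srs": False, "outcome": truth["outcome"],
            })
        subjects[sid] = subj

    for j in range(config.prior_srs_lesions):
        sid, ptype = sid_types[j % len(sid_types)]
        subj = subjects[sid]
        lid = f"{sid}_P{j + 1}"
        roi, new_lac, truth = generate_lesion(
            config, atlas, subj, next_seed(), lesion_id=lid
        )
        subj.series["lactate"] = new_lac
        lesion_masks[lid] = roi
        truth_rows.append(truth)
        cohort_rows.append({
            "subject_id": sid, "lesion_id": lid, "primary_type": ptype,
            "prior_srs": True, "outcome": truth["outcome"],
        })

    cohort = CohortTable(pd.DataFrame(
        cohort_rows,
        columns=["subject_id", "lesion_id", "primary_type", "prior_srs", "outcome"],
    ))
    truth_df = pd.DataFrame(
        truth_rows,
        columns=["lesion_id", "subject_id", "z_target", "lesion_amplitude",
                 "progression_prob", "outcome", "center_x_mm", "center_y_mm",
                 "center_z_mm"],
    )
    truth_df["subject_scale"] = truth_df["subject_id"].map(
        {sid: s.scale for sid, s in subjects.items()}
    )
    dataset = CohortDataset(
        config=config, atlas=atlas, subjects=subjects,
        lesion_masks=lesion_masks, cohort=cohort, truth=truth_df,
    )
    if out_dir is not None:
        dataset.write(out_dir)
        logger.info("wrote synthetic cohort to %s", out_dir)
    return dataset
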