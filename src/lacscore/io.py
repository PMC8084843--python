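"""NIfTI and table I/O with validation."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .grid import Grid, Volume

logger = logging.getLogger(__name__)

__all__ = [
    "PRIMARY_TYPES",
    "OUTCOMES",
    "CohortTable",
    "load_volume",
    "save_volume",
    "load_cohort_table",
]

PRIMARY_TYPES = ("NSCLC", "RCC", "breast", "colorectal", "other")
OUTCOMES = ("progressed", "stable", "unknown")

COHORT_COLUMNS = ["subject_id", "lesion_id", "primary_type", "prior_srs", "outcome"]


def load_volume(
    path: str | Path,
    expected_frames: int | None = None,
    allow_nan: bool = False,
) -> Volume:
    """Load a 3-D or 4-D NIfTI volume.

    Integer payloads (label volumes, masks) keep their dtype; no
    interpolation or reorientation is applied.  Non-finite voxels are
    rejected unless ``allow_nan`` is set (resampled maps use NaN as
    their missing marker).  If ``expected_frames`` is given and the file
    carries a different number of frames, a warning is logged and the
    actual count is kept.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume not found: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several unrelated types
        raise ValueError(f"{path} is not a readable NIfTI file: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim not in (3, 4):
        raise ValueError(f"{path}: expected 3-D or 4-D data, got ndim={data.ndim}")
    bad = ~np.isfinite(data)
    if allow_nan:
        bad &= ~np.isnan(data)
    if bad.any():
        raise ValueError(f"{path}: contains {int(bad.sum())} non-finite voxel(s)")
    vol = Volume(data=data, grid=Grid(shape=data.shape[:3], affine=img.affine))
    if expected_frames is not None and vol.n_frames != expected_frames:
        logger.warning(
            "%s: expected %d frames, found %d; keeping %d",
            path, expected_frames, vol.n_frames, vol.n_frames,
        )
    return vol


def save_volume(vol: Volume, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(vol.data, vol.grid.affine), str(path))
    return path


@dataclass
class CohortTable:
    """Validated cohort table: one row per lesion.

    Columns: subject_id, lesion_id, primary_type, prior_srs, outcome and
    optionally lesion_zscore.  Rows with outcome "unknown" or with
    prior_srs set are retained (they are scored) but flagged as excluded
    from the ROC/ANOVA stages.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df.copy()
        missing = [c for c in COHORT_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"cohort table missing column(s): {missing}")
        df["subject_id"] = df["subject_id"].astype(str)
        df["lesion_id"] = df["lesion_id"].astype(str)
        df["primary_type"] = df["primary_type"].astype(str)
        df["outcome"] = df["outcome"].astype(str)
        if df["prior_srs"].dtype == object:
            df["prior_srs"] = df["prior_srs"].astype(str).str.lower().isin(
                ("true", "1", "yes")
            )
        df["prior_srs"] = df["prior_srs"].astype(bool)

        dup = df["lesion_id"][df["lesion_id"].duplicated()].unique()
        if len(dup):
            raise ValueError(f"duplicate lesion_id(s): {sorted(dup)}")
        bad_type = df.loc[~df["primary_type"].isin(PRIMARY_TYPES)]
        if len(bad_type):
            raise ValueError(
                "unrecognized primary_type in rows "
                f"{bad_type.index.tolist()}: {bad_type['primary_type'].tolist()} "
                f"(allowed: {list(PRIMARY_TYPES)})"
            )
        bad_out = df.loc[~df["outcome"].isin(OUTCOMES)]
        if len(bad_out):
            raise ValueError(
                f"unrecognized outcome in rows {bad_out.index.tolist()}: "
                f"{bad_out['outcome'].tolist()} (allowed: {list(OUTCOMES)})"
            )
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def subject_ids(self) -> list[str]:
        return sorted(self.df["subject_id"].unique().tolist())

    def group_sizes(self) -> dict[str, int]:
        """Number of subjects per primary cancer type."""
        g = self.df.drop_duplicates("subject_id").groupby("primary_type")
        return g.size().to_dict()

    def roc_eligible(self, include_prior_srs: bool = False) -> pd.Series:
        """Boolean mask of lesions usable for ROC/ANOVA.

        Lesions with unknown 6-month outcome are never eligible;
        previously-treated lesions are excluded by default.
        """
        ok = self.df["outcome"] != "unknown"
        if not include_prior_srs:
            ok &= ~self.df["prior_srs"]
        return ok

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        self.df.to_csv(path, index=False)
        return path


def load_cohort_table(path: str | Path) -> CohortTable:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"cohort table not found: {path}")
    df = pd.read_csv(path)
    table = CohortTable(df)
    n_excl = int((~table.roc_eligible()).sum())
    if n_excl:
        logger.info("%s: %d lesion(s) flagged excluded-from-ROC", path, n_excl)
    return table
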