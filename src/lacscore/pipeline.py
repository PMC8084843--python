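"""End-to-end analysis pipeline.

Chains the stages: (optional) simulation -> per-metabolite AUC maps ->
resampling to the anatomical grid -> region/lesion z-scores -> cohort
statistics -> per-type rescaling and ROC prediction.  Every stage's
outputs are plain CSV/JSON; a fixed config + seed gives byte-identical
results.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .grid import Volume
from .io import CohortTable, load_cohort_table, load_volume
from .maps import DynamicMetaboliteSeries, compute_auc_map, resample_to_grid
from .normalization import (
    lesion_mean,
    lesion_zscore,
    profile_zscores,
    region_means,
)
from .phantom import PhantomConfig, generate_cohort
from .prediction import analyze_roc, rescale_by_type
from .stats import kendalls_w, oneway_anova

logger = logging.getLogger(__name__)

__all__ = [
    "subject_region_profile",
    "analyze_cohort",
    "cohort_statistics",
    "predict_outcomes",
    "run_pipeline",
]

_FLOAT_FMT = "%.12g"


def subject_region_profile(
    series: DynamicMetaboliteSeries,
    atlas: Volume,
    subject_id: str = "",
    ddof: int = 1,
    roi_exclude: Volume | None = None,
):
    """AUC map -> anatomical grid -> region means -> z-score profile.

    Returns ``(profile, resampled_map)``; the resampled map is reused
    for lesion means so each subject's volume is interpolated once.
    """
    aucmap = compute_auc_map(series)
    resampled = resample_to_grid(aucmap, atlas.grid)
    x = region_means(resampled, atlas, n_regions=_count_labels(atlas),
                    roi_exclude=roi_exclude)
    profile = profile_zscores(x, subject_id=subject_id, ddof=ddof)
    return profile, resampled


def _count_labels(atlas: Volume) -> int:
    return int(atlas.data.max())


def analyze_cohort(
    atlas: Volume,
    lactate_series: dict[str, DynamicMetaboliteSeries],
    cohort: CohortTable,
    lesion_masks: dict[str, Volume],
    ddof: int = 1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score every subject and lesion of a cohort.

    Returns ``(region_z, lesion_scores)``: region_z is subjects x
    regions (z-scores); lesion_scores has one row per cohort lesion
    with its mean signal and z-score.
    """
    n_regions = _count_labels(atlas)
    missing = set(cohort.subject_ids) - set(lactate_series)
    if missing:
        raise KeyError(f"no lactate series for subject(s) {sorted(missing)}")
    profiles, resampled = {}, {}
    z_rows = {}
    for sid in sorted(lactate_series):
        prof, rmap = subject_region_profile(
            lactate_series[sid], atlas, subject_id=sid, ddof=ddof
        )
        profiles[sid], resampled[sid] = prof, rmap
        z_rows[sid] = prof.z
    region_z = pd.DataFrame.from_dict(z_rows, orient="index")
    region_z.columns = [f"region_{i + 1:02d}" for i in range(n_regions)]
    region_z.index.name = "subject_id"
    region_z = region_z.sort_index()

    rows = []
    for rec in cohort.df.itertuples(index=False):
        if rec.lesion_id not in lesion_masks:
            raise KeyError(f"no ROI mask for lesion {rec.lesion_id}")
        x_les = lesion_mean(resampled[rec.subject_id], lesion_masks[rec.lesion_id])
        z_les = lesion_zscore(x_les, profiles[rec.subject_id])
        rows.append({
            "lesion_id": rec.lesion_id,
            "subject_id": rec.subject_id,
            "primary_type": rec.primary_type,
            "prior_srs": bool(rec.prior_srs),
            "outcome": rec.outcome,
            "x_lesion": x_les,
            "z_lesion": z_les,
        })
    lesion_df = pd.DataFrame(
        rows,
        columns=["lesion_id", "subject_id", "primary_type", "prior_srs",
                 "outcome", "x_lesion", "z_lesion"],
    )
    return region_z, lesion_df


def cohort_statistics(
    region_z: pd.DataFrame,
    lesion_scores: pd.DataFrame,
    include_prior_srs: bool = False,
) -> dict:
    """Kendall's W across subjects and one-way ANOVA of lesion z by type."""
    out: dict = {}
    if len(region_z) >= 2:
        conc = kendalls_w(region_z.to_numpy())
        out.update(W=conc.W, m=conc.m, n=conc.n, tie_corrected=conc.tie_corrected)
    else:
        out.update(W=None, m=len(region_z), n=region_z.shape[1])
        out["message"] = "concordance undefined for fewer than 2 subjects"
        logger.info("skipping Kendall's W: %s", out["message"])

    eligible = _eligible(lesion_scores, include_prior_srs)
    groups = [
        g["z_lesion"].to_numpy()
        for _, g in lesion_scores[eligible].groupby("primary_type")
    ]
    try:
        an = oneway_anova(groups)
        out.update(F=an.F, df_between=an.df_between, df_within=an.df_within,
                   anova_p=an.p)
    except ValueError as exc:
        out.update(F=None)
        out["anova_message"] = str(exc)
        logger.info("skipping ANOVA: %s", exc)
    return out


def _eligible(lesion_scores: pd.DataFrame, include_prior_srs: bool) -> pd.Series:
    ok = lesion_scores["outcome"].isin(["progressed", "stable"])
    if not include_prior_srs:
        ok &= ~lesion_scores["prior_srs"].astype(bool)
    return ok


def predict_outcomes(
    lesion_scores: pd.DataFrame,
    include_prior_srs: bool = False,
    alternative: str = "greater",
    method: str = "normal",
) -> tuple[pd.DataFrame, "object | None"]:
    """Per-type rescaling + pooled ROC against 6-month progression.

    Returns the scored table (``prediction_score`` column added for
    eligible lesions) and the ROCAnalysis, or None when the ROC is
    undefined (no eligible lesions or a single outcome class).
    """
    scored = lesion_scores.copy()
    scored["prediction_score"] = np.nan
    eligible = _eligible(scored, include_prior_srs)
    if eligible.sum() == 0:
        logger.info("no ROC-eligible lesions; prediction stage skipped")
        return scored, None
    sub = scored[eligible]
    scores = rescale_by_type(sub["z_lesion"].to_numpy(),
                             sub["primary_type"].to_numpy())
    scored.loc[eligible, "prediction_score"] = scores
    labels = (sub["outcome"] == "progressed").to_numpy().astype(int)
    if labels.min() == labels.max():
        logger.info("single outcome class among eligible lesions; ROC skipped")
        return scored, None
    roc = analyze_roc(scores, labels, alternative=alternative, method=method)
    return scored, roc


def _roc_to_dict(roc) -> dict:
    return {
        "auc": roc.auc, "U": roc.U, "n_pos": roc.n_pos, "n_neg": roc.n_neg,
        "p_value": roc.p_value, "optimal_threshold": roc.optimal_threshold,
        "tpr_opt": roc.tpr_opt, "fpr_opt": roc.fpr_opt, "ppv_opt": roc.ppv_opt,
    }


def load_config(config: str | Path | dict) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            return json.load(fh)
    return dict(config)


def _load_inputs(inputs: dict, frames_expected: int | None):
    atlas = load_volume(inputs["atlas"])
    cohort = load_cohort_table(inputs["cohort"])
    lactate = {}
    for sub in inputs["subjects"]:
        sid = str(sub["subject_id"])
        vol = load_volume(sub["lactate"], expected_frames=frames_expected)
        lactate[sid] = DynamicMetaboliteSeries(
            metabolite="lactate", data=vol.data.astype(float),
            frame_interval=float(sub.get("frame_interval_s", 5.0)), grid=vol.grid,
        )
        if "bicarbonate" not in sub:
            logger.info("subject %s: no bicarbonate file; lactate-only analysis", sid)
    masks = {
        lid: load_volume(path) for lid, path in inputs.get("lesion_masks", {}).items()
    }
    return atlas, lactate, cohort, masks


def run_pipeline(
    config: str | Path | dict,
    out_dir: str | Path,
    seed: int | None = None,
) -> dict:
    """Run the full chain described by a JSON config.

    The config either requests simulation (``{"simulate": {...phantom
    overrides...}}``) or names input files (``{"inputs": {"atlas": ...,
    "cohort": ..., "subjects": [...], "lesion_masks": {...}}}``).
    Writes region_zscores.csv, lesion_scores.csv, cohort_stats.json,
    roc.json, roc_curve.csv and summary.json under ``out_dir``.
    """
    cfg = load_config(config)
    if "simulate" not in cfg and "inputs" not in cfg:
        raise ValueError("config must contain either 'simulate' or 'inputs'")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    analysis = cfg.get("analysis", {})
    summary: dict = {"stages": []}

    def stage(name):
        logger.info("stage: %s", name)
        summary["stages"].append(name)

    try:
        if "simulate" in cfg:
            stage("simulate")
            sim = dict(cfg["simulate"])
            if seed is not None:
                sim["seed"] = int(seed)
            elif "seed" not in sim:
                sim["seed"] = int(cfg.get("seed", 0))
            for key in ("grid_shape", "c13_grid_shape", "fov_mm",
                        "lesion_z_target_range"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            pcfg = PhantomConfig(**sim)
            dataset = generate_cohort(pcfg, out_dir=out / "dataset")
            atlas, cohort = dataset.atlas, dataset.cohort
            lactate = {sid: s.series["lactate"] for sid, s in dataset.subjects.items()}
            masks = dataset.lesion_masks
            summary["simulate"] = {"seed": pcfg.seed,
                                   "n_subjects": pcfg.n_subjects,
                                   "n_lesions": len(masks)}
        elif "inputs" in cfg:
            stage("load")
            atlas, lactate, cohort, masks = _load_inputs(
                cfg["inputs"], analysis.get("frames_expected")
            )
        else:
            raise ValueError("config must contain either 'simulate' or 'inputs'")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'load/simulate' failed: {exc}") from exc

    try:
        stage("normalize")
        region_z, lesion_scores = analyze_cohort(
            atlas, lactate, cohort, masks, ddof=int(analysis.get("ddof", 1))
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'normalize' failed: {exc}") from exc
    region_z.to_csv(out / "region_zscores.csv", float_format=_FLOAT_FMT)
    lesion_scores.to_csv(out / "lesion_scores.csv", index=False,
                         float_format=_FLOAT_FMT)

    include_prior = bool(analysis.get("include_prior_srs", False))
    try:
        stage("cohort-stats")
        stats = cohort_statistics(region_z, lesion_scores,
                                  include_prior_srs=include_prior)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'cohort-stats' failed: {exc}") from exc
    (out / "cohort_stats.json").write_text(json.dumps(stats, indent=2, sort_keys=True))

    try:
        stage("predict")
        scored, roc = predict_outcomes(
            lesion_scores, include_prior_srs=include_prior,
            alternative=analysis.get("alternative", "greater"),
            method=analysis.get("method", "normal"),
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'predict' failed: {exc}") from exc
    scored.to_csv(out / "lesion_scores.csv", index=False, float_format=_FLOAT_FMT)
    if roc is not None:
        (out / "roc.json").write_text(
            json.dumps(_roc_to_dict(roc), indent=2, sort_keys=True)
        )
        pd.DataFrame({
            "threshold": roc.thresholds, "fpr": roc.fpr, "tpr": roc.tpr,
        }).to_csv(out / "roc_curve.csv", index=False, float_format=_FLOAT_FMT)
        summary["roc"] = _roc_to_dict(roc)
    else:
        summary["roc"] = None
        summary["roc_message"] = "ROC stage skipped (no eligible lesions or one class)"

    summary["cohort_stats"] = stats
    summary["n_subjects"] = len(cohort.subject_ids)
    summary["n_lesions"] = len(cohort)
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
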