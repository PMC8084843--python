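# lacscore

Scoring pipeline for hyperpolarized ¹³C-pyruvate brain MRI: dynamic
metabolite volumes are collapsed to area-under-the-curve (AUC) maps,
normalized against a 56-region anatomical parcellation by within-subject
z-scoring, and lesion z-scores are turned into per-cancer-type prediction
scores whose pooled ROC curve predicts treatment failure at 6 months.

Because the subject-level signal strength of a hyperpolarized substrate
varies over a wide range (polarization level, injection timing), absolute
signal is not comparable across subjects.  The core normalization expresses
every region's and lesion's signal in units of the spread of the 56
atlas-region means *within the same subject*:

```
z_i      = (x_i      − μ) / σ
z_lesion = (x_lesion − μ) / σ
```

with μ, σ the mean and standard deviation of that subject's 56 region-mean
lactate signals.  Any multiplicative subject factor cancels exactly.

A synthetic phantom generator (`lacscore.phantom`) produces multi-subject
datasets with the statistical structure the analysis assumes — a canonical
cross-region lactate pattern, log-normal subject scale factors,
gamma-variate voxel kinetics on a coarse 1.5-cm metabolite grid, and
spherical lesions whose lactate elevation drives a logistic outcome model —
plus ground-truth tables for parameter-recovery tests.

## Modules

| module | contents |
| --- | --- |
| `lacscore.grid` | voxel grids with world-affine geometry |
| `lacscore.io` | NIfTI volume I/O, validated cohort tables |
| `lacscore.maps` | dynamic series, AUC maps, world-coordinate trilinear resampling |
| `lacscore.normalization` | region means, z-score profiles, lesion z-scores |
| `lacscore.stats` | Kendall's W (tie-corrected), one-way ANOVA |
| `lacscore.prediction` | per-type min-max rescaling, ROC/AUC (Mann–Whitney U form), Youden point, PPV, significance |
| `lacscore.phantom` | synthetic atlas/subject/lesion/cohort generator |
| `lacscore.pipeline` | stage orchestration, CSV/JSON outputs |
| `lacscore.cli` | `lacscore` command-line driver |

## CLI

```bash
# synthetic cohort (NIfTI + CSV) under out/data
lacscore simulate --seed 1 --out-dir out/data

# AUC map from a 4-D series, resampled onto the anatomical grid
lacscore aucmap --in out/data/subjects/S01/lactate_dynamic.nii.gz \
                --out out/S01_auc.nii.gz --resample-to out/data/atlas.nii.gz

# full chain from a JSON config (simulate or file inputs)
echo '{"seed": 1, "simulate": {}}' > config.json
lacscore run --config config.json --out-dir out/results

# stage-wise, from intermediate CSVs
lacscore cohort-stats --region-z out/results/region_zscores.csv \
                      --lesions out/results/lesion_scores.csv --out stats.json
lacscore predict --lesions out/results/lesion_scores.csv --out-dir out/pred
```

`run` writes `region_zscores.csv` (subjects × 56 region z-scores),
`lesion_scores.csv` (per-lesion mean signal, z-score, prediction score),
`cohort_stats.json` (Kendall's W, ANOVA), `roc.json` / `roc_curve.csv`
and `summary.json`.  Identical config + seed ⇒ byte-identical outputs.
Lesions with unknown 6-month outcome or previously treated (prior SRS)
are scored but excluded from ROC/ANOVA by default
(`--include-prior-srs` to include the latter).

## Synthetic dataset layout

```
<out-dir>/
  atlas.nii.gz                      # 56-region label volume (ellipsoid brain)
  cohort.csv                        # subject_id, lesion_id, primary_type, prior_srs, outcome
  truth.csv                         # generative ground truth (z*, outcome prob, scale, centres)
  subjects/<sid>/<met>_dynamic.nii.gz   # 16×16×24×12 dynamic series per metabolite
  lesions/<lesion_id>_mask.nii.gz   # binary ROI on the anatomical grid
```
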