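import numpy as np
import pytest
from scipy.special import expit

from lacscore import (
    CANONICAL_PATTERN,
    PhantomConfig,
    analyze_cohort,
    generate_atlas,
    generate_cohort,
    generate_lesion,
    generate_subject,
    profile_zscores,
    roc_auc,
    subject_region_profile,
)
from conftest import small_config


class TestCanonicalPattern:
    def test_z_range_minus3_to_2(self):
        z = profile_zscores(CANONICAL_PATTERN).z
        assert z.min() == pytest.approx(-3.0, abs=1e-5)
        assert z.max() == pytest.approx(2.0, abs=1e-5)

    def test_positive_and_56_long(self):
        assert CANONICAL_PATTERN.shape == (56,)
        assert (CANONICAL_PATTERN > 0).all()


class TestGenerateAtlas:
    def test_56_nonzero_labels(self, atlas):
        labels, counts = np.unique(atlas.data, return_counts=True)
        nonzero = labels[labels > 0]
        assert len(nonzero) == 56
        assert nonzero.min() == 1 and nonzero.max() == 56
        assert (counts[labels > 0] > 0).all()

    def test_background_outside_mask(self, atlas):
        assert (atlas.data == 0).any()

    def test_determinism(self, session_config):
        a1 = generate_atlas(session_config, seed=5)
        a2 = generate_atlas(session_config, seed=5)
        np.testing.assert_array_equal(a1.data, a2.data)

    def test_different_seeds_differ(self, session_config):
        a1 = generate_atlas(session_config, seed=5)
        a2 = generate_atlas(session_config, seed=6)
        assert (a1.data != a2.data).any()

    def test_regions_connected(self, atlas):
        from scipy.ndimage import label as cc_label
        for region in (1, 14, 33, 56):
            _, n = cc_label(atlas.data == region)
            assert n == 1

    def test_tiny_grid_rejected(self):
        cfg = small_config(grid_shape=(8, 8, 8))
        with pytest.raises(ValueError, match="too small"):
            generate_atlas(cfg, seed=0)


class TestGenerateSubject:
    def test_noise_free_limit_proportional_to_pattern(self, atlas):
        cfg = small_config(subject_scale_sigma=0.0, region_noise_sd=0.0)
        subj = generate_subject(cfg, atlas, seed=1)
        ratio = subj.region_amplitudes / CANONICAL_PATTERN
        assert np.allclose(ratio, ratio[0], rtol=1e-12)

    def test_frame_sum_equals_region_amplitude(self, atlas, session_config):
        subj = generate_subject(session_config, atlas, seed=2)
        lac = subj.series["lactate"]
        frame_sum = lac.data.sum(axis=3)
        vals = np.unique(frame_sum[frame_sum > 0])
        for v in vals:
            assert np.any(np.isclose(subj.region_amplitudes, v, rtol=1e-9))

    def test_scale_invariance_of_zscores(self, atlas):
        # same noise seed, scales differing 2x -> identical z-score vectors
        cfg = small_config()
        s1 = generate_subject(cfg, atlas, seed=9, scale=2.0)
        s2 = generate_subject(cfg, atlas, seed=9, scale=1.0)
        p1, _ = subject_region_profile(s1.series["lactate"], atlas)
        p2, _ = subject_region_profile(s2.series["lactate"], atlas)
        assert np.allclose(p1.z, p2.z, atol=1e-10)

    def test_determinism(self, atlas, session_config):
        a = generate_subject(session_config, atlas, seed=4)
        b = generate_subject(session_config, atlas, seed=4)
        np.testing.assert_array_equal(
            a.series["lactate"].data, b.series["lactate"].data
        )
        assert a.scale == b.scale

    def test_all_metabolites_rendered(self, atlas, session_config):
        subj = generate_subject(session_config, atlas, seed=4)
        assert set(subj.series) == {"pyruvate", "lactate", "bicarbonate"}
        assert subj.series["pyruvate"].data.sum() > subj.series["lactate"].data.sum()


class TestGenerateLesion:
    def test_zero_target_equals_region_mean(self, atlas):
        cfg = small_config(lesion_z_target_range=(0.0, 0.0))
        subj = generate_subject(cfg, atlas, seed=3)
        _, _, truth = generate_lesion(cfg, atlas, subj, seed=10)
        assert truth["z_target"] == 0.0
        assert truth["lesion_amplitude"] == pytest.approx(
            subj.region_amplitudes.mean()
        )

    def test_roi_mask_nonempty_sphere(self, atlas, session_config):
        subj = generate_subject(session_config, atlas, seed=3)
        roi, _, truth = generate_lesion(session_config, atlas, subj, seed=11)
        vol_mm3 = roi.data.sum() * np.prod(roi.grid.spacing)
        sphere = 4 / 3 * np.pi * session_config.lesion_radius_mm**3
        assert vol_mm3 == pytest.approx(sphere, rel=0.35)

    def test_beta_zero_rate_matches_logistic_alpha(self, atlas):
        # Monte-Carlo: with beta = 0 the progression rate is logistic(alpha)
        cfg = small_config(outcome_beta=0.0, outcome_alpha=-0.5)
        subj = generate_subject(cfg, atlas, seed=3)
        n = 2000
        rng = np.random.default_rng(123)
        hits = 0
        for _ in range(n):
            _, _, truth = generate_lesion(
                cfg, atlas, subj, seed=int(rng.integers(2**31))
            )
            hits += truth["outcome"] == "progressed"
        p_hat = hits / n
        p_true = float(expit(-0.5))
        # 99.9% binomial CI
        ci = 3.29 * np.sqrt(p_true * (1 - p_true) / n)
        assert abs(p_hat - p_true) < ci

    def test_large_beta_recovered_z_separates_outcomes(self):
        # end-to-end recovery: strong outcome slope -> recovered z has AUC > 0.9
        zs, ys = [], []
        for rep in range(10):
            cfg = small_config(seed=100 + rep, outcome_beta=10.0,
                               lesion_z_target_range=(-2.0, 4.0),
                               lesions_per_subject=2)
            ds = generate_cohort(cfg)
            lac = {sid: s.series["lactate"] for sid, s in ds.subjects.items()}
            _, lesions = analyze_cohort(ds.atlas, lac, ds.cohort, ds.lesion_masks)
            zs.append(lesions["z_lesion"].to_numpy())
            ys.append((lesions["outcome"] == "progressed").to_numpy().astype(int))
        z = np.concatenate(zs)
        y = np.concatenate(ys)
        assert len(z) >= 200
        auc, _ = roc_auc(z, y)
        assert auc > 0.9

    def test_radius_exceeding_mask_rejected(self):
        with pytest.raises(ValueError, match="radius"):
            small_config(lesion_radius_mm=60.0)


class TestParameterRecovery:
    def test_high_fidelity_recovery(self):
        # low noise + lesion much larger than a metabolite voxel
        # (one lesion per subject: overlapping lesions contaminate each other)
        z_rec, z_true = [], []
        for rep in range(3):
            cfg = small_config(seed=77 + rep, region_noise_sd=0.05,
                               lesion_radius_mm=25.0)
            ds = generate_cohort(cfg)
            lac = {sid: s.series["lactate"] for sid, s in ds.subjects.items()}
            _, lesions = analyze_cohort(ds.atlas, lac, ds.cohort, ds.lesion_masks)
            merged = lesions.merge(ds.truth[["lesion_id", "z_target"]],
                                   on="lesion_id")
            z_rec.append(merged["z_lesion"].to_numpy())
            z_true.append(merged["z_target"].to_numpy())
        r = np.corrcoef(np.concatenate(z_rec), np.concatenate(z_true))[0, 1]
        assert r > 0.95

    def test_recovery_degrades_with_small_lesions(self):
        def slope_at(radius):
            cfg = small_config(seed=77, region_noise_sd=0.05,
                               lesion_radius_mm=radius, lesions_per_subject=2)
            ds = generate_cohort(cfg)
            lac = {sid: s.series["lactate"] for sid, s in ds.subjects.items()}
            _, lesions = analyze_cohort(ds.atlas, lac, ds.cohort, ds.lesion_masks)
            m = lesions.merge(ds.truth[["lesion_id", "z_target"]], on="lesion_id")
            # slope of recovered on true z: partial volume shrinks it toward 0
            return np.polyfit(m["z_target"], m["z_lesion"], 1)[0]
        assert slope_at(10.0) < slope_at(30.0)

    def test_progressed_mean_exceeds_stable_mean_when_beta_positive(self):
        zs, ys = [], []
        for rep in range(8):
            cfg = small_config(seed=300 + rep, outcome_beta=2.0)
            ds = generate_cohort(cfg)
            lac = {sid: s.series["lactate"] for sid, s in ds.subjects.items()}
            _, lesions = analyze_cohort(ds.atlas, lac, ds.cohort, ds.lesion_masks)
            zs.append(lesions["z_lesion"].to_numpy())
            ys.append((lesions["outcome"] == "progressed").to_numpy())
        z, y = np.concatenate(zs), np.concatenate(ys)
        assert z[y].mean() > z[~y].mean()


class TestGenerateCohort:
    def test_group_sizes_4_2_4_1(self, cohort_dataset):
        assert cohort_dataset.cohort.group_sizes() == {
            "NSCLC": 4, "RCC": 2, "breast": 4, "colorectal": 1,
        }
        assert len(cohort_dataset.cohort) == 11

    def test_truth_table_determinism(self, session_config):
        t1 = generate_cohort(session_config).truth
        t2 = generate_cohort(session_config).truth
        assert t1.equals(t2)

    def test_one_row_per_lesion(self, cohort_dataset):
        assert len(cohort_dataset.truth) == len(cohort_dataset.cohort)
        assert set(cohort_dataset.truth["lesion_id"]) == set(
            cohort_dataset.cohort.df["lesion_id"]
        )

    def test_single_subject_cohort(self):
        cfg = small_config(n_subjects_per_type={"other": 1})
        ds = generate_cohort(cfg)
        assert len(ds.cohort.subject_ids) == 1

    def test_prior_srs_lesions_flagged(self):
        cfg = small_config(prior_srs_lesions=2)
        ds = generate_cohort(cfg)
        assert int(ds.cohort.df["prior_srs"].sum()) == 2
        assert len(ds.cohort) == 13

    def test_dataset_written_to_disk(self, session_config, tmp_path):
        ds = generate_cohort(session_config, out_dir=tmp_path / "data")
        assert (tmp_path / "data" / "atlas.nii.gz").exists()
        assert (tmp_path / "data" / "cohort.csv").exists()
        assert (tmp_path / "data" / "truth.csv").exists()
        sid = ds.cohort.subject_ids[0]
        assert (tmp_path / "data" / "subjects" / sid / "lactate_dynamic.nii.gz").exists()

    def test_config_validation(self):
        with pytest.raises(ValueError):
            small_config(n_subjects_per_type={"NSCLC": 0})
        with pytest.raises(ValueError):
            small_config(subject_scale_sigma=-1.0)
        with pytest.raises(ValueError):
            small_config(frames=0)
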