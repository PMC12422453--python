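"""Synthetic-study generator: determinism, cohort statistics, closed forms."""

import numpy as np
import pandas as pd
import pytest

from skintherm.colorimetry import convert_melanin
from skintherm.roi import extract_median, make_control_roi
from skintherm.simulate import (CAMERA_PRESETS, Condition, GenerativeConfig,
                                generate_study, render_image_pair,
                                sample_cohort, simulate_measurements,
                                simulate_study)

NOISELESS = dict(pixel_noise_sd_E8XT_C=0.0, pixel_noise_sd_ONEPro_C=0.0,
                 frame_drift_sd_C=0.0, region_fluct_sd_C=0.0, gap_sd_C=0.0,
                 boundary_jitter_px=0.0)


class TestConfig:
    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            GenerativeConfig(n_subjects=1)
        with pytest.raises(ValueError):
            GenerativeConfig(baseline_sd_C=0.0)
        with pytest.raises(ValueError):
            GenerativeConfig(pixel_noise_sd_E8XT_C=-0.1)
        with pytest.raises(ValueError):
            GenerativeConfig(cooled_plateau_scale=1.3)

    def test_yaml_round_trip(self, tmp_path):
        cfg = GenerativeConfig(n_subjects=5, rng_seed=9, distance_effect_C=-0.2)
        cfg.to_yaml(tmp_path / "c.yaml")
        assert GenerativeConfig.from_yaml(tmp_path / "c.yaml") == cfg

    def test_derived_truths_consistent(self):
        cfg = GenerativeConfig()
        # marginal absolute cooling difference between cameras equals the
        # configured interaction, and likewise on the differential outcome
        assert cfg.cooling_depth("E8XT") - cfg.cooling_depth("ONEPro") == \
            pytest.approx(cfg.cooling_x_camera_abs_C)
        assert cfg.differential_cooling("ONEPro") - cfg.differential_cooling("E8XT") == \
            pytest.approx(cfg.cooling_x_camera_diff_C)


class TestCohort:
    def test_fixed_seed_reproduces_cohort(self):
        cfg = GenerativeConfig(n_subjects=10, rng_seed=3)
        assert sample_cohort(cfg) == sample_cohort(cfg)

    def test_large_sample_baseline_mean(self):
        cfg = GenerativeConfig(n_subjects=10_000, rng_seed=4)
        cohort = sample_cohort(cfg)
        mean = np.mean([s.baseline_skin_temp_C for s in cohort])
        se = cfg.baseline_sd_C / np.sqrt(cfg.n_subjects)
        assert abs(mean - cfg.baseline_mean_C) < 3 * se

    def test_melanin_consistency_and_categories(self):
        cohort = sample_cohort(GenerativeConfig(n_subjects=400, rng_seed=5))
        cats = pd.Series([s.eumelanin_category for s in cohort])
        for s in cohort:
            assert s.melanin_converted == pytest.approx(
                convert_melanin(s.melanin_raw), rel=1e-9)
        # truncation spans IntermediateLow..IntermediateHigh only, with the
        # cohort concentrated in IntermediateMid
        assert set(cats) <= {"IntermediateLow", "Intermediate",
                             "IntermediateMid", "IntermediateHigh"}
        assert cats.value_counts().idxmax() == "IntermediateMid"
        assert (cats == "IntermediateMid").mean() > 0.45


class TestRenderClosedForm:
    def _subject(self, cfg):
        return sample_cohort(cfg)[0]

    def test_baseline_median_is_exact(self):
        cfg = GenerativeConfig(n_subjects=2, rng_seed=6, **NOISELESS)
        sub = self._subject(cfg)
        for camera, distance, expected_shift in [
                ("E8XT", 35, 0.0),
                ("ONEPro", 35, cfg.camera_offset_ONEPro_C),
                ("E8XT", 50, cfg.distance_effect_C)]:
            img = render_image_pair(
                sub, Condition(camera, distance, "room", "stacked", "baseline"),
                cfg, cohort_mean_melanin=sub.melanin_converted)
            med = extract_median(img.thermal.grid, img.roi_true)
            assert med == pytest.approx(
                sub.baseline_skin_temp_C + expected_shift, abs=1e-9)

    def test_cooled_differential_matches_closed_form(self):
        cfg = GenerativeConfig(n_subjects=2, rng_seed=6, **NOISELESS)
        sub = self._subject(cfg)
        img = render_image_pair(
            sub, Condition("E8XT", 35, "room", "stacked", "cooled"), cfg,
            cohort_mean_melanin=sub.melanin_converted)
        roi_med = extract_median(img.thermal.grid, img.roi_true)
        ctl = make_control_roi(img.roi_true, img.thermal.grid.shape)
        ctl_med = extract_median(img.thermal.grid, ctl)
        # the differential cooling is distance-free (whole-frame distance
        # terms cancel between regions); the baseline gap rides on top
        expected_diff = (cfg.control_baseline_gap_C
                         + cfg.differential_cooling("E8XT"))
        assert roi_med - ctl_med == pytest.approx(expected_diff, abs=1e-9)

    def test_same_seed_renders_identical_frames(self):
        cfg = GenerativeConfig(n_subjects=2, rng_seed=8)
        sub = self._subject(cfg)
        cond = Condition("ONEPro", 50, "ring", "knee_forward", "cooled")
        img1 = render_image_pair(sub, cond, cfg, image_index=4, subject_index=1)
        img2 = render_image_pair(sub, cond, cfg, image_index=4, subject_index=1)
        np.testing.assert_array_equal(img1.thermal.grid, img2.thermal.grid)
        np.testing.assert_array_equal(img1.boundary_points_optical,
                                      img2.boundary_points_optical)

    def test_camera_resolution_presets(self):
        cfg = GenerativeConfig(n_subjects=2, rng_seed=8)
        sub = self._subject(cfg)
        for camera in ("E8XT", "ONEPro"):
            img = render_image_pair(
                sub, Condition(camera, 35, "room", "stacked", "baseline"), cfg)
            preset = CAMERA_PRESETS[camera]
            assert img.thermal.grid.shape == (preset.height, preset.width)

    def test_unknown_condition_rejected(self):
        with pytest.raises(ValueError, match="unknown condition"):
            Condition("E8XT", 42, "room", "stacked", "baseline")


class TestStudy:
    def test_manifest_counts_and_balance(self, tmp_path):
        cfg = GenerativeConfig(n_subjects=2, rng_seed=9)
        manifest = generate_study(cfg, tmp_path / "study",
                                  write_optical_rasters=False)
        assert len(manifest) == 2 * 48  # 12 conditions x 2 phases x 2 cameras
        per_subject = manifest.groupby("subject_id").size()
        assert (per_subject == 48).all()
        cells = manifest.groupby(["lighting", "distance_cm", "posture"]).size()
        assert cells.nunique() == 1  # full factorial is balanced
        assert (tmp_path / "study" / "ground_truth.json").exists()
        assert (tmp_path / "study" / "config.yaml").exists()
        assert (tmp_path / "study" / "colorimetry.csv").exists()
        # thermal frames exist on disk
        assert all((tmp_path / "study").joinpath().exists()
                   for _ in range(1))
        sample = manifest.iloc[0]
        assert (tmp_path / "study").exists()
        assert pd.io.common.file_exists(sample["thermal_path"])

    def test_measurement_fast_path_counts_and_determinism(self):
        cfg = GenerativeConfig(n_subjects=3, rng_seed=10)
        m1 = simulate_measurements(cfg)
        m2 = simulate_measurements(cfg)
        pd.testing.assert_frame_equal(m1, m2)
        assert len(m1) == 3 * 48 * 2  # images x regions
        assert set(m1["region"]) == {"roi", "control"}

    def test_study_stream_matches_fast_path_truth_structure(self):
        """The image path and the fast path share the generative means."""
        cfg = GenerativeConfig(n_subjects=2, rng_seed=12, **NOISELESS)
        sim = simulate_study(cfg)
        fast = simulate_measurements(cfg)
        for img in sim.iter_images():
            roi_med = extract_median(img.thermal.grid, img.roi_true)
            row = fast[(fast["image_id"] == img.image_id)
                       & (fast["region"] == "roi")].iloc[0]
            assert roi_med == pytest.approx(row["median_temp_C"], abs=1e-9)
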