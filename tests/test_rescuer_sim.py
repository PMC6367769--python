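"""Simulator: presets, chain geometry, determinism, and the calibrated
feature-level generator."""
import numpy as np
import pandas as pd
import pytest

import cprkinemat as ck
from cprkinemat.config import PREDICTOR_COLUMNS
from cprkinemat.errors import GeometryError, ValidationError


class TestReferencePosture:
    def test_correct_preset_values(self):
        pose = ck.reference_posture("correct")
        assert (pose.lkfa, pose.rkfa) == (109.0, 97.0)
        assert (pose.lefa, pose.refa) == (14.1, 3.7)
        assert pose.trunk_incl == 23.4
        assert pose.hip_height > 0

    def test_shallow_preset_reduces_knee_flexion_by_8(self):
        correct = ck.reference_posture("correct")
        shallow = ck.reference_posture("shallow")
        assert shallow.lkfa == correct.lkfa - 8
        assert shallow.rkfa == correct.rkfa - 8
        assert shallow.trunk_incl == correct.trunk_incl

    def test_unknown_preset_names_valid_ones(self):
        with pytest.raises(ValidationError, match="correct"):
            ck.reference_posture("standing")


class TestGenerateTrial:
    def test_deterministic_bit_identical(self, correct_pose):
        cfg = ck.TrialConfig(pose=correct_pose, duration_s=15.0, seed=9)
        kin1, man1 = ck.generate_trial(cfg)
        kin2, man2 = ck.generate_trial(cfg)
        for s in kin1.positions:
            assert np.array_equal(kin1.positions[s], kin2.positions[s])
        assert np.array_equal(man1.depth_mm, man2.depth_mm)

    def test_depth_and_rate_round_trip(self, correct_pose):
        """Cycle detector recovers the configured depth and rate."""
        cfg = ck.TrialConfig(
            pose=correct_pose, duration_s=60.0, depth_mm=50.0, rate_cpm=110.0,
            noise_sd_mm=0.0, seed=3,
        )
        _, man = ck.generate_trial(cfg)
        cycles = ck.detect_cycles(man)
        depth, rate = cycles.in_window(man.time_s[0], man.time_s[0] + 60.0)
        assert depth == pytest.approx(50.0, abs=0.5)
        assert rate == pytest.approx(110.0, abs=1.0)

    def test_noiseless_depth_fidelity_within_one_percent(self, correct_pose):
        cfg = ck.TrialConfig(
            pose=correct_pose, duration_s=30.0, depth_mm=42.0, noise_sd_mm=0.0,
            seed=0,
        )
        _, man = ck.generate_trial(cfg)
        cycles = ck.detect_cycles(man)
        assert cycles.depths_mm.mean() == pytest.approx(42.0, rel=0.01)

    def test_manikin_clock_offset_applied(self, correct_pose):
        cfg = ck.TrialConfig(
            pose=correct_pose, duration_s=12.0, clock_offset_s=1.25, seed=1
        )
        kin, man = ck.generate_trial(cfg)
        assert man.time_s[0] - kin.time_s[0] == pytest.approx(1.25)

    def test_depth_drift_shifts_per_minute_amplitude(self, correct_pose):
        cfg = ck.TrialConfig(
            pose=correct_pose, duration_s=180.0, depth_mm=50.0, noise_sd_mm=0.0,
            drift=ck.DriftConfig(depth_mm_per_min=-5.0), seed=0,
        )
        _, man = ck.generate_trial(cfg)
        cycles = ck.detect_cycles(man)
        d0, _ = cycles.in_window(0.0, 60.0)
        d2, _ = cycles.in_window(120.0, 180.0)
        assert d0 - d2 == pytest.approx(10.0, abs=0.5)

    def test_pose_drift_changes_extracted_angle(self, correct_pose):
        cfg = ck.TrialConfig(
            pose=correct_pose, duration_s=120.0, noise_sd_mm=0.0,
            drift=ck.DriftConfig(pose_deg_per_min={"lkfa": -4.0}), seed=0,
        )
        kin, _ = ck.generate_trial(cfg)
        series = ck.extract_pose_series(kin)
        first = series.window_means(0.0, 30.0)["lkfa"]
        second = series.window_means(60.0, 90.0)["lkfa"]
        assert first == pytest.approx(109.0, abs=0.5)
        assert second == pytest.approx(105.0, abs=0.5)

    def test_unreachable_geometry_raises(self, correct_pose):
        stubby = dict(ck.DEFAULT_SEGMENT_LENGTHS, upper_arm=60.0, forearm=50.0,
                      hand=20.0)
        cfg = ck.TrialConfig(pose=correct_pose, segment_lengths=stubby,
                             duration_s=12.0, seed=0)
        with pytest.raises(GeometryError, match="cannot reach"):
            ck.generate_trial(cfg)


class TestEquicorrelationSolver:
    def test_reference_calibration_rho(self):
        """With the tabulated betas and R2 = 0.418 the solved rho is -0.166:
        rho = (0.418 - 0.360587) / (2 * -0.172873)."""
        rho = ck.solve_equicorrelation(ck.TABLE_BETA, 0.418)
        assert rho == pytest.approx(-0.16606, abs=5e-4)

    def test_independent_predictors_when_r2_equals_beta_norm(self):
        beta = (0.3, -0.2, 0.25, -0.15)
        r2 = float(np.dot(beta, beta))
        assert ck.solve_equicorrelation(beta, r2) == pytest.approx(0.0, abs=1e-12)

    def test_unattainable_r2_reports_range(self):
        with pytest.raises(ValidationError, match="attainable"):
            ck.solve_equicorrelation(ck.TABLE_BETA, 0.9)


class TestGenerateFeatureTable:
    def test_deterministic_and_shapes(self):
        cfg = ck.StatsGenConfig(n_rows=500, seed=4)
        t1 = ck.generate_feature_table(cfg)
        t2 = ck.generate_feature_table(cfg)
        pd.testing.assert_frame_equal(t1, t2)
        assert list(t1.columns) == [*PREDICTOR_COLUMNS, "depth_mm"]
        assert t1.shape == (500, 5)

    def test_large_sample_ols_recovers_beta(self, oracle_ols=None):
        """Independent statsmodels fit on standardized variables recovers the
        configured coefficients at large n."""
        import statsmodels.api as sm

        table = ck.generate_feature_table(ck.StatsGenConfig(n_rows=100_000, seed=5))
        X = table[list(PREDICTOR_COLUMNS)].to_numpy()
        y = table["depth_mm"].to_numpy()
        Xz = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
        yz = (y - y.mean()) / y.std(ddof=1)
        fit = sm.OLS(yz, sm.add_constant(Xz)).fit()
        assert np.allclose(fit.params[1:], ck.TABLE_BETA, atol=0.01)

    def test_physical_scales_match_config(self):
        cfg = ck.StatsGenConfig(n_rows=200_000, seed=6)
        table = ck.generate_feature_table(cfg)
        for j, col in enumerate(PREDICTOR_COLUMNS):
            assert table[col].mean() == pytest.approx(cfg.pred_means[j], abs=3 * cfg.pred_sds[j] / np.sqrt(cfg.n_rows) + 1e-9)
            assert table[col].std(ddof=1) == pytest.approx(cfg.pred_sds[j], rel=0.02)
        assert table["depth_mm"].std(ddof=1) == pytest.approx(cfg.depth_sd, rel=0.02)

    def test_explicit_rho_overrides_target(self):
        cfg = ck.StatsGenConfig(n_rows=100, pred_rho=0.0, seed=1)
        table = ck.generate_feature_table(cfg)
        assert table.attrs["solved_rho"] == 0.0
        assert table.attrs["population_r2"] == pytest.approx(0.360587, abs=1e-4)
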