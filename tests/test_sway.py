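"""Body-COP trajectory, prediction ellipse, stabilogram."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pawpress import (CHI2_90_2D, CopTrajectory, DegenerateEllipseError,
                      PressureRecording, ValidationError, body_cop_trajectory,
                      empirical_coverage, fit_prediction_ellipse, label_paws,
                      simulate_recording, stabilogram_summary)
from tests.conftest import quiet_config


def gaussian_traj(n, sd_x, sd_y, seed=0):
    rng = np.random.default_rng(seed)
    return np.column_stack([rng.normal(0, sd_x, n), rng.normal(0, sd_y, n)])


class TestBodyCop:
    def test_two_equal_point_loads_balance_at_origin(self, default_spec):
        frames = np.zeros((5, 48, 48))
        # sensor centres at x = -55 and +55 mm on the y=5 row
        frames[:, 23, 18] = 100.0
        frames[:, 23, 29] = 100.0
        rec = PressureRecording(default_spec, frames, duration_s=0.05)
        traj = body_cop_trajectory(rec)
        assert np.allclose(traj.x_mm, 0.0)

    def test_lever_arithmetic_60_40(self, default_spec):
        # loads 60/40 at x = +/-50 -> COP at -50*0.4 + 50*0.6 = +10 mm
        frames = np.zeros((5, 48, 48))
        frames[:, 23, 18] = 40.0   # x = -55
        frames[:, 23, 29] = 60.0   # x = +55
        rec = PressureRecording(default_spec, frames, duration_s=0.05)
        traj = body_cop_trajectory(rec)
        assert np.allclose(traj.x_mm, -55 * 0.4 + 55 * 0.6)

    def test_zero_sway_trajectory_constant(self, symmetric_quiet):
        rec, _ = symmetric_quiet
        traj = body_cop_trajectory(rec, label_paws(rec))
        assert np.ptp(traj.x_mm) == 0.0 and np.ptp(traj.y_mm) == 0.0

    def test_body_cop_shifts_toward_loaded_limb(self, lame_trial):
        rec, truth = lame_trial
        traj = body_cop_trajectory(rec)
        # 60/40 toward the right limb: mean x near the truth offset
        assert traj.x_mm.mean() == pytest.approx(truth.body_cop_mean_mm[0],
                                                 abs=2.0)
        assert traj.x_mm.mean() > 5.0

    def test_empty_frames_dropped_with_warning(self, default_spec):
        frames = np.zeros((4, 48, 48))
        frames[:2, 23, 18] = 100.0
        frames[:2, 23, 29] = 100.0
        rec = PressureRecording(default_spec, frames, duration_s=0.04)
        with pytest.warns(UserWarning, match="empty frame"):
            traj = body_cop_trajectory(rec)
        assert len(traj) == 2

    def test_all_empty_raises(self, default_spec):
        rec = PressureRecording(default_spec, np.zeros((3, 48, 48)),
                                duration_s=0.03)
        with pytest.raises(ValidationError):
            body_cop_trajectory(rec)


class TestPredictionEllipse:
    def test_unit_circle_closed_form(self):
        th = np.linspace(0, 2 * np.pi, 400, endpoint=False)
        pts = np.column_stack([np.cos(th), np.sin(th)])
        ell = fit_prediction_ellipse(pts)
        lam = 0.5 * 400 / 399  # per-axis sample variance of the circle
        assert ell.area_mm2 == pytest.approx(math.pi * CHI2_90_2D * lam,
                                             rel=1e-12)
        assert ell.semi_axis_major_mm == pytest.approx(
            ell.semi_axis_minor_mm, rel=1e-9)

    def test_area_identity(self):
        ell = fit_prediction_ellipse(gaussian_traj(500, 2.0, 1.0, seed=3))
        assert ell.area_mm2 == pytest.approx(
            math.pi * ell.semi_axis_major_mm * ell.semi_axis_minor_mm)
        assert ell.semi_axis_major_mm >= ell.semi_axis_minor_mm > 0

    def test_isotropic_convergence_to_closed_form(self):
        sigma = 0.9806
        ell = fit_prediction_ellipse(gaussian_traj(20000, sigma, sigma,
                                                   seed=1))
        assert ell.area_mm2 == pytest.approx(
            math.pi * CHI2_90_2D * sigma ** 2, rel=0.05)

    def test_anisotropic_area(self):
        ell = fit_prediction_ellipse(gaussian_traj(20000, 0.50, 0.30, seed=2))
        assert ell.area_mm2 == pytest.approx(
            math.pi * CHI2_90_2D * 0.50 * 0.30, rel=0.05)
        # principal axis along x
        assert abs(math.sin(ell.orientation_rad)) < 0.25

    def test_degenerate_inputs_flagged(self):
        assert fit_prediction_ellipse(np.zeros((2, 2))).degenerate
        collinear = np.column_stack([np.arange(10.0), 2 * np.arange(10.0)])
        ell = fit_prediction_ellipse(collinear)
        assert ell.degenerate and ell.area_mm2 == 0.0

    def test_empirical_method_covers_exact_fraction(self):
        pts = gaussian_traj(1000, 1.0, 0.7, seed=5)
        ell = fit_prediction_ellipse(pts, method="empirical")
        assert empirical_coverage(pts, ell) == pytest.approx(0.9, abs=1e-9)

    @given(st.floats(-math.pi, math.pi), st.floats(-50, 50),
           st.floats(-50, 50))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_rigid_motions_preserve_area_and_transport_center(self, angle,
                                                              dx, dy):
        pts = gaussian_traj(300, 1.5, 0.6, seed=7)
        ell = fit_prediction_ellipse(pts)
        rot = np.array([[math.cos(angle), -math.sin(angle)],
                        [math.sin(angle), math.cos(angle)]])
        moved = pts @ rot.T + np.array([dx, dy])
        ell2 = fit_prediction_ellipse(moved)
        assert ell2.area_mm2 == pytest.approx(ell.area_mm2, rel=1e-9)
        expect_center = rot @ np.asarray(ell.center_xy_mm) + np.array([dx, dy])
        assert ell2.center_xy_mm == pytest.approx(tuple(expect_center),
                                                  abs=1e-6)


class TestCoverage:
    def test_large_sample_coverage_near_nominal(self):
        pts = gaussian_traj(20000, 1.0, 1.0, seed=4)
        ell = fit_prediction_ellipse(pts)
        assert empirical_coverage(pts, ell) == pytest.approx(0.90, abs=0.01)

    def test_scaling_ellipse_up_increases_coverage(self):
        from dataclasses import replace
        pts = gaussian_traj(2000, 1.0, 0.5, seed=6)
        ell = fit_prediction_ellipse(pts)
        big = replace(ell, semi_axis_major_mm=2 * ell.semi_axis_major_mm,
                      semi_axis_minor_mm=2 * ell.semi_axis_minor_mm)
        assert empirical_coverage(pts, big) > empirical_coverage(pts, ell)

    def test_points_at_center_fully_covered(self):
        pts = gaussian_traj(100, 1.0, 1.0, seed=8)
        ell = fit_prediction_ellipse(pts)
        center = np.tile(ell.center_xy_mm, (50, 1))
        assert empirical_coverage(center, ell) == 1.0

    def test_degenerate_coverage_raises(self):
        ell = fit_prediction_ellipse(np.zeros((5, 2)))
        with pytest.raises(DegenerateEllipseError):
            empirical_coverage(np.zeros((5, 2)), ell)


class TestStabilogram:
    def test_constant_trajectory_zeroes(self):
        traj = CopTrajectory(np.arange(5) / 100, np.full(5, 3.0),
                             np.full(5, -2.0))
        s = stabilogram_summary(traj)
        assert s.sd_x_mm == s.sd_y_mm == 0.0
        assert s.range_x_mm == s.range_y_mm == 0.0
        assert (s.mean_x_mm, s.mean_y_mm) == (3.0, -2.0)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(9)
        x, y = rng.normal(0, 1, 200), rng.normal(0, 2, 200)
        s = stabilogram_summary(CopTrajectory(np.arange(200) / 100, x, y))
        assert s.sd_x_mm == pytest.approx(np.std(x, ddof=1))
        assert s.range_y_mm == pytest.approx(y.max() - y.min())
        assert s.sd_x_mm <= s.range_x_mm and s.sd_y_mm <= s.range_y_mm

    def test_lateral_sway_dominates_when_simulated(self):
        # latero-lateral sway only: sd_x >> sd_y, the sound-dog stabilogram
        from pawpress.simulate import SwayModel
        cfg = quiet_config(sway=SwayModel.from_stationary_sd(1.5, 0.0),
                           noise_kPa=0.0, seed=10)
        rec = simulate_recording(cfg, duration_s=3.0)
        s = stabilogram_summary(body_cop_trajectory(rec))
        assert s.sd_x_mm > 5 * s.sd_y_mm
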