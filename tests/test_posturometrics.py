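"""Per-limb static parameters and asymmetry arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pawpress import (LimbParameters, PressureRecording, asymmetry_indices,
                      average_trials, compute_limb_parameters, label_paws,
                      limb_cop, limb_load_share, limb_pressures,
                      max_pressure_point, paw_area, simulate_recording)
from tests.conftest import quiet_config


def make_limb_params(limb="left", share=50.0, area=40.0, mean_p=100.0,
                     max_p=250.0, cop=(-80.0, 0.0), maxpt=(-85.0, -15.0)):
    return LimbParameters(limb, share, area, mean_p, max_p, cop, maxpt)


def two_print_recording(default_spec, left_value=100.0, right_value=100.0,
                        n_frames=4):
    frames = np.zeros((n_frames, 48, 48))
    frames[:, 20:26, 8:15] = left_value
    frames[:, 20:26, 33:40] = right_value
    return PressureRecording(default_spec, frames,
                             duration_s=n_frames / 100.0)


class TestLoadShare:
    def test_symmetric_trial_splits_50_50(self, symmetric_quiet):
        rec, _ = symmetric_quiet
        left, right = limb_load_share(rec, label_paws(rec))
        assert left == pytest.approx(50.0, abs=1e-9)
        assert right == pytest.approx(50.0, abs=1e-9)

    def test_shares_sum_to_100_exactly(self, lame_trial):
        rec, _ = lame_trial
        left, right = limb_load_share(rec, label_paws(rec))
        assert left + right == 100.0

    def test_recovers_generator_split(self, lame_trial):
        rec, truth = lame_trial
        left, right = limb_load_share(rec, label_paws(rec))
        assert left == pytest.approx(100 * truth.load_split[0], abs=0.5)
        assert right == pytest.approx(100 * truth.load_split[1], abs=0.5)

    def test_constructed_60_40(self, default_spec):
        # equal areas, pressures in ratio 60:40
        rec = two_print_recording(default_spec, 60.0, 40.0)
        left, right = limb_load_share(rec, label_paws(rec))
        assert left == pytest.approx(60.0, abs=1e-9)


class TestAreaAndPressures:
    def test_area_counts_cells(self, default_spec):
        rec = two_print_recording(default_spec)  # 6x7 cells per print
        seg = label_paws(rec)
        assert paw_area(rec, seg, "left") == pytest.approx(42.0)
        assert paw_area(rec, seg, "right") == pytest.approx(42.0)

    def test_area_equals_brute_force_frame_average(self, lame_trial):
        rec, _ = lame_trial
        seg = label_paws(rec)
        brute = np.mean([m.sum() for m in seg.left_masks])
        assert paw_area(rec, seg, "left") == pytest.approx(brute)

    def test_loaded_limb_is_larger_with_elasticity(self, lame_trial):
        rec, _ = lame_trial
        seg = label_paws(rec)
        assert paw_area(rec, seg, "right") > paw_area(rec, seg, "left")

    def test_uniform_print_mean_is_exact(self, default_spec):
        rec = two_print_recording(default_spec, left_value=89.61,
                                  right_value=112.11)
        seg = label_paws(rec)
        mean_l, max_l = limb_pressures(rec, seg, "left")
        assert mean_l == pytest.approx(89.61, abs=1e-12)
        assert max_l == pytest.approx(89.61, abs=1e-12)

    def test_peak_hold_max(self, default_spec):
        rec = two_print_recording(default_spec)
        rec.frames[2, 22, 10] = 212.0  # single capped sensor in one frame
        seg = label_paws(rec)
        _, max_l = limb_pressures(rec, seg, "left")
        assert max_l == 212.0

    def test_mean_below_max_everywhere(self, lame_trial):
        rec, _ = lame_trial
        seg = label_paws(rec)
        for limb in ("left", "right"):
            mean_p, max_p = limb_pressures(rec, seg, limb)
            assert rec.spec.pressure_floor_kPa <= mean_p <= max_p
            assert max_p <= rec.spec.pressure_ceiling_kPa


class TestCopAndPeakPoint:
    def test_single_sensor_print(self, default_spec):
        frames = np.zeros((3, 48, 48))
        frames[:, 10, 5] = 100.0
        frames[:, 10, 40] = 100.0
        rec = PressureRecording(default_spec, frames, duration_s=0.03)
        seg = label_paws(rec)
        x, y = default_spec.cell_center_mm(10, 5)
        assert limb_cop(rec, seg, "left") == pytest.approx((x, y))
        assert max_pressure_point(rec, seg, "left") == pytest.approx((x, y))

    def test_symmetric_print_cop_on_axis(self, symmetric_quiet):
        rec, truth = symmetric_quiet
        seg = label_paws(rec)
        xl, _ = limb_cop(rec, seg, "left")
        xr, _ = limb_cop(rec, seg, "right")
        assert xl == pytest.approx(-xr, abs=1e-6)
        assert xl == pytest.approx(truth.limb_cop_mm["left"][0], abs=2.0)

    def test_boosted_pad_attracts_peak(self):
        # boost the 4th digital pad of the right (lame) paw; the trial peak
        # must land at that pad's centre within one sensor pitch
        from pawpress.simulate import PawTemplate
        tpl = PawTemplate.default("right")
        amps = tpl.pad_amplitudes.copy()
        amps[3] *= 2.5
        boosted = PawTemplate(tpl.pad_centers_mm, amps, tpl.pad_radii_mm,
                              side="right")
        cfg = quiet_config(template_right=boosted, seed=8)
        rec = simulate_recording(cfg, duration_s=0.05)
        seg = label_paws(rec)
        px, py = max_pressure_point(rec, seg, "right")
        pad_xy = boosted.pad_centers_mm[3] + np.array([80.0, 0.0])
        assert abs(px - pad_xy[0]) <= 10.0 and abs(py - pad_xy[1]) <= 10.0


class TestAsymmetryIndices:
    def test_day0_distribution_difference(self):
        left = make_limb_params("left", share=39.72)
        right = make_limb_params("right", share=60.28)
        idx = asymmetry_indices(left, right)
        assert idx.distribution_diff_pct == pytest.approx(20.56)
        assert idx.sl_limb == "right"

    def test_identical_limbs_all_zero(self):
        idx = asymmetry_indices(make_limb_params("left"),
                                make_limb_params("right"))
        assert idx.distribution_diff_pct == 0.0
        assert idx.area_diff_pct == 0.0
        assert idx.mean_pressure_diff_pct == 0.0
        assert idx.max_pressure_diff == 0.0

    def test_area_difference_mean_normalised(self):
        left = make_limb_params("left", share=39.72, area=38.20)
        right = make_limb_params("right", share=60.28, area=49.93)
        idx = asymmetry_indices(left, right)
        # (49.93-38.20)/((49.93+38.20)/2)*100
        assert idx.area_diff_pct == pytest.approx(26.62, abs=0.005)

    @pytest.mark.parametrize("formula,expected", [
        ("mean_normalized", (359.89 - 298.18) / 329.035 * 100),
        ("ll_normalized", (359.89 - 298.18) / 298.18 * 100),
        ("absolute", 61.71),
    ])
    def test_max_pressure_formula_selectable(self, formula, expected):
        left = make_limb_params("left", share=48.19, max_p=298.18)
        right = make_limb_params("right", share=51.81, max_p=359.89)
        idx = asymmetry_indices(left, right, max_pressure_formula=formula)
        assert idx.max_pressure_diff == pytest.approx(expected, abs=1e-6)

    @given(st.floats(0.1, 99.9))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_distribution_diff_matches_shares(self, share):
        left = make_limb_params("left", share=share)
        right = make_limb_params("right", share=100 - share)
        idx = asymmetry_indices(left, right)
        assert idx.distribution_diff_pct == pytest.approx(abs(100 - 2 * share))
        assert idx.area_diff_pct >= 0
        assert idx.mean_pressure_diff_pct >= 0


class TestAveraging:
    def test_idempotent_on_identical_trials(self):
        p = make_limb_params()
        avg = average_trials([p, p, p])
        assert avg.load_share_pct == p.load_share_pct
        assert avg.limb_cop_xy_mm == pytest.approx(p.limb_cop_xy_mm)

    def test_simple_mean(self):
        trials = [make_limb_params(share=s) for s in (58.0, 60.0, 62.0)]
        assert average_trials(trials).load_share_pct == pytest.approx(60.0)

    def test_invalid_trials_filtered_before_average(self):
        # filter-then-average: the caller drops the invalid trial, the
        # average is over the remaining two
        trials = [make_limb_params(share=s) for s in (58.0, 62.0, 90.0)]
        valid = [True, True, False]
        kept = [t for t, v in zip(trials, valid) if v]
        assert average_trials(kept).load_share_pct == pytest.approx(60.0)

    def test_empty_and_mixed_inputs_rejected(self):
        with pytest.raises(ValueError):
            average_trials([])
        with pytest.raises(ValueError):
            average_trials([make_limb_params("left"),
                            make_limb_params("right")])


class TestMonotonicity:
    def test_share_area_pressure_increase_with_load(self):
        shares, areas, means = [], [], []
        for frac in (0.52, 0.58, 0.64):
            cfg = quiet_config(load_split=(1 - frac, frac), seed=4)
            rec = simulate_recording(cfg, duration_s=0.05)
            seg = label_paws(rec)
            shares.append(limb_load_share(rec, seg)[1])
            areas.append(paw_area(rec, seg, "right"))
            means.append(limb_pressures(rec, seg, "right")[0])
        assert shares == sorted(shares) and shares[0] < shares[-1]
        assert areas == sorted(areas) and areas[0] < areas[-1]
        assert means == sorted(means) and means[0] < means[-1]


def test_full_parameter_set(lame_trial):
    rec, truth = lame_trial
    limbs = compute_limb_parameters(rec, label_paws(rec))
    assert set(limbs) == {"left", "right"}
    assert limbs["left"].load_share_pct + limbs["right"].load_share_pct \
        == pytest.approx(100.0)
    for limb, lp in limbs.items():
        assert lp.mean_pressure_kPa <= lp.max_pressure_kPa
        # limb COP inside the limb's stable-footprint bounding box
        X, Y = rec.spec.sensor_centers_mm()
        mask = truth.left_mask if limb == "left" else truth.right_mask
        assert X[mask].min() <= lp.limb_cop_xy_mm[0] <= X[mask].max()
        assert Y[mask].min() <= lp.limb_cop_xy_mm[1] <= Y[mask].max()
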