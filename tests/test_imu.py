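"""IMU pipeline: resampling, segmentation, reflection, normalization,
padding, labeling and the end-to-end stride coverage guarantee."""

import numpy as np
import pandas as pd
import pytest

from gaitstgp import imu
from gaitstgp.errors import FormatError, SegmentationError
from gaitstgp.params import STGP_NAMES, default_population_params, make_cohort
from gaitstgp.simulate import simulate_trial


class TestResample:
    def test_constant_preserved(self):
        t = np.arange(0, 2, 0.025)
        _, out = imu.resample_to_100hz(t, np.full((1, len(t)), 3.7))
        np.testing.assert_allclose(out, 3.7)

    def test_ramp_endpoints(self):
        t = np.arange(0, 1.0 + 1e-9, 0.025)
        x = np.linspace(0, 1, len(t))[None, :]
        t_out, out = imu.resample_to_100hz(t, x)
        assert out[0, 0] == 0.0 and abs(out[0, -1] - 1.0) < 1e-12

    def test_inclusive_grid_arithmetic(self):
        # 4.000 s of 40 Hz input (161 samples inclusive) -> 401 samples
        t = np.arange(161) / 40.0
        t_out, _ = imu.resample_to_100hz(t, np.zeros((1, 161)))
        assert len(t_out) == 401
        np.testing.assert_allclose(np.diff(t_out), 0.01, atol=1e-12)

    def test_jitter_rejected(self):
        t = np.arange(0, 2, 0.025).copy()
        t[10] += 0.01  # one sample 40% off the nominal step
        with pytest.raises(FormatError):
            imu.resample_to_100hz(t, np.zeros((1, len(t))))


class TestSegmentStrides:
    def test_flat_stream_fails(self):
        with pytest.raises(SegmentationError):
            imu.segment_strides(np.zeros(500), 100.0)

    def test_short_stream_fails(self):
        with pytest.raises(ValueError):
            imu.segment_strides(np.zeros(50), 100.0)

    def test_scaling_leaves_boundaries(self, noisy_trial):
        _, up = imu.resample_to_100hz(noisy_trial.imu_time, noisy_trial.imu["foot_l"])
        w1 = imu.segment_strides(up[4], 100.0)
        w2 = imu.segment_strides(2.0 * up[4], 100.0)
        assert w1 == w2

    def test_boundaries_near_truth_heel_strikes(self, zero_noise_trial):
        tr = zero_noise_trial
        for side, sensor in (("L", "foot_l"), ("R", "foot_r")):
            _, up = imu.resample_to_100hz(tr.imu_time, tr.imu[sensor])
            windows = imu.segment_strides(up[4], 100.0)
            assert len(windows) >= 4
            hs = tr.events[side]["heel_strikes"]
            for a, _b in windows:
                assert np.min(np.abs(hs - a / 100.0)) <= 0.03

    def test_windows_ordered_nonoverlapping(self, noisy_trial):
        _, up = imu.resample_to_100hz(noisy_trial.imu_time, noisy_trial.imu["foot_r"])
        windows = imu.segment_strides(up[4], 100.0)
        for (a1, b1), (a2, b2) in zip(windows[:-1], windows[1:]):
            assert a1 < b1 <= a2 < b2


class TestReflectLeft:
    def test_involution(self):
        rng = np.random.default_rng(0)
        w = rng.normal(0, 0.3, (12, 50))
        np.testing.assert_array_equal(imu.reflect_left(imu.reflect_left(w)), w)

    def test_pure_sagittal_rotation_unchanged(self):
        w = np.zeros((6, 40))
        w[4] = 1.5  # gy only
        np.testing.assert_array_equal(imu.reflect_left(w), w)

    def test_mirrored_channels(self):
        w = np.ones((6, 10))
        out = imu.reflect_left(w)
        np.testing.assert_array_equal(out[[1, 3, 5]], -1.0)
        np.testing.assert_array_equal(out[[0, 2, 4]], 1.0)

    def test_right_side_rejected(self):
        with pytest.raises(ValueError):
            imu.reflect_left(np.zeros((6, 10)), side="R")

    def test_symmetric_gait_mirror(self):
        """With all stride variability off, a reflected left stride matches
        the corresponding right stride up to sensor noise and the 40 Hz
        sampling offset."""
        pop = default_population_params()
        frozen = {
            key: type(p)(p.cohort, p.pace, dict(p.mean), {k: 0.0 for k in p.sd})
            for key, p in pop.items()
        }
        profile = make_cohort(1, 0, seed=0)[0]
        profile = type(profile)(
            subject_id="S01", cohort="OA", laterality="none",
            offset_z={k: 0.0 for k in profile.offset_z},
        )
        tr = simulate_trial(profile, "normal", 6, seed=3, noise_scale=0.0,
                            population=frozen)
        segs, _ = imu.segments_from_trial(tr)
        left = [s for s in segs if s.side == "L"][2].data
        right = [s for s in segs if s.side == "R"][2].data
        # mirroring maps each left-side sensor onto the corresponding
        # right-side sensor: compare with the L/R sensor blocks swapped
        order = imu.SENSOR_ORDER
        swap = {"foot_l": "foot_r", "foot_r": "foot_l", "pelvis": "pelvis",
                "shank_l": "shank_r", "shank_r": "shank_l",
                "thigh_l": "thigh_r", "thigh_r": "thigh_l"}
        rows = np.concatenate(
            [np.arange(6) + 6 * order.index(swap[s]) for s in order]
        )
        resid = left - right[rows]
        rel = np.linalg.norm(resid) / np.linalg.norm(right)
        assert rel < 0.15


class TestNormalize:
    def test_full_scale_maps_to_one(self):
        w = np.zeros((6, 10))
        w[0] = imu.DEFAULT_ACC_RANGE
        w[3] = imu.DEFAULT_GYRO_RANGE
        out, n_sat = imu.normalize(w)
        assert out[0, 0] == 1.0 and out[3, 0] == 1.0 and n_sat == 0

    def test_zero_window(self):
        out, n_sat = imu.normalize(np.zeros((6, 10)))
        np.testing.assert_array_equal(out, 0.0)
        assert n_sat == 0

    def test_nonpositive_range_rejected(self):
        with pytest.raises(ValueError):
            imu.normalize(np.zeros((6, 5)), acc_range=0.0)

    def test_default_ranges_cover_simulated_gait(self, desk_dataset):
        """The default full-scale ranges leave the simulated cohort
        essentially unclipped and keep gyro channels well inside +-0.5."""
        dataset, report, _ = desk_dataset
        total = dataset.data.size
        assert report["saturated_samples"] / total < 1e-3
        gyro_rows = np.concatenate([np.arange(3, 6) + 6 * s for s in range(7)])
        assert np.abs(dataset.data[:, gyro_rows]).max() < 0.5


class TestPadToFixed:
    def test_pads_with_trailing_zeros(self):
        out, valid = imu.pad_to_fixed(np.ones((6, 150)))
        assert out.shape == (6, 212) and valid == 150
        np.testing.assert_array_equal(out[:, 150:], 0.0)

    def test_exact_length_identity(self):
        w = np.random.default_rng(1).normal(size=(6, 212))
        out, valid = imu.pad_to_fixed(w)
        np.testing.assert_array_equal(out, w)
        assert valid == 212

    def test_overflow_rejected(self):
        with pytest.raises(OverflowError):
            imu.pad_to_fixed(np.ones((6, 213)))


class TestLabelStrides:
    def _rows(self, times):
        return pd.DataFrame(
            {"stride_start_time": times} | {k: 0.0 for k in STGP_NAMES}
        )

    def test_nearest_within_tolerance(self):
        matches, dropped = imu.label_strides(
            [1.02, 2.5], self._rows([1.0, 2.0, 3.0]), tolerance=0.1
        )
        assert matches == [(0, 0)] and dropped == 1

    def test_zero_tolerance_exact_only(self):
        matches, dropped = imu.label_strides(
            [1.0, 2.01], self._rows([1.0, 2.0]), tolerance=0.0
        )
        assert matches == [(0, 0)] and dropped == 1

    def test_empty_rows_all_dropped(self):
        matches, dropped = imu.label_strides([0.5, 1.5], self._rows([]), 0.1)
        assert matches == [] and dropped == 2

    def test_duplicate_claims_closer_wins(self):
        matches, dropped = imu.label_strides(
            [0.98, 1.05], self._rows([1.0]), tolerance=0.1
        )
        assert matches == [(0, 0)] and dropped == 1


class TestStrideSegmentInvariants:
    def test_construction_checks(self):
        label = {k: 1.0 for k in STGP_NAMES}
        good = np.zeros((12, 212))
        imu.StrideSegment(good, 100, "L", "S01", "normal", 0.0, label)
        with pytest.raises(ValueError):  # values outside [-1, 1]
            imu.StrideSegment(good + 2.0, 100, "L", "S01", "normal", 0.0, label)
        bad = good.copy()
        bad[0, 150] = 0.5  # nonzero inside the padding region
        with pytest.raises(ValueError):
            imu.StrideSegment(bad, 100, "L", "S01", "normal", 0.0, label)
        with pytest.raises(ValueError):  # channel count not a sensor multiple
            imu.StrideSegment(np.zeros((5, 212)), 100, "L", "S01", "normal", 0.0, label)

    def test_feet_selection_yields_12_channels(self, desk_dataset):
        dataset, _, _ = desk_dataset
        idx = dataset.channel_indices(["foot_l", "foot_r"])
        assert len(idx) == 12
        assert dataset.data[:, idx].shape[1] == 12


class TestEndToEnd:
    def test_coverage_and_event_agreement(self, desk_dataset):
        """>= 95% of truth strides yield a labeled segment and segment
        starts agree with truth heel strikes with MAE <= 0.03 s."""
        dataset, report, trials = desk_dataset
        truth_total = sum(len(t.truth) for t in trials)
        covered = 0
        errs = []
        for t in trials:
            segs = dataset.meta[
                (dataset.meta.subject_id == t.subject_id) & (dataset.meta.pace == t.pace)
            ]
            for _, row in t.truth.iterrows():
                hit = (segs.side == row.side) & (
                    np.abs(segs.stride_start_time - row.stride_start_time) < 0.05
                )
                if hit.any():
                    covered += 1
            for _, seg in segs.iterrows():
                hs = t.events[seg.side]["heel_strikes"]
                errs.append(np.min(np.abs(hs - seg.stride_start_time)))
        assert covered / truth_total >= 0.95
        assert np.mean(errs) <= 0.03

    def test_labels_match_mocap_not_truth(self, zero_noise_trial):
        """Segment labels come from the marker analysis; at zero noise these
        coincide with the generator truth."""
        segs, _ = imu.segments_from_trial(zero_noise_trial)
        truth = zero_noise_trial.truth
        for s in segs[:5]:
            row = truth[
                (truth.side == s.side)
                & (np.abs(truth.stride_start_time - s.stride_start_time) < 0.02)
            ]
            if len(row):
                for k in STGP_NAMES:
                    assert abs(s.label[k] - float(row.iloc[0][k])) < 1e-3
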