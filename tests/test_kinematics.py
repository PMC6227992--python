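"""Kinematics: 3-D speed, segmentation, exclusions, resampling, peaks."""

import numpy as np
import pandas as pd
import pytest

from imikin.datatypes import (
    DegenerateCurveError,
    NoMovementError,
    Person,
    Tracker,
    Trajectory,
    ValidationError,
)
from imikin.kinematics import (
    apply_exclusions,
    mean_digit_params,
    peak_params,
    resample_normalize,
    segment_primary,
    speed3d,
)
from imikin.simulate import minimum_jerk_speed


class TestSpeed3d:
    def test_stationary_all_zero(self):
        traj = Trajectory(
            tracker=Tracker.WRIST, person=Person.ACTOR, fs=240.0, pos=np.ones((50, 3))
        )
        assert np.allclose(speed3d(traj), 0.0)

    def test_uniform_motion(self):
        fs = 240.0
        pos = np.zeros((100, 3))
        pos[:, 1] = 10.0 * np.arange(100) / fs  # 10 cm/s along y
        traj = Trajectory(tracker=Tracker.WRIST, person=Person.ACTOR, fs=fs, pos=pos)
        assert np.allclose(speed3d(traj), 10.0, atol=1e-9)

    def test_circular_motion_tangential_speed(self):
        """Speed of uniform circular motion is r * omega (closed form)."""
        fs, r, omega = 240.0, 5.0, 2 * np.pi * 1.5
        t = np.arange(1000) / fs
        pos = np.column_stack([r * np.cos(omega * t), r * np.sin(omega * t), 0 * t])
        traj = Trajectory(tracker=Tracker.WRIST, person=Person.ACTOR, fs=fs, pos=pos)
        interior = speed3d(traj)[2:-2]
        assert np.allclose(interior, r * omega, rtol=1e-3)

    def test_too_short_rejected(self):
        with pytest.raises(ValidationError):
            speed3d(
                Trajectory(
                    tracker=Tracker.WRIST, person=Person.ACTOR, fs=240.0, pos=np.zeros((2, 3))
                )
            )


class TestSegmentPrimary:
    def test_minimum_jerk_threshold_crossings(self):
        """Onset/offset match the analytic threshold crossings of the
        closed-form minimum-jerk speed to within one sample."""
        fs, D, T = 240.0, 64.0, 1.2  # peak = 1.875 * 64 / 1.2 = 100 cm/s
        t = np.arange(int(T * fs) + 1) / fs
        v = minimum_jerk_speed(t, D, T)
        onset, offset = segment_primary(v)
        dense = np.linspace(0, T, 2_000_001)
        vd = minimum_jerk_speed(dense, D, T)
        first = dense[np.argmax(vd >= 12.0)]
        after_peak = dense > T / 2
        last = dense[after_peak][np.argmax(vd[after_peak] < 12.0)]
        assert abs(onset / fs - first) <= 1.0 / fs
        assert abs(offset / fs - last) <= 1.0 / fs

    def test_never_reaching_threshold_flags_no_movement(self):
        with pytest.raises(NoMovementError):
            segment_primary(np.full(100, 5.0))

    def test_plateau_then_drop(self):
        """Hand-applied rule on a crafted vector: offset is the first
        sub-threshold sample after the global peak."""
        v = np.array([0, 5, 13, 40, 80, 40, 13, 11, 13, 5, 0], dtype=float)
        onset, offset = segment_primary(v)
        assert onset == 2  # first >= 12
        assert offset == 7  # first < 12 after the peak at index 4

    def test_offset_none_when_speed_stays_high(self):
        v = np.array([0, 20, 50, 80, 60, 40, 30], dtype=float)
        onset, offset = segment_primary(v)
        assert onset == 1 and offset is None


class TestApplyExclusions:
    def test_clean_trial_retained(self, noiseless_trial_pair):
        import copy

        trial = copy.deepcopy(noiseless_trial_pair[0])
        trial = apply_exclusions(trial)
        assert not trial.excluded

    def test_overspeed_excluded(self, noiseless_trial_pair):
        import copy

        trial = copy.deepcopy(noiseless_trial_pair[0])
        traj = trial.trajectory("imitator", "wrist")
        i = int(trial.timeline.imitator_go_tone_s * trial.fs) + 100
        traj.pos[i, 0] += 260.0 / trial.fs * 2  # > 250 cm/s for one sample
        trial = apply_exclusions(trial)
        assert trial.excluded and trial.exclusion_reason == "overspeed"

    def test_premature_start_excluded(self, noiseless_trial_pair):
        import copy

        trial = copy.deepcopy(noiseless_trial_pair[0])
        traj = trial.trajectory("imitator", "index")
        fs = trial.fs
        go = trial.timeline.imitator_go_tone_s
        # 50 cm/s drift starting 200 ms before the go tone
        i0, i1 = int((go - 0.2) * fs), int(go * fs)
        ramp = 50.0 / fs * np.arange(i1 - i0)
        traj.pos[i0:i1, 2] += ramp
        traj.pos[i1:, 2] += ramp[-1]
        trial = apply_exclusions(trial)
        assert trial.excluded and trial.exclusion_reason == "premature_start"

    def test_first_rule_wins(self, noiseless_trial_pair):
        """premature_start fires before overspeed when both apply."""
        import copy

        trial = copy.deepcopy(noiseless_trial_pair[0])
        fs = trial.fs
        go = trial.timeline.imitator_go_tone_s
        traj = trial.trajectory("imitator", "index")
        i0, i1 = int((go - 0.2) * fs), int(go * fs)
        ramp = 50.0 / fs * np.arange(i1 - i0)
        traj.pos[i0:i1, 2] += ramp
        traj.pos[i1:, 2] += ramp[-1]
        wrist = trial.trajectory("imitator", "wrist")
        wrist.pos[i1 + 100, 0] += 300.0 / fs * 2
        trial = apply_exclusions(trial)
        assert trial.exclusion_reason == "premature_start"


class TestResampleNormalize:
    def test_constant_segment_all_ones(self):
        curve = resample_normalize(np.full(57, 33.0))
        assert curve.values.shape == (120,)
        assert np.allclose(curve.values, 1.0)

    def test_identity_on_120_samples(self):
        rng = np.random.default_rng(0)
        seg = rng.uniform(1, 50, 120)
        curve = resample_normalize(seg)
        assert np.allclose(curve.values, seg / seg.max(), atol=1e-12)

    def test_half_sine_peak_at_middle(self):
        for n in (37, 120, 301):
            seg = 40 * np.sin(np.linspace(0, np.pi, n))
            curve = resample_normalize(seg)
            assert abs(int(np.argmax(curve.values)) - 59) <= 1
            assert curve.values.max() == 1.0

    def test_idempotent_on_own_output(self):
        seg = 40 * np.sin(np.linspace(0, np.pi, 77)) + 5
        once = resample_normalize(seg)
        twice = resample_normalize(once.values)
        assert np.allclose(once.values, twice.values, atol=1e-9)

    def test_zero_segment_degenerate(self):
        with pytest.raises(DegenerateCurveError):
            resample_normalize(np.zeros(50))


class TestPeakParams:
    def test_minimum_jerk_peak_velocity(self):
        fs, D, T = 240.0, 48.0, 1.0
        t = np.arange(int(T * fs) + 1) / fs
        pk = peak_params(minimum_jerk_speed(t, D, T), fs)
        assert pk.pv == pytest.approx(1.875 * D / T, rel=0.005)

    def test_ramp_to_plateau(self):
        v = np.concatenate([np.linspace(0, 60, 100), np.full(100, 60.0)])
        pk = peak_params(v, 240.0)
        assert pk.pv == 60.0
        assert pk.pd == pytest.approx(0.0, abs=1e-9)

    def test_symmetric_bell_pa_equals_pd(self):
        v = 80 * np.sin(np.linspace(0, np.pi, 241)) ** 2
        pk = peak_params(v, 240.0)
        assert pk.pa == pytest.approx(-pk.pd, rel=1e-6)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_scan(self, seed):
        """PV/PA/PD equal an explicit scan of the discrete derivative."""
        rng = np.random.default_rng(seed)
        v = np.abs(np.cumsum(rng.normal(0, 1, 200)))
        fs = 240.0
        pk = peak_params(v, fs)
        acc = np.gradient(v) * fs
        assert pk.pv == v.max()
        assert pk.pa == acc.max()
        assert pk.pd == acc.min()
        assert pk.pa >= 0 >= pk.pd


class TestMeanDigitParams:
    @staticmethod
    def _records():
        rows = []
        for p in (1, 2):
            for trial in range(2):
                for tr in Tracker:
                    rows.append(
                        {
                            "participant": p,
                            "site": "PMv",
                            "stim_time": "imitation",
                            "trial": trial,
                            "tracker": tr.value,
                            "excluded": False,
                            "pv": 50.0,
                            "pd": -300.0,
                        }
                    )
        return pd.DataFrame(rows)

    def test_identical_digits_give_that_value(self):
        out = mean_digit_params(self._records(), "pv")
        assert np.allclose(out["pv"], 50.0)

    def test_excluded_trials_dropped(self):
        df = self._records()
        df.loc[(df.participant == 1) & (df.trial == 1), "excluded"] = True
        df.loc[(df.participant == 1) & (df.trial == 1), "pv"] = 1000.0
        out = mean_digit_params(df, "pv")
        assert np.allclose(out["pv"], 50.0)

    def test_arm_trackers_not_counted(self):
        df = self._records()
        df.loc[df.tracker.isin(["shoulder", "elbow", "wrist"]), "pv"] = 999.0
        out = mean_digit_params(df, "pv")
        assert np.allclose(out["pv"], 50.0)

    def test_invalid_parameter_name(self):
        with pytest.raises(ValidationError):
            mean_digit_params(self._records(), "pa")
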