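"""Preprocessing oracles: spike detection z-scores, interpolation repair,
locally weighted smoothing, spline excision and zero-phase filtering."""

import numpy as np
import pytest
from scipy import signal

from imikin.datatypes import Person, Tracker, Trajectory, ValidationError
from imikin.preprocess import (
    FilterSpec,
    InterpolationReport,
    detect_spikes,
    excise_tms_artifacts,
    lowess_outliers,
    lowpass,
    repair_spikes,
)
from imikin._utils import samples_to_ms


def _traj(pos_x: np.ndarray, fs: float = 240.0) -> Trajectory:
    pos = np.zeros((pos_x.size, 3))
    pos[:, 0] = pos_x
    return Trajectory(tracker=Tracker.WRIST, person=Person.IMITATOR, fs=fs, pos=pos)


class TestDetectSpikes:
    def test_constant_series_empty(self):
        assert detect_spikes(_traj(np.full(100, 3.0))) == set()

    def test_smooth_sinusoid_empty(self):
        """Standardized second difference of a sinusoid peaks at sqrt(2) < 3."""
        x = 5 * np.sin(2 * np.pi * 2 * np.arange(500) / 240)
        d2 = np.diff(x, n=2)
        assert np.abs((d2 - d2.mean()) / d2.std()).max() < 3
        assert detect_spikes(_traj(x)) == set()

    def test_displaced_sample_flagged(self):
        """Brute-force z-score of the second difference flags the spike."""
        x = 0.1 * np.arange(200)
        x[80] += 10.0
        d2 = np.diff(x, n=2)
        z = np.abs((d2 - d2.mean()) / d2.std())
        expected = set((np.flatnonzero(z > 3) + 1).tolist())
        assert 80 in expected  # the oracle itself flags the displaced sample
        assert detect_spikes(_traj(x)) == expected

    def test_too_short_rejected(self):
        with pytest.raises(ValidationError):
            detect_spikes(_traj(np.arange(4.0)))

    def test_sensitivity_and_false_positives_on_generator(self, spiked_trial_pair):
        """Injected 5 cm spikes (250x the 0.02 cm noise) are all caught;
        false positives stay under 1% of clean samples."""
        trial, truth = spiked_trial_pair
        hits = misses = fp = clean = 0
        for key, traj in trial.trajectories.items():
            detected = detect_spikes(traj)
            spikes = set(truth.spike_indices[key].tolist())
            for s in spikes:
                if detected & {s - 1, s, s + 1}:
                    hits += 1
                else:
                    misses += 1
            near_truth = set()
            for s in spikes:
                near_truth.update({s - 1, s, s + 1})
            fp += len(detected - near_truth)
            clean += traj.n_samples - len(near_truth)
        assert hits / (hits + misses) >= 0.95
        assert fp / clean <= 0.01


class TestRepairSpikes:
    def test_linear_path_repaired_exactly(self):
        x = 0.5 * np.arange(60)
        spiked = x.copy()
        spiked[30] += 8.0
        repaired = repair_spikes(_traj(spiked), {30})
        assert np.allclose(repaired.pos[:, 0], x, atol=1e-12)

    def test_boundary_window_clamped(self):
        x = np.ones(30)
        x[2] += 5.0
        repaired = repair_spikes(_traj(x), {2})
        # no left anchor: the window is filled from the right anchor
        assert np.allclose(repaired.pos[:6, 0], 1.0)

    def test_nearby_spikes_merge_into_one_window(self):
        """Two spikes 4 samples apart: the definition applied by hand on a
        20-sample vector gives a single interpolation span [i1-3, i2+3]."""
        x = np.arange(20.0)
        x[8] += 6.0
        x[12] -= 6.0
        repaired = repair_spikes(_traj(x), {8, 12})
        # hand-applied rule: one merged span 5..15, anchors x[4] and x[16]
        expected = x.copy()
        expected[5:16] = np.interp(np.arange(5, 16), [4, 16], [x[4], x[16]])
        assert np.allclose(repaired.pos[:, 0], expected, atol=1e-12)
        # stacking the two windows separately would differ: check merge kept
        # the outside samples untouched
        assert repaired.pos[4, 0] == x[4] and repaired.pos[16, 0] == x[16]


class TestLowessOutliers:
    def test_noiseless_line_empty(self):
        assert lowess_outliers(_traj(0.3 * np.arange(100))) == set()

    def test_large_outlier_flagged(self):
        rng = np.random.default_rng(0)
        x = 0.2 * np.arange(300) + rng.normal(0, 0.01, 300)
        x[150] += 0.2  # 20x the noise s.d.
        flagged = lowess_outliers(_traj(x))
        assert 150 in flagged

    def test_repaired_outlier_not_reflagged(self):
        """After interpolation repair the spike site passes a second
        detection pass; residuals there sit at the noise floor."""
        rng = np.random.default_rng(1)
        x = np.sin(np.arange(300) / 40) + rng.normal(0, 0.005, 300)
        x[100] += 0.3
        traj = _traj(x)
        flagged = lowess_outliers(traj)
        assert 100 in flagged
        cleaned = repair_spikes(traj, flagged)
        assert not (lowess_outliers(cleaned) & flagged)
        assert abs(cleaned.pos[100, 0] - np.sin(100 / 40)) < 0.02


class TestExciseTms:
    def test_cubic_path_reconstructed_exactly(self):
        """Cubic splines reproduce cubic polynomials: excised windows on a
        cubic path come back to within 1e-9."""
        t = np.arange(400) / 240.0
        x = 2.0 + 3.0 * t - 1.5 * t**2 + 0.8 * t**3
        out, report = excise_tms_artifacts(_traj(x), [0.5, 1.0], window_ms=25.0)
        assert np.allclose(out.pos[:, 0], x, atol=1e-9)
        assert report.total_samples > 0

    def test_report_conversions_and_conservation(self):
        report = InterpolationReport(fs=240.0, period_lengths=[53, 10, 10])
        assert report.max_run_samples == 53
        assert report.max_run_ms == 221.0
        assert report.total_samples == sum(report.period_lengths)

    def test_overlapping_windows_merged(self):
        t = np.arange(400) / 240.0
        x = np.sin(t)
        _, report = excise_tms_artifacts(_traj(x), [0.5, 0.52], window_ms=25.0)
        assert len(report.period_lengths) == 1  # one merged run, not two

    def test_excessive_coverage_rejected(self):
        x = np.sin(np.arange(100) / 10)
        with pytest.raises(ValidationError):
            excise_tms_artifacts(_traj(x), list(np.arange(0.02, 0.4, 0.03)), window_ms=200.0)

    def test_onset_outside_trial_rejected(self):
        with pytest.raises(ValidationError):
            excise_tms_artifacts(_traj(np.zeros(100)), [5.0], window_ms=25.0)


class TestLowpass:
    def test_dc_gain_unity(self):
        out = lowpass(_traj(np.full(500, 7.5)))
        assert np.allclose(out.pos[:, 0], 7.5, atol=1e-9)

    @pytest.mark.parametrize("freq", [2.0, 50.0])
    def test_gain_matches_squared_butterworth_magnitude(self, freq):
        """Bidirectional filtering squares the Butterworth magnitude:
        |H|^2 = 1/(1 + w^(2*order)) with the bilinear-prewarped frequency
        ratio w = tan(pi f / fs) / tan(pi fc / fs) (which reduces to f/fc
        well below Nyquist)."""
        fs, fc, order = 240.0, 12.0, 4
        t = np.arange(4800) / fs
        x = np.sin(2 * np.pi * freq * t)
        out = lowpass(_traj(x), FilterSpec(order=order, cutoff_hz=fc))
        core = slice(500, -500)  # ignore filter edge transients
        gain = out.pos[core, 0].std() / x[core].std()
        w = np.tan(np.pi * freq / fs) / np.tan(np.pi * fc / fs)
        expected = 1.0 / (1.0 + w ** (2 * order))
        assert gain == pytest.approx(expected, rel=0.01, abs=1e-7)
        if freq <= fc / 2:  # analog form agrees at low frequency
            analog = 1.0 / (1.0 + (freq / fc) ** (2 * order))
            assert gain == pytest.approx(analog, rel=0.01)

    def test_zero_phase_no_lag(self):
        """Peak cross-correlation between input and output sits at lag 0."""
        fs = 240.0
        t = np.arange(2400) / fs
        x = np.sin(2 * np.pi * 3 * t) + 0.3 * np.sin(2 * np.pi * 7 * t)
        y = lowpass(_traj(x)).pos[:, 0]
        xc = signal.correlate(y - y.mean(), x - x.mean(), mode="full")
        lag = np.argmax(xc) - (x.size - 1)
        assert lag == 0

    def test_too_short_rejected(self):
        with pytest.raises(ValidationError):
            lowpass(_traj(np.zeros(10)))


@pytest.mark.parametrize(
    "samples, decimals, expected",
    [(53, 0, 221.0), (33, 0, 138.0), (28, 0, 117.0), (19, 1, 79.2), (165, 1, 687.5)],
)
def test_samples_to_ms_report_convention(samples, decimals, expected):
    assert samples_to_ms(samples, 240.0, decimals) == expected
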