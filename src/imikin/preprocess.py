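"""Artifact-robust cleaning of raw tracker trajectories.

Stages, in the order a trial is cleaned:

1. single-sample electromagnetic spikes: samples whose per-axis second
   difference lies more than 3 s.d. from its trial mean, repaired by
   linear interpolation across three adjacent samples either side;
2. residual outliers: locally weighted linear smoothing (window of five
   samples, first-degree polynomial) flags samples with large residuals,
   repaired by the same interpolation rule;
3. stimulation-locked artifact windows: excised around each known pulse
   onset and reconstructed by cubic-spline interpolation over the
   flanking data, with a per-trial interpolation report;
4. bidirectional (zero-phase) low-pass fourth-order Butterworth filter,
   cut-off 12 Hz.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal
from scipy.interpolate import CubicSpline
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from ._utils import samples_to_ms
from .datatypes import Trajectory, Trial, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "SpikeParams",
    "SmoothParams",
    "FilterSpec",
    "InterpolationReport",
    "detect_spikes",
    "repair_spikes",
    "lowess_outliers",
    "excise_tms_artifacts",
    "lowpass",
    "clean_trajectory",
    "clean_trial",
]


@dataclass(frozen=True)
class SpikeParams:
    """Spike detection/repair: z threshold on the double-differentiated
    series and the half-width of the repair window."""

    z_threshold: float = 3.0
    repair_halfwidth: int = 3

    def __post_init__(self) -> None:
        if self.z_threshold <= 0:
            raise ValidationError("z_threshold must be positive")
        if self.repair_halfwidth < 1:
            raise ValidationError("repair_halfwidth must be >= 1")


@dataclass(frozen=True)
class SmoothParams:
    """Locally weighted linear smoothing used for residual-outlier detection."""

    window: int = 5
    degree: int = 1
    residual_z_threshold: float = 3.0

    def __post_init__(self) -> None:
        if self.window < 3 or self.window % 2 == 0:
            raise ValidationError("window must be odd and >= 3")
        if self.degree != 1:
            raise ValidationError("only first-degree local fits are supported")


@dataclass(frozen=True)
class FilterSpec:
    """Zero-phase Butterworth low-pass design."""

    order: int = 4
    cutoff_hz: float = 12.0

    def validate(self, fs: float) -> None:
        if not 0 < self.cutoff_hz < fs / 2:
            raise ValidationError(
                f"cutoff {self.cutoff_hz} Hz must lie in (0, fs/2) for fs={fs}"
            )


@dataclass
class InterpolationReport:
    """Bookkeeping of spline-interpolated stimulation-artifact windows.

    ``period_lengths`` holds one entry per excised run (in samples);
    their sum equals ``total_samples``.  Millisecond values follow the
    printed-report convention: integer ms for runs, 0.1 ms for means,
    rounded half away from zero.
    """

    fs: float
    period_lengths: list = field(default_factory=list)

    @property
    def total_samples(self) -> int:
        return int(sum(self.period_lengths))

    @property
    def max_run_samples(self) -> int:
        return int(max(self.period_lengths)) if self.period_lengths else 0

    @property
    def max_run_ms(self) -> float:
        return samples_to_ms(self.max_run_samples, self.fs, 0)

    @property
    def mean_run_ms(self) -> float:
        if not self.period_lengths:
            return 0.0
        return samples_to_ms(float(np.mean(self.period_lengths)), self.fs, 1)

    @property
    def total_ms(self) -> float:
        return samples_to_ms(self.total_samples, self.fs, 1)


def detect_spikes(traj: Trajectory, params: SpikeParams = SpikeParams()) -> set[int]:
    """Indices whose second difference deviates > ``z_threshold`` s.d. from its mean.

    The second difference is taken per position axis and standardized by
    that trial-and-axis mean/s.d.; flagged indices are the union over the
    three axes (a second-difference value at ``i`` is attributed to the
    centre sample ``i + 1``).
    """
    n = traj.n_samples
    if n < 5:
        raise ValidationError(f"need >= 5 samples to detect spikes, got {n}")
    flagged: set[int] = set()
    for ax in range(3):
        d2 = np.diff(traj.pos[:, ax], n=2)
        sd = d2.std()
        if sd == 0:
            continue
        z = (d2 - d2.mean()) / sd
        flagged.update((np.flatnonzero(np.abs(z) > params.z_threshold) + 1).tolist())
    return flagged


def _merge_windows(indices, halfwidth: int, n: int) -> list[tuple[int, int]]:
    """Merge per-index repair windows [i-hw, i+hw] into disjoint spans."""
    if not indices:
        return []
    spans = []
    for i in sorted(indices):
        a, b = max(i - halfwidth, 0), min(i + halfwidth, n - 1)
        if spans and a <= spans[-1][1] + 1:
            spans[-1] = (spans[-1][0], max(spans[-1][1], b))
        else:
            spans.append((a, b))
    return spans


def _linear_repair(x: np.ndarray, spans: list[tuple[int, int]]) -> np.ndarray:
    """Replace each span by linear interpolation between its flanking anchors.

    Boundary spans (no anchor on one side) are filled from the nearest
    valid anchor on the other side.
    """
    y = x.copy()
    n = len(x)
    for a, b in spans:
        left = a - 1
        right = b + 1
        if left < 0 and right >= n:
            continue  # nothing valid to anchor on
        if left < 0:
            y[a : b + 1] = x[right]
        elif right >= n:
            y[a : b + 1] = x[left]
        else:
            y[a : b + 1] = np.interp(np.arange(a, b + 1), [left, right], [x[left], x[right]])
    return y


def repair_spikes(
    traj: Trajectory, indices, params: SpikeParams = SpikeParams()
) -> Trajectory:
    """Repair flagged samples by linear interpolation across the repair window.

    For a flagged index ``i`` the samples ``i-3 ... i+3`` are replaced by
    linear interpolation between samples ``i-4`` and ``i+4``; overlapping
    windows are merged (never stacked) and boundary windows are clamped
    to the nearest valid anchors.
    """
    spans = _merge_windows(set(indices), params.repair_halfwidth, traj.n_samples)
    out = traj.copy()
    for ax in range(3):
        out.pos[:, ax] = _linear_repair(out.pos[:, ax], spans)
    return out


def lowess_outliers(
    traj: Trajectory, params: SmoothParams = SmoothParams()
) -> set[int]:
    """Residual outliers of a locally weighted (tricube) linear smooth.

    A moving window of ``params.window`` samples fits a first-degree
    weighted polynomial per axis; samples whose residual exceeds
    ``residual_z_threshold`` s.d. of all residuals on that axis are
    flagged (union over axes).
    """
    n = traj.n_samples
    if n < params.window:
        raise ValidationError(f"need >= {params.window} samples, got {n}")
    t = np.arange(n, dtype=float)
    frac = min(params.window / n, 1.0)
    flagged: set[int] = set()
    for ax in range(3):
        smoothed = _sm_lowess(
            traj.pos[:, ax], t, frac=frac, it=0, delta=0.0, return_sorted=False
        )
        resid = traj.pos[:, ax] - smoothed
        sd = resid.std()
        # numerically-zero residuals (noise-free data) are not outliers
        scale = max(np.ptp(traj.pos[:, ax]), 1.0)
        if sd <= 1e-9 * scale:
            continue
        z = (resid - resid.mean()) / sd
        flagged.update(np.flatnonzero(np.abs(z) > params.residual_z_threshold).tolist())
    return flagged


def excise_tms_artifacts(
    traj: Trajectory,
    onsets_s,
    window_ms: float = 25.0,
    report: InterpolationReport | None = None,
) -> tuple[Trajectory, InterpolationReport]:
    """Excise ``onset +/- window_ms`` around each pulse and spline-interpolate.

    Overlapping windows are merged before interpolation; removed samples
    are reconstructed by a cubic spline fitted to the remaining data
    (exact on cubic-polynomial paths).  The report accumulates per-run
    lengths, their total and the maximum run, in samples and ms.
    """
    if window_ms <= 0:
        raise ValidationError("window_ms must be positive")
    n = traj.n_samples
    fs = traj.fs
    dur = traj.duration_s
    for onset in onsets_s:
        if not 0.0 <= onset <= dur:
            raise ValidationError(f"artifact onset {onset} s outside trial [0, {dur:.3f}]")
    mask = np.zeros(n, dtype=bool)
    half = window_ms / 1000.0
    for onset in onsets_s:
        j0 = max(int(np.ceil((onset - half) * fs)), 0)
        j1 = min(int(np.floor((onset + half) * fs)), n - 1)
        mask[j0 : j1 + 1] = True
    frac = mask.mean()
    if frac > 0.9:
        raise ValidationError(
            f"artifact windows cover {frac:.0%} of the trial; nothing left to interpolate from"
        )
    if frac > 0.5:
        logger.warning("artifact windows cover %.0f%% of the trial", 100 * frac)

    if report is None:
        report = InterpolationReport(fs=fs)
    out = traj.copy()
    if mask.any():
        keep = ~mask
        idx = np.arange(n, dtype=float)
        for ax in range(3):
            spline = CubicSpline(idx[keep], traj.pos[keep, ax])
            out.pos[mask, ax] = spline(idx[mask])
        # record merged runs
        edges = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
        for a, b in zip(edges[::2], edges[1::2]):
            report.period_lengths.append(int(b - a))
    return out, report


def lowpass(traj: Trajectory, spec: FilterSpec = FilterSpec()) -> Trajectory:
    """Zero-phase Butterworth low-pass (forward + reverse pass of the design).

    Two passes square the magnitude response, so the effective gain at
    frequency ``f`` is ``1 / (1 + (f / cutoff)^(2 * order))`` and the DC
    gain is exactly 1 with no phase shift.
    """
    spec.validate(traj.fs)
    b, a = signal.butter(spec.order, spec.cutoff_hz / (traj.fs / 2.0))
    padlen = 3 * max(len(a), len(b))
    if traj.n_samples <= padlen:
        raise ValidationError(
            f"trajectory of {traj.n_samples} samples too short for filtfilt (need > {padlen})"
        )
    out = traj.copy()
    out.pos = signal.filtfilt(b, a, traj.pos, axis=0)
    return out


def clean_trajectory(
    traj: Trajectory,
    artifact_onsets_s=(),
    spike_params: SpikeParams = SpikeParams(),
    smooth_params: SmoothParams = SmoothParams(),
    filter_spec: FilterSpec = FilterSpec(),
    tms_window_ms: float = 25.0,
) -> tuple[Trajectory, InterpolationReport]:
    """Full cleaning chain for one trajectory; returns it plus the report."""
    spikes = detect_spikes(traj, spike_params)
    traj = repair_spikes(traj, spikes, spike_params)
    outliers = lowess_outliers(traj, smooth_params)
    traj = repair_spikes(traj, outliers, spike_params)
    traj, report = excise_tms_artifacts(traj, artifact_onsets_s, tms_window_ms)
    traj = lowpass(traj, filter_spec)
    return traj, report


def clean_trial(
    trial: Trial,
    spike_params: SpikeParams = SpikeParams(),
    smooth_params: SmoothParams = SmoothParams(),
    filter_spec: FilterSpec = FilterSpec(),
    tms_window_ms: float = 25.0,
) -> tuple[Trial, dict]:
    """Clean all 16 trajectories of a trial; returns (trial, reports).

    Reports are keyed by ``(person, tracker)``.
    """
    cleaned = {}
    reports = {}
    for key, traj in trial.trajectories.items():
        cleaned[key], reports[key] = clean_trajectory(
            traj,
            artifact_onsets_s=trial.artifact_onsets_s,
            spike_params=spike_params,
            smooth_params=smooth_params,
            filter_spec=filter_spec,
            tms_window_ms=tms_window_ms,
        )
    new_trial = replace(trial, trajectories=cleaned)
    return new_trial, reports
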