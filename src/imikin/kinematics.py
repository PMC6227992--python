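"""Speed computation, primary-movement segmentation, exclusions and peaks.

The primary movement runs from movement onset to gesture completion,
delimited by a 12 cm/s speed threshold: onset is the first sample at or
above threshold, completion the first sample after the global speed peak
that falls back below it.  Trials are excluded when the participant
starts before the go tone, fails to finish in time, or any tracker
exceeds 250 cm/s.  Analysed curves are resampled to 120 samples and
amplitude-normalized; peak parameters (PV, PA, PD) are taken on the
original, non-resampled segments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import (
    DIGIT_TRACKERS,
    DegenerateCurveError,
    NoMovementError,
    NormalizedCurve,
    Person,
    Tracker,
    Trajectory,
    Trial,
    ValidationError,
)

__all__ = [
    "SegmentationParams",
    "PeakParams",
    "speed3d",
    "speed_from_positions",
    "segment_primary",
    "apply_exclusions",
    "resample_normalize",
    "resample_speed",
    "peak_params",
    "mean_digit_params",
    "EXCLUSION_REASONS",
]

#: fixed order in which exclusion rules fire (first hit is the reason)
EXCLUSION_REASONS = ("premature_start", "late_finish", "overspeed")


@dataclass(frozen=True)
class SegmentationParams:
    movement_threshold_cm_s: float = 12.0
    max_speed_cm_s: float = 250.0
    finish_tolerance_ms: float = 200.0
    max_movement_time_ms: float = 1800.0

    def __post_init__(self) -> None:
        if not 0 < self.movement_threshold_cm_s < self.max_speed_cm_s:
            raise ValidationError("require 0 < movement threshold < max speed")


@dataclass(frozen=True)
class PeakParams:
    """Peak kinematic parameters of a segmented movement.

    PV is the peak speed (cm/s), PA the maximum and PD the minimum of the
    speed derivative (cm/s^2); PD is reported negative.
    """

    pv: float
    pa: float
    pd: float


def speed_from_positions(pos: np.ndarray, fs: float) -> np.ndarray:
    """Euclidean norm of the position derivative (central differences).

    Interior samples use second-order central differences, the two edge
    samples one-sided differences (``np.gradient`` convention).
    """
    pos = np.asarray(pos, dtype=float)
    if pos.shape[0] < 3:
        raise ValidationError("need >= 3 samples to differentiate")
    vel = np.gradient(pos, axis=0) * fs
    return np.linalg.norm(vel, axis=1)


def speed3d(traj: Trajectory) -> np.ndarray:
    """Per-sample 3-D speed (cm/s) of a trajectory."""
    return speed_from_positions(traj.pos, traj.fs)


def segment_primary(
    speed: np.ndarray,
    params: SegmentationParams = SegmentationParams(),
) -> tuple[int, int | None]:
    """(onset, offset) indices of the primary movement within ``speed``.

    Onset is the first index with ``speed >= threshold``; offset the first
    index after the global peak with ``speed < threshold`` (``None`` if
    the speed never falls back below threshold -- the movement did not
    complete within the window).

    Raises
    ------
    NoMovementError
        if the speed never reaches the threshold.
    """
    speed = np.asarray(speed, dtype=float)
    thr = params.movement_threshold_cm_s
    above = speed >= thr
    if not above.any():
        raise NoMovementError("speed never reaches the movement threshold")
    onset = int(np.argmax(above))
    peak = int(np.argmax(speed))
    below_after = np.flatnonzero(speed[peak + 1 :] < thr)
    offset = int(peak + 1 + below_after[0]) if below_after.size else None
    return onset, offset


def apply_exclusions(
    trial: Trial,
    params: SegmentationParams = SegmentationParams(),
    person: Person = Person.IMITATOR,
) -> Trial:
    """Flag a trial against the exclusion rules, in fixed order.

    * ``premature_start``: any tracker's movement onset (threshold
      crossing within the response window) precedes the go tone;
    * ``late_finish``: the wrist movement fails to complete by the return
      tone plus the finish tolerance, or exceeds the maximum movement
      time;
    * ``overspeed``: any tracker exceeds ``max_speed_cm_s`` anywhere in
      the trial.

    The first rule that fires sets the (single) exclusion reason.
    """
    fs = trial.fs
    if person is Person.IMITATOR:
        go, ret = trial.timeline.imitator_go_tone_s, trial.timeline.imitator_hold_end_s
    else:
        go, ret = trial.timeline.actor_go_tone_s, trial.timeline.actor_hold_end_s
    tol_s = params.finish_tolerance_ms / 1000.0
    i_go = int(round(go * fs))
    # search window starts half a second before the go tone to catch jumps
    i_win0 = max(int(round((go - 0.5) * fs)), 0)
    i_end = min(int(round((ret + tol_s) * fs)), trial.n_samples - 1)

    reason = None
    speeds = {
        tr: speed3d(trial.trajectory(person, tr)) for tr in Tracker
    }
    # premature_start
    for tr in Tracker:
        window = speeds[tr][i_win0:i_end]
        above = window >= params.movement_threshold_cm_s
        if above.any() and i_win0 + int(np.argmax(above)) < i_go:
            reason = "premature_start"
            break
    # late_finish (wrist defines arm transport)
    if reason is None:
        sp = speeds[Tracker.WRIST][i_go : i_end + 1]
        try:
            onset, offset = segment_primary(sp, params)
        except NoMovementError:
            onset, offset = None, None
        if offset is None:
            reason = "late_finish"
        elif (offset - (onset or 0)) / fs * 1000.0 > params.max_movement_time_ms:
            reason = "late_finish"
    # overspeed
    if reason is None:
        for tr in Tracker:
            if np.any(speeds[tr] > params.max_speed_cm_s):
                reason = "overspeed"
                break
    if reason is not None:
        trial.exclude(reason)
    return trial


def resample_speed(segment: np.ndarray, n: int = NormalizedCurve.N_SAMPLES) -> np.ndarray:
    """Linear-interpolation resampling of a speed segment to ``n`` points."""
    segment = np.asarray(segment, dtype=float)
    if segment.size < 2:
        raise ValidationError("segment must contain at least 2 samples")
    x_old = np.linspace(0.0, 1.0, segment.size)
    return np.interp(np.linspace(0.0, 1.0, n), x_old, segment)


def resample_normalize(segment: np.ndarray, source: tuple = ()) -> NormalizedCurve:
    """Resample a speed segment to 120 points, then divide by its maximum."""
    resampled = resample_speed(segment)
    peak = resampled.max()
    if peak <= 0:
        raise DegenerateCurveError("segment maximum is zero; cannot normalize")
    return NormalizedCurve(values=resampled / peak, source=source)


def peak_params(segment: np.ndarray, fs: float) -> PeakParams:
    """PV, PA, PD of a (non-resampled) speed segment.

    The acceleration is the derivative of speed (central differences
    interior, one-sided edges); PA is its maximum, PD its minimum.
    """
    segment = np.asarray(segment, dtype=float)
    if segment.size < 3:
        raise ValidationError("need >= 3 samples for peak parameters")
    accel = np.gradient(segment) * fs
    return PeakParams(pv=float(segment.max()), pa=float(accel.max()), pd=float(accel.min()))


def mean_digit_params(records: pd.DataFrame, which: str = "pv") -> pd.DataFrame:
    """Participant x condition means of a digit-averaged peak parameter.

    ``records`` is a long table with one row per (trial, tracker) holding
    at least ``participant, site, stim_time, tracker, excluded`` and the
    requested parameter column (``pv`` or ``pd``).  Excluded trials are
    dropped; the five digit trackers are averaged within each trial, then
    trials are averaged within each (participant, site, stim_time) cell.
    """
    if which not in {"pv", "pd"}:
        raise ValidationError("which must be 'pv' or 'pd'")
    digits = {tr.value for tr in DIGIT_TRACKERS}
    kept = records[
        (~records["excluded"].astype(bool)) & records["tracker"].isin(digits)
    ]
    per_trial = (
        kept.groupby(["participant", "site", "stim_time", "trial"], observed=True)[which]
        .mean()
        .reset_index()
    )
    return (
        per_trial.groupby(["participant", "site", "stim_time"], observed=True)[which]
        .mean()
        .reset_index()
    )
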