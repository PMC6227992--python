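"""Finger-thumb opposition task: touch detection, ITI stats, epoch speeds.

The task is 15 s of repetitively touching the thumb to each fingertip
back-and-forth across the hand (index, middle, ring, little, ring,
middle, ...), with a 3 Hz stimulation train during the middle 5 s.
Performance measures are computed per epoch (5 s pre-stimulation, 5 s
stimulation, 5 s post-stimulation): mean finger speed (average over the
four fingertip trackers), thumb speed, and the inter-touch interval (ITI)
mean and s.d. pooled across digits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .datatypes import Tracker, Trajectory, ValidationError
from .kinematics import speed3d

logger = logging.getLogger(__name__)

__all__ = ["EpochSpec", "TouchEvent", "OppositionResult", "detect_touches", "iti_stats", "epoch_speeds", "analyze_opposition"]

EPOCH_NAMES = ("pre", "stim", "post")


@dataclass(frozen=True)
class EpochSpec:
    """Half-open epochs [0,5), [5,10), [10,15] s and the pulse schedule.

    The stimulation train delivers ``stim_pulses`` pulses at
    ``stim_rate_hz`` from ``boundaries[1]``: 3 Hz from 5.00 s gives 15
    pulses, the last at 9.67 s.
    """

    boundaries: tuple = (0.0, 5.0, 10.0, 15.0)
    stim_rate_hz: float = 3.0
    stim_pulses: int = 15

    def __post_init__(self) -> None:
        if list(self.boundaries) != sorted(self.boundaries) or len(self.boundaries) != 4:
            raise ValidationError("boundaries must be 4 increasing times")

    def epoch_of(self, t: float) -> str | None:
        """Epoch containing time ``t`` (half-open except the last edge)."""
        b = self.boundaries
        if b[0] <= t < b[1]:
            return "pre"
        if b[1] <= t < b[2]:
            return "stim"
        if b[2] <= t <= b[3]:
            return "post"
        return None

    def pulse_times(self) -> np.ndarray:
        return self.boundaries[1] + np.arange(self.stim_pulses) / self.stim_rate_hz


@dataclass(frozen=True)
class TouchEvent:
    time_s: float
    digit: Tracker
    distance_cm: float


@dataclass
class OppositionResult:
    """Per-epoch opposition-task measures (Table-1 measure set)."""

    finger_speed_cm_s: dict
    thumb_speed_cm_s: dict
    iti_ms: dict
    iti_sd_ms: dict
    touches: list = field(default_factory=list)

    @property
    def touch_times_s(self) -> np.ndarray:
        return np.array([ev.time_s for ev in self.touches])


def detect_touches(
    thumb: Trajectory,
    fingers: dict,
    contact_mm: float = 5.0,
    min_gap_ms: float = 100.0,
) -> list[TouchEvent]:
    """Thumb-fingertip touches: local distance minima below the contact threshold.

    For each fingertip the thumb-fingertip distance series is scanned for
    local minima below ``contact_mm``; events across fingers are pooled
    in time order and a refractory gap of ``min_gap_ms`` is enforced on
    the pooled stream (the closer contact wins).  Each event is labelled
    with its finger.
    """
    fs = thumb.fs
    contact_cm = contact_mm / 10.0
    gap = int(round(min_gap_ms / 1000.0 * fs))
    candidates: list[TouchEvent] = []
    for tracker, finger in fingers.items():
        dist = np.linalg.norm(thumb.pos - finger.pos, axis=1)
        # prominence keeps noise wiggles on the approach slope from
        # registering as contacts; a real touch rises back to the
        # inter-finger spacing, far above the contact threshold
        peaks, _ = find_peaks(
            -dist, height=-contact_cm, distance=max(gap, 1), prominence=contact_cm
        )
        for i in peaks:
            candidates.append(
                TouchEvent(time_s=i / fs, digit=Tracker(tracker), distance_cm=float(dist[i]))
            )
    if not candidates:
        logger.warning("no finger ever came within %.1f mm of the thumb", contact_mm)
        return []
    candidates.sort(key=lambda ev: ev.time_s)
    events: list[TouchEvent] = []
    for ev in candidates:
        if events and (ev.time_s - events[-1].time_s) * fs < gap:
            if ev.distance_cm < events[-1].distance_cm:
                events[-1] = ev
        else:
            events.append(ev)
    return events


def iti_stats(
    touches: list, epochs: EpochSpec = EpochSpec()
) -> tuple[dict, dict]:
    """Per-epoch inter-touch-interval mean and sample s.d. (ms).

    Intervals between consecutive touches (pooled across digits) are
    assigned to the epoch containing the *later* touch.  An epoch needs
    at least one interval for its mean and two for its s.d. (n - 1
    denominator); otherwise the value is NaN and logged.
    """
    times = np.array([ev.time_s for ev in touches])
    if np.any(np.diff(times) <= 0):
        raise ValidationError("touch times must be strictly increasing")
    by_epoch: dict[str, list] = {name: [] for name in EPOCH_NAMES}
    for earlier, later in zip(times, times[1:]):
        epoch = epochs.epoch_of(later)
        if epoch is not None:
            by_epoch[epoch].append((later - earlier) * 1000.0)
    mean_ms, sd_ms = {}, {}
    for name, intervals in by_epoch.items():
        if len(intervals) >= 1:
            mean_ms[name] = float(np.mean(intervals))
        else:
            mean_ms[name] = float("nan")
            logger.info("epoch %s has no intervals; ITI mean missing", name)
        if len(intervals) >= 2:
            sd_ms[name] = float(np.std(intervals, ddof=1))
        else:
            sd_ms[name] = float("nan")
    return mean_ms, sd_ms


def epoch_speeds(
    thumb: Trajectory, fingers: dict, epochs: EpochSpec = EpochSpec()
) -> tuple[dict, dict]:
    """Per-epoch time-averaged 3-D speeds: fingers (mean of 4) and thumb.

    Epochs are half-open, so a sample at exactly 5.000 s counts toward
    the stimulation epoch.
    """
    fs = thumb.fs
    t = thumb.t
    thumb_speed = speed3d(thumb)
    finger_speed = np.mean(
        [speed3d(fingers[tr]) for tr in fingers], axis=0
    )
    b = epochs.boundaries
    masks = {
        "pre": (t >= b[0]) & (t < b[1]),
        "stim": (t >= b[1]) & (t < b[2]),
        "post": (t >= b[2]) & (t <= b[3]),
    }
    finger_mean = {k: float(finger_speed[m].mean()) for k, m in masks.items()}
    thumb_mean = {k: float(thumb_speed[m].mean()) for k, m in masks.items()}
    return finger_mean, thumb_mean


def analyze_opposition(
    thumb: Trajectory,
    fingers: dict,
    epochs: EpochSpec = EpochSpec(),
    contact_mm: float = 5.0,
    min_gap_ms: float = 100.0,
) -> OppositionResult:
    """Full opposition-task analysis of one recording."""
    touches = detect_touches(thumb, fingers, contact_mm=contact_mm, min_gap_ms=min_gap_ms)
    mean_ms, sd_ms = iti_stats(touches, epochs) if touches else (
        {k: float("nan") for k in EPOCH_NAMES},
        {k: float("nan") for k in EPOCH_NAMES},
    )
    finger_mean, thumb_mean = epoch_speeds(thumb, fingers, epochs)
    return OppositionResult(
        finger_speed_cm_s=finger_mean,
        thumb_speed_cm_s=thumb_mean,
        iti_ms=mean_ms,
        iti_sd_ms=sd_ms,
        touches=touches,
    )
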