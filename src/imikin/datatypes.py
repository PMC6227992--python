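"""Shared data types for two-person motion-tracking trials.

The recording model is a Polhemus-style electromagnetic tracker array:
eight trackers per person (shoulder, elbow, wrist, thumb and the four
fingertips), six degrees of freedom each (x, y, z position in cm plus
azimuth, elevation, roll in degrees), sampled at 240 Hz.  Orientation
angles are carried and round-tripped but no analysis consumes them.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Tracker",
    "Person",
    "Site",
    "StimTime",
    "Meaning",
    "Effector",
    "StimCondition",
    "DIGIT_TRACKERS",
    "FINGERTIP_TRACKERS",
    "Condition",
    "Trajectory",
    "TrialTimeline",
    "Trial",
    "ExperimentDesign",
    "NormalizedCurve",
    "ValidationError",
    "SchemaError",
    "FormatError",
    "NoMovementError",
    "DegenerateCurveError",
    "UndefinedCorrelationError",
    "MissingCellError",
]


class ValidationError(ValueError):
    """An object violates one of its declared invariants."""


class SchemaError(ValidationError):
    """A file does not conform to the on-disk schema."""


class FormatError(ValidationError):
    """A file is structurally malformed (e.g. non-monotone time column)."""


class NoMovementError(ValidationError):
    """Speed never reaches the movement threshold within the window."""


class DegenerateCurveError(ValidationError):
    """A speed segment cannot be amplitude-normalized (zero maximum)."""


class UndefinedCorrelationError(ValidationError):
    """Pearson correlation is undefined (zero variance in a curve)."""


class MissingCellError(ValidationError):
    """A participant x condition cell required by a balanced design is empty."""


class Tracker(str, enum.Enum):
    SHOULDER = "shoulder"
    ELBOW = "elbow"
    WRIST = "wrist"
    THUMB = "thumb"
    INDEX = "index"
    MIDDLE = "middle"
    RING = "ring"
    LITTLE = "little"


#: the five digit trackers averaged for "mean digit" kinematic parameters
DIGIT_TRACKERS = (
    Tracker.THUMB,
    Tracker.INDEX,
    Tracker.MIDDLE,
    Tracker.RING,
    Tracker.LITTLE,
)

#: the four fingertips opposed to the thumb in the opposition task
FINGERTIP_TRACKERS = (Tracker.INDEX, Tracker.MIDDLE, Tracker.RING, Tracker.LITTLE)


class Person(str, enum.Enum):
    ACTOR = "actor"
    IMITATOR = "imitator"


class Site(str, enum.Enum):
    PMV = "PMv"
    PMD = "PMd"
    VERTEX = "vertex"


class StimTime(str, enum.Enum):
    OBSERVATION = "observation"
    IMITATION = "imitation"


class Meaning(str, enum.Enum):
    MEANINGFUL = "meaningful"
    MEANINGLESS = "meaningless"


class Effector(str, enum.Enum):
    HAND = "hand"
    FINGER = "finger"


class StimCondition(str, enum.Enum):
    """When in the trial the stimulation train is delivered."""

    OBSERVATION = "observation"
    IMITATION = "imitation"
    NONE = "none"


@dataclass(frozen=True)
class Condition:
    """Factorial cell of the 3 (site) x 2 (stim time) x 2 (meaning) x 2 (effector) design."""

    site: Site
    stim_time: StimTime
    meaning: Meaning
    effector: Effector

    def __post_init__(self) -> None:
        object.__setattr__(self, "site", Site(self.site))
        object.__setattr__(self, "stim_time", StimTime(self.stim_time))
        object.__setattr__(self, "meaning", Meaning(self.meaning))
        object.__setattr__(self, "effector", Effector(self.effector))

    def as_dict(self) -> dict[str, str]:
        return {
            "site": self.site.value,
            "stim_time": self.stim_time.value,
            "meaning": self.meaning.value,
            "effector": self.effector.value,
        }


@dataclass
class Trajectory:
    """One tracker's 6-d.f. time-series at a fixed sampling rate.

    Parameters
    ----------
    tracker, person
        Which tracker on which person.
    fs
        Sampling rate in Hz (recording standard: 240).
    pos
        ``(n, 3)`` array of x, y, z positions in cm.
    ang
        ``(n, 3)`` array of azimuth, elevation, roll in degrees.  Stored
        for fidelity to the 6-d.f. recording; never analysed.
    """

    tracker: Tracker
    person: Person
    fs: float
    pos: np.ndarray
    ang: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.tracker = Tracker(self.tracker)
        self.person = Person(self.person)
        self.pos = np.asarray(self.pos, dtype=float)
        if self.fs <= 0:
            raise ValidationError(f"sampling rate must be positive, got {self.fs}")
        if self.pos.ndim != 2 or self.pos.shape[1] != 3:
            raise ValidationError(f"pos must be (n, 3), got shape {self.pos.shape}")
        if self.pos.shape[0] == 0:
            raise ValidationError("trajectory must contain at least one sample")
        if self.ang is None:
            self.ang = np.zeros_like(self.pos)
        else:
            self.ang = np.asarray(self.ang, dtype=float)
            if self.ang.shape != self.pos.shape:
                raise ValidationError(
                    f"ang shape {self.ang.shape} does not match pos shape {self.pos.shape}"
                )

    @property
    def n_samples(self) -> int:
        return self.pos.shape[0]

    @property
    def t(self) -> np.ndarray:
        """Sample times in seconds from trial start."""
        return np.arange(self.n_samples) / self.fs

    @property
    def duration_s(self) -> float:
        return (self.n_samples - 1) / self.fs

    def copy(self) -> "Trajectory":
        return Trajectory(
            tracker=self.tracker,
            person=self.person,
            fs=self.fs,
            pos=self.pos.copy(),
            ang=self.ang.copy(),
        )


@dataclass
class TrialTimeline:
    """Event times (s from trial start) of one imitation trial.

    The trial runs: image onset -> actor go tone 1000 ms later -> actor
    holds the gesture until a return tone 2000 ms after that -> imitator
    go tone 1000 ms after the actor's return tone -> imitator holds until
    a return tone 2000 ms later.  Stimulation is a 3 s train at 3 Hz that
    either starts 333 ms after image onset (observation) or 1000 ms
    before the imitator's go tone (imitation).
    """

    image_onset_s: float
    actor_go_tone_s: float
    actor_hold_end_s: float
    imitator_go_tone_s: float
    imitator_hold_end_s: float
    stim_condition: StimCondition = StimCondition.NONE
    stim_onset_s: float | None = None
    stim_rate_hz: float = 3.0
    stim_duration_s: float = 3.0
    inter_train_gap_s: float = 10.0

    def __post_init__(self) -> None:
        self.stim_condition = StimCondition(self.stim_condition)
        order = [
            self.image_onset_s,
            self.actor_go_tone_s,
            self.actor_hold_end_s,
            self.imitator_go_tone_s,
            self.imitator_hold_end_s,
        ]
        if any(b < a for a, b in zip(order, order[1:])):
            raise ValidationError(f"timeline events must be non-decreasing: {order}")

    @classmethod
    def standard(
        cls,
        image_onset_s: float = 0.5,
        stim_condition: StimCondition | str = StimCondition.NONE,
    ) -> "TrialTimeline":
        """Build the canonical trial timeline from the image-onset time."""
        stim_condition = StimCondition(stim_condition)
        actor_go = image_onset_s + 1.0
        actor_hold_end = actor_go + 2.0
        imitator_go = actor_hold_end + 1.0
        imitator_hold_end = imitator_go + 2.0
        if stim_condition is StimCondition.OBSERVATION:
            stim_onset: float | None = image_onset_s + 0.333
        elif stim_condition is StimCondition.IMITATION:
            stim_onset = imitator_go - 1.0
        else:
            stim_onset = None
        return cls(
            image_onset_s=image_onset_s,
            actor_go_tone_s=actor_go,
            actor_hold_end_s=actor_hold_end,
            imitator_go_tone_s=imitator_go,
            imitator_hold_end_s=imitator_hold_end,
            stim_condition=stim_condition,
            stim_onset_s=stim_onset,
        )

    def stim_pulse_times(self) -> np.ndarray:
        """Pulse onsets of the stimulation train (empty when unstimulated).

        A train of ``rate * duration`` pulses starting at ``stim_onset_s``:
        3 s at 3 Hz delivers pulses at 0, 1/3, ..., 8/3 s after onset.
        """
        if self.stim_onset_s is None:
            return np.array([])
        n = int(round(self.stim_rate_hz * self.stim_duration_s))
        return self.stim_onset_s + np.arange(n) / self.stim_rate_hz

    def as_dict(self) -> dict:
        return {
            "image_onset_s": self.image_onset_s,
            "actor_go_tone_s": self.actor_go_tone_s,
            "actor_hold_end_s": self.actor_hold_end_s,
            "imitator_go_tone_s": self.imitator_go_tone_s,
            "imitator_hold_end_s": self.imitator_hold_end_s,
            "stim_condition": self.stim_condition.value,
            "stim_onset_s": self.stim_onset_s,
            "stim_rate_hz": self.stim_rate_hz,
            "stim_duration_s": self.stim_duration_s,
            "inter_train_gap_s": self.inter_train_gap_s,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrialTimeline":
        return cls(**d)


@dataclass
class Trial:
    """All 16 trajectories of one actor-imitator trial plus metadata."""

    trajectories: dict[tuple[Person, Tracker], Trajectory]
    timeline: TrialTimeline
    condition: Condition
    participant_id: int
    session: int = 1
    artifact_onsets_s: list[float] = field(default_factory=list)
    excluded: bool = False
    exclusion_reason: str | None = None

    def __post_init__(self) -> None:
        expected = {(p, tr) for p in Person for tr in Tracker}
        present = set(self.trajectories)
        if present != expected:
            missing = sorted(
                (p.value, tr.value) for (p, tr) in expected - present
            )
            extra = sorted((p.value, tr.value) for (p, tr) in present - expected)
            parts = []
            if missing:
                parts.append(f"missing channels: {missing}")
            if extra:
                parts.append(f"unexpected channels: {extra}")
            raise SchemaError(
                "trial must contain exactly 16 (person, tracker) trajectories; "
                + "; ".join(parts)
            )
        ns = {tr.n_samples for tr in self.trajectories.values()}
        if len(ns) != 1:
            raise ValidationError(f"inconsistent sample counts across trackers: {sorted(ns)}")
        fss = {tr.fs for tr in self.trajectories.values()}
        if len(fss) != 1:
            raise ValidationError(f"inconsistent sampling rates across trackers: {sorted(fss)}")
        dur = self.duration_s
        for onset in self.artifact_onsets_s:
            if not 0.0 <= onset <= dur:
                raise ValidationError(
                    f"artifact onset {onset} s outside trial bounds [0, {dur:.3f}]"
                )

    @property
    def fs(self) -> float:
        return next(iter(self.trajectories.values())).fs

    @property
    def n_samples(self) -> int:
        return next(iter(self.trajectories.values())).n_samples

    @property
    def duration_s(self) -> float:
        return (self.n_samples - 1) / self.fs

    def trajectory(self, person: Person | str, tracker: Tracker | str) -> Trajectory:
        return self.trajectories[(Person(person), Tracker(tracker))]

    def exclude(self, reason: str) -> None:
        self.excluded = True
        self.exclusion_reason = reason


@dataclass(frozen=True)
class ExperimentDesign:
    """Scale of the full experiment (the study ran 12 x 3 x 64)."""

    n_participants: int = 12
    sessions_per_participant: int = 3
    trials_per_session: int = 64
    trackers_per_person: int = 8

    def __post_init__(self) -> None:
        for name in (
            "n_participants",
            "sessions_per_participant",
            "trials_per_session",
            "trackers_per_person",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")

    @property
    def n_trials(self) -> int:
        return self.n_participants * self.sessions_per_participant * self.trials_per_session


@dataclass
class NormalizedCurve:
    """A 120-sample, amplitude-normalized speed profile of a primary movement."""

    values: np.ndarray
    source: tuple = ()

    N_SAMPLES = 120

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.N_SAMPLES,):
            raise ValidationError(
                f"normalized curve must have exactly {self.N_SAMPLES} samples, "
                f"got shape {self.values.shape}"
            )
        if np.any(self.values < 0):
            raise ValidationError("normalized speed values must be non-negative")
        if not np.isclose(self.values.max(), 1.0):
            raise ValidationError("normalized curve must peak at 1")
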