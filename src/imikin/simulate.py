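"""Synthetic actor-imitator trials and opposition recordings with known truth.

The canonical primary movement is a minimum-jerk reach: position profile
``x(tau) = x0 + dx * (10 tau^3 - 15 tau^4 + 6 tau^5)`` whose speed is the
closed-form bell ``v(tau) = (D/T) * 30 (tau^2 - 2 tau^3 + tau^4)`` with
peak ``1.875 * D / T`` at ``tau = 1/2``.  Actor-imitator coupling is a
shared latent bell plus independent smooth shape noise per person, scaled
by the closed-form attenuation ``rho = V_m / (V_m + V_e)`` so that the
Pearson correlation of the analysed (segmented, resampled) curves equals
the requested coupling in expectation.

Everything is deterministic under the master seed: per-trial generators
are spawned from ``SeedSequence([seed, participant, session, trial])`` so
the output is independent of generation order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import (
    DIGIT_TRACKERS,
    FINGERTIP_TRACKERS,
    Condition,
    Effector,
    ExperimentDesign,
    Meaning,
    Person,
    Site,
    StimCondition,
    StimTime,
    Tracker,
    Trajectory,
    Trial,
    TrialTimeline,
    ValidationError,
)

__all__ = [
    "GeneratorSpec",
    "TrialTruth",
    "OppositionRecording",
    "minimum_jerk_position",
    "minimum_jerk_speed",
    "coupled_speed_curves",
    "digit_effect",
    "generate_trial",
    "generate_trial_curves",
    "assign_conditions",
    "generate_experiment",
    "simulate_contrast_cells",
    "generate_opposition",
]

# nominal tracker layout (cm): start-point posture of the responding arm
_BASE_POS = {
    Tracker.SHOULDER: np.array([-15.0, 0.0, 40.0]),
    Tracker.ELBOW: np.array([-10.0, 10.0, 20.0]),
    Tracker.WRIST: np.array([-2.0, 18.0, 8.0]),
    Tracker.THUMB: np.array([1.0, 21.0, 5.0]),
    Tracker.INDEX: np.array([2.5, 23.0, 5.5]),
    Tracker.MIDDLE: np.array([2.0, 24.0, 5.0]),
    Tracker.RING: np.array([1.0, 23.5, 4.5]),
    Tracker.LITTLE: np.array([0.0, 22.5, 4.0]),
}

# nominal movement direction per tracker (unit vectors)
_BASE_DIR = {
    Tracker.SHOULDER: np.array([0.2, 0.3, 0.93]),
    Tracker.ELBOW: np.array([0.3, 0.5, 0.81]),
    Tracker.WRIST: np.array([0.4, 0.6, 0.69]),
    Tracker.THUMB: np.array([0.5, 0.6, 0.62]),
    Tracker.INDEX: np.array([0.5, 0.65, 0.57]),
    Tracker.MIDDLE: np.array([0.45, 0.7, 0.55]),
    Tracker.RING: np.array([0.4, 0.7, 0.59]),
    Tracker.LITTLE: np.array([0.35, 0.7, 0.62]),
}

_DEFAULT_PEAK_SPEED = {
    Tracker.SHOULDER: 25.0,
    Tracker.ELBOW: 45.0,
    Tracker.WRIST: 65.0,
    Tracker.THUMB: 80.0,
    Tracker.INDEX: 85.0,
    Tracker.MIDDLE: 85.0,
    Tracker.RING: 80.0,
    Tracker.LITTLE: 75.0,
}


@dataclass(frozen=True)
class GeneratorSpec:
    """All knobs of the synthetic world.

    ``actor_imitator_coupling`` is the target Pearson r of the segmented,
    120-sample-resampled actor and imitator speed curves.  ``effect_map``
    maps ``(site, stim_time, tracker subset)`` to a multiplicative
    peak-speed factor applied to the *imitator* in matching trials.
    ``spike_rate`` is the expected number of single-sample electromagnetic
    spikes per trajectory per trial.
    """

    seed: int = 0
    fs: float = 240.0
    movement_duration_s: float = 1.2
    peak_speed_cm_s: dict = field(default_factory=lambda: dict(_DEFAULT_PEAK_SPEED))
    actor_imitator_coupling: float = 0.7
    effect_map: dict = field(default_factory=dict)
    spike_rate: float = 1.0
    spike_amplitude_cm: float = 5.0
    tms_artifact_window_ms: float = 20.0
    tms_artifact_amplitude_cm: float = 8.0
    noise_sd_cm: float = 0.02
    amplitude_jitter_cv: float = 0.08
    duration_jitter_cv: float = 0.05
    participant_speed_cv: float = 0.10
    reaction_time_s: float = 0.35
    reaction_time_jitter_s: float = 0.04
    segment_threshold_cm_s: float = 12.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.actor_imitator_coupling <= 1.0:
            raise ValidationError("coupling must lie in [0, 1]")
        for key, factor in self.effect_map.items():
            if factor <= 0:
                raise ValidationError(f"effect factor for {key} must be positive")
        if self.fs <= 0 or self.movement_duration_s <= 0:
            raise ValidationError("fs and movement duration must be positive")


@dataclass
class TrialTruth:
    """Ground truth returned next to every generated trial."""

    spike_indices: dict  # (person, tracker) -> sorted array of injected spike samples
    artifact_onsets_s: np.ndarray
    artifact_window_ms: float
    movement_onset_s: dict  # person -> movement start (s)
    movement_duration_s: dict  # person -> movement duration (s)
    peak_speed_cm_s: dict  # (person, tracker) -> noiseless peak speed of the bell
    coupling: float


def minimum_jerk_position(tau: np.ndarray) -> np.ndarray:
    """Normalized minimum-jerk position profile on tau in [0, 1], clamped outside."""
    tau = np.clip(np.asarray(tau, dtype=float), 0.0, 1.0)
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def minimum_jerk_speed(t: np.ndarray, distance: float, duration: float) -> np.ndarray:
    """Closed-form speed of a minimum-jerk reach of ``distance`` over ``duration``."""
    tau = np.asarray(t, dtype=float) / duration
    v = np.where(
        (tau >= 0) & (tau <= 1),
        30.0 * distance / duration * (tau**2 - 2 * tau**3 + tau**4),
        0.0,
    )
    return v


def _smooth_shape_noise(rng: np.random.Generator, tau: np.ndarray, n_harmonics: int = 6) -> np.ndarray:
    """Smooth zero-boundary random function: decaying random Fourier sine series."""
    ks = np.arange(1, n_harmonics + 1)
    coef = rng.standard_normal(n_harmonics) / ks
    return np.sin(np.pi * np.outer(tau, ks)) @ coef


def _perturbed_bell(
    rng: np.random.Generator,
    peak_speed: float,
    duration_s: float,
    fs: float,
    coupling: float,
    threshold: float,
) -> np.ndarray:
    """One speed curve: minimum-jerk bell + calibrated smooth shape noise.

    The noise is enveloped by the bell (so the curve stays non-negative and
    its tails quiet), centred, projected orthogonal to the bell, and scaled
    to variance ``V_m (1 - rho) / rho`` over the supra-threshold support --
    the part of the curve the analysis pipeline actually correlates.
    """
    n = int(round(duration_s * fs)) + 1
    tau = np.linspace(0.0, 1.0, n)
    distance = peak_speed * duration_s / 1.875
    m = minimum_jerk_speed(tau * duration_s, distance, duration_s)
    if coupling >= 1.0:
        return m
    support = m >= threshold
    if support.sum() < 4:  # pragma: no cover - degenerate tiny movements
        support = np.ones(n, dtype=bool)
    ms = m[support]
    m_c = ms - ms.mean()
    v_m = float(m_c @ m_c) / ms.size
    rho = max(coupling, 1e-6)
    v_e = v_m * (1.0 - rho) / rho

    # basis of envelope-shaped harmonics: each vanishes where the bell is
    # within 2x threshold of the segmentation level, so the analysis
    # windows stay deterministic (threshold crossings do not move)
    margin = 2.0 * threshold
    envelope = np.clip(m - margin, 0.0, None) / (m.max() - margin)
    ks = np.arange(1, 7)
    basis = np.sin(np.pi * np.outer(tau, ks)) * envelope[:, None]  # (n, K)
    bs = basis[support]
    # project the random coefficients so the realized noise is exactly
    # mean-free and bell-orthogonal on the support (keeps the closed-form
    # attenuation r = V_m / (V_m + V_e) exact per realization)
    constraints = np.vstack([bs.sum(axis=0), m_c @ bs])  # (2, K)
    w = rng.standard_normal(ks.size) / ks
    sol, *_ = np.linalg.lstsq(constraints.T, w, rcond=None)
    w = w - constraints.T @ sol
    es = bs @ w
    var_g = float(es @ es) / es.size
    if var_g <= 0:  # pragma: no cover
        return m
    scale = math.sqrt(v_e / var_g)
    return np.clip(m + scale * (basis @ w), 0.0, None)


def _segment_resample(curve: np.ndarray, threshold: float, n: int = 120) -> np.ndarray:
    """Supra-threshold segment of a curve resampled to ``n`` points
    (the analysis pipeline's segmentation convention)."""
    above = curve >= threshold
    onset = int(np.argmax(above))
    peak = int(np.argmax(curve))
    after = np.flatnonzero(curve[peak + 1 :] < threshold)
    offset = int(peak + 1 + after[0]) if after.size else curve.size - 1
    seg = curve[onset : offset + 1]
    return np.interp(np.linspace(0, 1, n), np.linspace(0, 1, seg.size), seg)


def coupled_speed_curves(
    rng: np.random.Generator,
    peak_actor: float,
    peak_imitator: float,
    duration_s: float,
    fs: float,
    coupling: float,
    threshold: float = 12.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Actor and imitator speed curves sharing the latent bell.

    Each person receives independent shape noise with variance
    ``V_m (1 - rho') / rho'``, giving expected Pearson correlation
    ``coupling`` between the segmented, resampled curves.  When the two
    peak speeds differ, their supra-threshold windows differ, so even the
    noiseless resampled bells correlate at some ``rho_mm < 1``; the noise
    target is deflated to ``rho' = coupling / rho_mm`` to compensate
    (closed-form attenuation calibration).
    """
    if coupling >= 1.0:
        a = _perturbed_bell(rng, peak_actor, duration_s, fs, 1.0, threshold)
        b = _perturbed_bell(rng, peak_imitator, duration_s, fs, 1.0, threshold)
        return a, b
    n = int(round(duration_s * fs)) + 1
    tau = np.linspace(0.0, 1.0, n)
    bells = [
        minimum_jerk_speed(tau * duration_s, pk * duration_s / 1.875, duration_s)
        for pk in (peak_actor, peak_imitator)
    ]
    rho_mm = float(
        np.corrcoef(
            _segment_resample(bells[0], threshold), _segment_resample(bells[1], threshold)
        )[0, 1]
    )
    rho_eff = min(coupling / rho_mm, 1.0) if rho_mm > 0 else coupling
    a = _perturbed_bell(rng, peak_actor, duration_s, fs, rho_eff, threshold)
    b = _perturbed_bell(rng, peak_imitator, duration_s, fs, rho_eff, threshold)
    return a, b


def digit_effect(site: Site | str, stim_time: StimTime | str, factor: float) -> dict:
    """Effect map raising the imitator's digit peak speeds in one design cell."""
    return {(Site(site), StimTime(stim_time), DIGIT_TRACKERS): factor}


def _effect_factor(spec: GeneratorSpec, condition: Condition, tracker: Tracker) -> float:
    factor = 1.0
    for (site, stim_time, trackers), f in spec.effect_map.items():
        if Site(site) is condition.site and StimTime(stim_time) is condition.stim_time:
            if tracker in tuple(Tracker(t) for t in trackers):
                factor *= f
    return factor


def _trial_rng(spec: GeneratorSpec, participant_id: int, session: int, trial_index: int):
    return np.random.default_rng(
        np.random.SeedSequence([spec.seed, int(participant_id), int(session), int(trial_index)])
    )


def _participant_factor(spec: GeneratorSpec, participant_id: int) -> float:
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 990001, int(participant_id)]))
    return float(np.exp(rng.normal(0.0, spec.participant_speed_cv)))


def generate_trial(
    spec: GeneratorSpec,
    condition: Condition,
    participant_id: int,
    session: int = 1,
    trial_index: int = 0,
) -> tuple[Trial, TrialTruth]:
    """Generate one actor-imitator trial plus its ground truth.

    Both persons execute minimum-jerk reaches in their response windows;
    the imitator's curves are coupled to the actor's at the requested
    strength; peak speeds are scaled by the effect map for the trial's
    condition; spikes and stimulation-locked artifact windows are injected
    at known, returned locations.
    """
    condition = Condition(
        condition.site, condition.stim_time, condition.meaning, condition.effector
    )
    rng = _trial_rng(spec, participant_id, session, trial_index)
    timeline = TrialTimeline.standard(
        stim_condition=StimCondition(condition.stim_time.value)
    )
    fs = spec.fs
    total_s = timeline.imitator_hold_end_s + 1.5
    n = int(round(total_s * fs)) + 1
    t = np.arange(n) / fs

    p_factor = _participant_factor(spec, participant_id)

    # per-person movement timing
    onsets, durations = {}, {}
    for person, go in (
        (Person.ACTOR, timeline.actor_go_tone_s),
        (Person.IMITATOR, timeline.imitator_go_tone_s),
    ):
        rt = spec.reaction_time_s + spec.reaction_time_jitter_s * rng.standard_normal()
        onsets[person] = go + max(rt, 0.05)
        dur = spec.movement_duration_s * float(
            np.exp(spec.duration_jitter_cv * rng.standard_normal())
        )
        durations[person] = dur

    trajectories: dict[tuple[Person, Tracker], Trajectory] = {}
    spike_truth: dict[tuple[Person, Tracker], np.ndarray] = {}
    peak_truth: dict[tuple[Person, Tracker], float] = {}

    for tracker in Tracker:
        base_peak = spec.peak_speed_cm_s[tracker]
        amp_jitter = float(np.exp(spec.amplitude_jitter_cv * rng.standard_normal()))
        peak_actor = base_peak * amp_jitter
        peak_imit = (
            base_peak
            * p_factor
            * float(np.exp(spec.amplitude_jitter_cv * rng.standard_normal()))
            * _effect_factor(spec, condition, tracker)
        )
        curve_a, curve_i = coupled_speed_curves(
            rng,
            peak_actor,
            peak_imit,
            spec.movement_duration_s,
            fs,
            spec.actor_imitator_coupling,
            spec.segment_threshold_cm_s,
        )
        for person, curve, peak in (
            (Person.ACTOR, curve_a, peak_actor),
            (Person.IMITATOR, curve_i, peak_imit),
        ):
            # person-specific time base: resample the shared-duration curve
            dur = durations[person]
            m = int(round(dur * fs)) + 1
            curve_p = np.interp(
                np.linspace(0.0, 1.0, m), np.linspace(0.0, 1.0, curve.size), curve
            )
            direction = _BASE_DIR[tracker] + 0.05 * rng.standard_normal(3)
            direction = direction / np.linalg.norm(direction)
            pos = np.tile(_BASE_POS[tracker], (n, 1)).astype(float)
            i0 = int(round(onsets[person] * fs))
            i1 = min(i0 + m, n)
            path = np.cumsum(curve_p)[: i1 - i0] / fs
            pos[i0:i1] += np.outer(path, direction)
            displacement = path[-1] if len(path) else 0.0
            pos[i1:] += displacement * direction
            # return movement after the hold period
            hold_end = (
                timeline.actor_hold_end_s
                if person is Person.ACTOR
                else timeline.imitator_hold_end_s
            )
            r0 = int(round((hold_end + 0.2) * fs))
            r1 = min(r0 + int(round(0.8 * fs)), n)
            if r0 < n and displacement > 0:
                back = minimum_jerk_position(np.linspace(0.0, 1.0, r1 - r0))
                pos[r0:r1] -= np.outer(back * displacement, direction)
                pos[r1:] -= displacement * direction
            pos += spec.noise_sd_cm * rng.standard_normal(pos.shape)
            trajectories[(person, tracker)] = Trajectory(
                tracker=tracker, person=person, fs=fs, pos=pos
            )
            peak_truth[(person, tracker)] = peak

    # single-sample electromagnetic spikes
    for key, traj in trajectories.items():
        n_spikes = rng.poisson(spec.spike_rate)
        idx = np.sort(rng.integers(10, n - 10, size=n_spikes))
        for i in idx:
            axis = rng.integers(0, 3)
            traj.pos[i, axis] += spec.spike_amplitude_cm * rng.choice([-1.0, 1.0]) * (
                1.0 + rng.exponential(0.5)
            )
        spike_truth[key] = idx

    # stimulation-locked artifact windows on every channel
    pulses = timeline.stim_pulse_times()
    half = spec.tms_artifact_window_ms / 2000.0
    for onset in pulses:
        j0 = max(int(round((onset - half) * fs)), 0)
        j1 = min(int(round((onset + half) * fs)) + 1, n)
        burst = spec.tms_artifact_amplitude_cm * rng.standard_normal((j1 - j0, 3))
        for traj in trajectories.values():
            traj.pos[j0:j1] += burst

    trial = Trial(
        trajectories=trajectories,
        timeline=timeline,
        condition=condition,
        participant_id=participant_id,
        session=session,
        artifact_onsets_s=[float(x) for x in pulses],
    )
    truth = TrialTruth(
        spike_indices=spike_truth,
        artifact_onsets_s=pulses,
        artifact_window_ms=spec.tms_artifact_window_ms,
        movement_onset_s={p.value: onsets[p] for p in Person},
        movement_duration_s={p.value: durations[p] for p in Person},
        peak_speed_cm_s=peak_truth,
        coupling=spec.actor_imitator_coupling,
    )
    return trial, truth


def assign_conditions(design: ExperimentDesign, seed: int = 0) -> pd.DataFrame:
    """Counterbalanced condition table for a full experiment.

    Sites rotate across sessions in a Latin-square pattern over
    participants; within a session the 64 trials split into a meaningful
    and a meaningless block (32/32), each balanced over stimulation time
    and effector, with deterministic within-block shuffling.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 424242]))
    sites = list(Site)
    rows = []
    for p in range(1, design.n_participants + 1):
        for s in range(1, design.sessions_per_participant + 1):
            site = sites[(p + s - 2) % len(sites)]
            per_block = design.trials_per_session // 2
            block_order = [Meaning.MEANINGFUL, Meaning.MEANINGLESS]
            if rng.random() < 0.5:
                block_order.reverse()
            trial_idx = 0
            for meaning in block_order:
                combos = [(st, eff) for st in StimTime for eff in Effector]
                # cycle the 4 stim_time x effector combinations so blocks of
                # any size stay as balanced as possible (exact at 16k trials)
                cells = [combos[i % 4] for i in range(per_block)]
                rng.shuffle(cells)
                for stim_time, effector in cells:
                    rows.append(
                        {
                            "participant": p,
                            "session": s,
                            "trial": trial_idx,
                            "site": site.value,
                            "stim_time": stim_time.value,
                            "meaning": meaning.value,
                            "effector": effector.value,
                        }
                    )
                    trial_idx += 1
    return pd.DataFrame(rows)


def generate_experiment(
    spec: GeneratorSpec,
    design: ExperimentDesign,
    out_dir=None,
):
    """Generate a whole experiment from the counterbalanced assignment.

    With ``out_dir`` given, trials are written in the on-disk schema and a
    manifest is written there; the manifest path is returned.  Without it,
    a list of ``(Trial, TrialTruth)`` is returned (only advisable for
    small designs -- full trials are ~1 MB each in memory).
    """
    from . import io as _io

    assignment = assign_conditions(design, seed=spec.seed)
    results = []
    stems = []
    for row in assignment.itertuples(index=False):
        condition = Condition(
            site=row.site, stim_time=row.stim_time, meaning=row.meaning, effector=row.effector
        )
        trial, truth = generate_trial(
            spec, condition, row.participant, session=row.session, trial_index=row.trial
        )
        if out_dir is None:
            results.append((trial, truth))
        else:
            stem = f"p{row.participant:02d}_s{row.session}_t{row.trial:03d}"
            _io.write_trial(trial, out_dir / stem if hasattr(out_dir, "__truediv__") else f"{out_dir}/{stem}")
            stems.append(stem)
    if out_dir is not None:
        from pathlib import Path

        manifest = _io.write_manifest(Path(out_dir) / "manifest.json", stems, design=design)
        return manifest
    return results


def generate_trial_curves(
    spec: GeneratorSpec,
    condition: Condition,
    participant_id: int,
    session: int = 1,
    trial_index: int = 0,
    trackers=DIGIT_TRACKERS,
    person: Person = Person.IMITATOR,
) -> dict:
    """Curve-level fast path: per-tracker speed curves of one trial.

    Returns the noiseless-position speed curve (cm/s, sampled at
    ``spec.fs`` over the movement duration) that :func:`generate_trial`
    would realize for each requested tracker, with the same statistical
    structure (participant baseline factor, amplitude jitter, coupling
    shape noise, effect-map scaling) but without building 16-channel
    position files.  Intended for large simulation studies (power and
    type-I calibration) where generating full trials would dominate the
    runtime; deterministic under the same per-trial seeding scheme.
    """
    condition = Condition(
        condition.site, condition.stim_time, condition.meaning, condition.effector
    )
    rng = np.random.default_rng(
        np.random.SeedSequence(
            [spec.seed, 77, int(participant_id), int(session), int(trial_index)]
        )
    )
    p_factor = _participant_factor(spec, participant_id)
    curves = {}
    for tracker in (Tracker(t) for t in trackers):
        base_peak = spec.peak_speed_cm_s[tracker]
        amp_jitter = float(np.exp(spec.amplitude_jitter_cv * rng.standard_normal()))
        peak = base_peak * amp_jitter * _effect_factor(spec, condition, tracker)
        if person is Person.IMITATOR:
            peak *= p_factor
        curves[tracker] = _perturbed_bell(
            rng,
            peak,
            spec.movement_duration_s,
            spec.fs,
            spec.actor_imitator_coupling,
            spec.segment_threshold_cm_s,
        )
    return curves


def simulate_contrast_cells(
    spec: GeneratorSpec,
    cond_a: Condition,
    cond_b: Condition,
    n_participants: int = 12,
    n_trials: int = 32,
    trackers=DIGIT_TRACKERS,
) -> tuple[np.ndarray, np.ndarray]:
    """Participant-mean resampled digit curves for a two-cell contrast.

    For every participant and cell, ``n_trials`` trials are generated via
    the curve-level fast path, each tracker curve is segmented at the
    movement threshold and resampled to 120 samples, tracker curves are
    averaged within trial and trials within participant.  Returns the two
    ``(n_participants, 120)`` matrices ready for
    :class:`~imikin.clusters.ClusterPermutation`.
    """
    from .kinematics import resample_speed, segment_primary

    def cell(cond: Condition, participant: int, session: int) -> np.ndarray:
        trial_means = []
        for t in range(n_trials):
            curves = generate_trial_curves(
                spec, cond, participant, session, t, trackers=trackers
            )
            resampled = []
            for c in curves.values():
                onset, offset = segment_primary(c)
                offset = offset if offset is not None else c.size - 1
                resampled.append(resample_speed(c[onset : offset + 1]))
            trial_means.append(np.mean(resampled, axis=0))
        return np.mean(trial_means, axis=0)

    a = np.array([cell(cond_a, p, 1) for p in range(1, n_participants + 1)])
    b = np.array([cell(cond_b, p, 2) for p in range(1, n_participants + 1)])
    return a, b


# ---------------------------------------------------------------------------
# finger-thumb opposition task
# ---------------------------------------------------------------------------

_OPPOSITION_CYCLE = (
    Tracker.INDEX,
    Tracker.MIDDLE,
    Tracker.RING,
    Tracker.LITTLE,
    Tracker.RING,
    Tracker.MIDDLE,
)

_FINGER_POS = {
    Tracker.INDEX: np.array([2.5, 8.0, 0.5]),
    Tracker.MIDDLE: np.array([0.8, 9.0, 0.3]),
    Tracker.RING: np.array([-0.8, 8.6, 0.1]),
    Tracker.LITTLE: np.array([-2.4, 7.4, 0.0]),
}


@dataclass
class OppositionRecording:
    """Thumb + four fingertip trajectories with ground-truth touch events."""

    thumb: Trajectory
    fingers: dict  # Tracker -> Trajectory
    touch_times_s: np.ndarray
    touch_digits: list  # Tracker labels, cycling index,middle,ring,little,ring,middle,...
    fs: float


def generate_opposition(
    spec: GeneratorSpec,
    duration_s: float = 15.0,
    iti_ms: float = 350.0,
    iti_jitter_ms: float = 0.0,
) -> OppositionRecording:
    """Cyclic finger-thumb opposition with known touch times.

    The thumb hops between static fingertip positions with minimum-jerk
    segments, arriving (distance zero) exactly at each ground-truth touch
    time; the touch order cycles index, middle, ring, little, ring,
    middle, ...  Touch times are ``iti_ms`` apart plus optional Gaussian
    jitter, snapped to the sample grid.
    """
    if duration_s < 3.0:
        raise ValidationError("opposition recording must span at least 3 epochs (>= 3 s)")
    fs = spec.fs
    if iti_ms < 4000.0 / fs:
        raise ValidationError(
            f"iti_ms={iti_ms} too small to resolve at fs={fs} (need >= {4000.0 / fs:.1f} ms)"
        )
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 515151]))
    n = int(round(duration_s * fs)) + 1
    t = np.arange(n) / fs

    # ground-truth touch schedule, snapped to the sample grid
    touch_times: list[float] = []
    touch_digits: list[Tracker] = []
    k = 0
    next_t = iti_ms / 1000.0
    # leave a 100 ms tail so the last contact minimum has neighbours on
    # both sides (a boundary sample can never be a detectable minimum)
    while next_t <= duration_s - 0.1:
        snapped = round(next_t * fs) / fs
        if touch_times and snapped <= touch_times[-1] + 2.0 / fs:
            snapped = touch_times[-1] + 3.0 / fs
        touch_times.append(snapped)
        touch_digits.append(_OPPOSITION_CYCLE[k % len(_OPPOSITION_CYCLE)])
        k += 1
        step = iti_ms + iti_jitter_ms * rng.standard_normal()
        next_t = snapped + max(step, 4000.0 / fs) / 1000.0

    # thumb path: constant-velocity segments between consecutive targets.
    # The thumb passes each fingertip with non-zero speed, so the
    # thumb-fingertip distance has a kinematically sharp (V-shaped)
    # minimum exactly at the scheduled touch sample, robust to tracker
    # noise at the sub-millimetre level.
    start = np.array([1.0, 5.5, 2.5])
    # park the thumb back at the neutral position after the last touch so
    # the tail of the recording produces no spurious near-contacts
    waypoints = np.array([start] + [_FINGER_POS[d] for d in touch_digits] + [start])
    times = np.array([0.0] + touch_times + [max(duration_s, touch_times[-1] + 0.3)])
    thumb_pos = np.column_stack(
        [np.interp(t, times, waypoints[:, ax]) for ax in range(3)]
    )

    noise = spec.noise_sd_cm / 4.0  # tracker jitter well inside the contact threshold
    thumb = Trajectory(
        tracker=Tracker.THUMB,
        person=Person.IMITATOR,
        fs=fs,
        pos=thumb_pos + noise * rng.standard_normal((n, 3)),
    )
    fingers = {}
    for tr in FINGERTIP_TRACKERS:
        pos = np.tile(_FINGER_POS[tr], (n, 1)) + noise * rng.standard_normal((n, 3))
        fingers[tr] = Trajectory(tracker=tr, person=Person.IMITATOR, fs=fs, pos=pos)
    return OppositionRecording(
        thumb=thumb,
        fingers=fingers,
        touch_times_s=np.array(touch_times),
        touch_digits=touch_digits,
        fs=fs,
    )
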