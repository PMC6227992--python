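"""Read and write the tabular tracker format, trial metadata and manifests.

On disk a trial is a pair of files sharing a stem:

``<stem>.csv``
    one row per (time, person, tracker) with columns
    ``t_s, person, tracker, x_cm, y_cm, z_cm, azimuth_deg, elevation_deg, roll_deg``;
``<stem>.json``
    participant, session, condition labels, timeline, artifact onsets and
    the exclusion flag/reason.

Floats are written with Python's shortest round-tripping repr, so a
write/read cycle is bit-identical for 64-bit values.  An experiment
manifest is a single JSON listing trial stems relative to its own
location.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    Condition,
    ExperimentDesign,
    FormatError,
    Person,
    SchemaError,
    Tracker,
    Trajectory,
    Trial,
    TrialTimeline,
)

__all__ = ["read_trial", "write_trial", "read_manifest", "write_manifest"]

CSV_COLUMNS = [
    "t_s",
    "person",
    "tracker",
    "x_cm",
    "y_cm",
    "z_cm",
    "azimuth_deg",
    "elevation_deg",
    "roll_deg",
]


def _paths(path: str | Path) -> tuple[Path, Path]:
    p = Path(path)
    if p.suffix in {".csv", ".json"}:
        p = p.with_suffix("")
    return p.with_suffix(".csv"), p.with_suffix(".json")


def write_trial(trial: Trial, path: str | Path) -> Path:
    """Write ``trial`` to ``<path>.csv`` + ``<path>.json``; returns the CSV path."""
    csv_path, meta_path = _paths(path)
    frames = []
    for (person, tracker), traj in sorted(
        trial.trajectories.items(), key=lambda kv: (kv[0][0].value, kv[0][1].value)
    ):
        frames.append(
            pd.DataFrame(
                {
                    "t_s": traj.t,
                    "person": person.value,
                    "tracker": tracker.value,
                    "x_cm": traj.pos[:, 0],
                    "y_cm": traj.pos[:, 1],
                    "z_cm": traj.pos[:, 2],
                    "azimuth_deg": traj.ang[:, 0],
                    "elevation_deg": traj.ang[:, 1],
                    "roll_deg": traj.ang[:, 2],
                }
            )
        )
    table = pd.concat(frames, ignore_index=True)[CSV_COLUMNS]
    csv_path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(csv_path, index=False, float_format="%.17g")
    meta = {
        "participant_id": trial.participant_id,
        "session": trial.session,
        "fs": trial.fs,
        "condition": trial.condition.as_dict(),
        "timeline": trial.timeline.as_dict(),
        "artifact_onsets_s": list(map(float, trial.artifact_onsets_s)),
        "excluded": trial.excluded,
        "exclusion_reason": trial.exclusion_reason,
    }
    meta_path.write_text(json.dumps(meta, indent=1))
    return csv_path


def read_trial(path: str | Path) -> Trial:
    """Read a trial written by :func:`write_trial`.

    Raises
    ------
    SchemaError
        if a (person, tracker) channel is absent or a column is missing.
    FormatError
        if a channel's time column is not strictly increasing or sample
        counts differ across channels.
    """
    csv_path, meta_path = _paths(path)
    if not csv_path.exists():
        raise FileNotFoundError(csv_path)
    if not meta_path.exists():
        raise FileNotFoundError(meta_path)
    table = pd.read_csv(csv_path, float_precision="round_trip")
    missing_cols = [c for c in CSV_COLUMNS if c not in table.columns]
    if missing_cols:
        raise SchemaError(f"tracker table is missing columns: {missing_cols}")
    meta = json.loads(meta_path.read_text())
    fs = float(meta["fs"])

    trajectories: dict[tuple[Person, Tracker], Trajectory] = {}
    counts = set()
    for (person_s, tracker_s), grp in table.groupby(["person", "tracker"], sort=False):
        try:
            person, tracker = Person(person_s), Tracker(tracker_s)
        except ValueError as exc:
            raise SchemaError(f"unknown channel label ({person_s}, {tracker_s})") from exc
        t = grp["t_s"].to_numpy()
        if np.any(np.diff(t) <= 0):
            raise FormatError(
                f"non-monotone time column in channel ({person_s}, {tracker_s})"
            )
        trajectories[(person, tracker)] = Trajectory(
            tracker=tracker,
            person=person,
            fs=fs,
            pos=grp[["x_cm", "y_cm", "z_cm"]].to_numpy(),
            ang=grp[["azimuth_deg", "elevation_deg", "roll_deg"]].to_numpy(),
        )
        counts.add(len(grp))
    if len(counts) > 1:
        raise FormatError(f"inconsistent sample counts across channels: {sorted(counts)}")
    return Trial(  # Trial.__post_init__ raises SchemaError naming absent channels
        trajectories=trajectories,
        timeline=TrialTimeline.from_dict(meta["timeline"]),
        condition=Condition(**meta["condition"]),
        participant_id=int(meta["participant_id"]),
        session=int(meta["session"]),
        artifact_onsets_s=list(meta.get("artifact_onsets_s", [])),
        excluded=bool(meta.get("excluded", False)),
        exclusion_reason=meta.get("exclusion_reason"),
    )


def write_manifest(
    path: str | Path,
    trial_stems: list[str],
    design: ExperimentDesign | None = None,
    extra: dict | None = None,
) -> Path:
    """Write an experiment manifest listing trial stems relative to ``path``."""
    path = Path(path)
    doc: dict = {"trials": list(trial_stems)}
    if design is not None:
        doc["design"] = {
            "n_participants": design.n_participants,
            "sessions_per_participant": design.sessions_per_participant,
            "trials_per_session": design.trials_per_session,
            "trackers_per_person": design.trackers_per_person,
        }
    if extra:
        doc.update(extra)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(doc, indent=1))
    return path


def read_manifest(path: str | Path) -> tuple[list[Path], ExperimentDesign | None]:
    """Return absolute trial stems and the design recorded in a manifest."""
    path = Path(path)
    doc = json.loads(path.read_text())
    stems = [path.parent / stem for stem in doc["trials"]]
    design = ExperimentDesign(**doc["design"]) if "design" in doc else None
    return stems, design
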