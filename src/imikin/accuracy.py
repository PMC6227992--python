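"""Imitation accuracy: correlation of actor and imitator velocity curves.

Accuracy is the Pearson correlation between the actor's and the
imitator's 120-sample, amplitude-normalized speed curves, per trial and
tracker.  For parametric averaging the r values are Fisher-transformed,
``Z = 0.5 * ln((1 + r) / (1 - r))`` (equivalently ``atanh(r)``); cell
means of Z feed the repeated-measures ANOVA layer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import (
    NormalizedCurve,
    UndefinedCorrelationError,
    ValidationError,
)

logger = logging.getLogger(__name__)

__all__ = ["AccuracyRecord", "curve_correlation", "fisher_z", "condition_means"]

#: |r| is clipped to 1 - CLIP before the transform so Z stays finite (~8.06)
CLIP = 1e-7


@dataclass(frozen=True)
class AccuracyRecord:
    """Per-trial, per-tracker accuracy score with its condition labels."""

    r: float
    z: float
    participant: int
    tracker: str
    site: str
    stim_time: str
    meaning: str
    effector: str
    trial: int = 0


def curve_correlation(
    actor: NormalizedCurve | np.ndarray, imitator: NormalizedCurve | np.ndarray
) -> float:
    """Pearson r between two 120-sample curves.

    Raises
    ------
    UndefinedCorrelationError
        if either curve has zero variance (the record is dropped, logged
        by the caller).
    """
    a = actor.values if isinstance(actor, NormalizedCurve) else np.asarray(actor, float)
    b = (
        imitator.values
        if isinstance(imitator, NormalizedCurve)
        else np.asarray(imitator, float)
    )
    if a.shape != (NormalizedCurve.N_SAMPLES,) or b.shape != (NormalizedCurve.N_SAMPLES,):
        raise ValidationError(
            f"both curves must have exactly {NormalizedCurve.N_SAMPLES} samples"
        )
    if a.std() == 0 or b.std() == 0:
        raise UndefinedCorrelationError("zero variance curve; correlation undefined")
    return float(np.corrcoef(a, b)[0, 1])


def fisher_z(r: float) -> float:
    """Fisher transform ``0.5 * ln((1 + r) / (1 - r))``.

    ``|r| = 1`` is clipped to ``1 - 1e-7`` before the transform (logged);
    ``|r| > 1`` is a validation error.
    """
    if abs(r) > 1:
        raise ValidationError(f"|r| must be <= 1, got {r}")
    if abs(r) >= 1 - CLIP:
        logger.info("clipping |r| = %s before Fisher transform", r)
        r = np.sign(r) * (1 - CLIP)
    return float(np.arctanh(r))


def condition_means(records) -> pd.DataFrame:
    """Participant x condition mean Z per tracker.

    ``records`` is an iterable of :class:`AccuracyRecord` or an equivalent
    DataFrame.  Returns one row per (participant, site, stim_time,
    meaning, effector, tracker) with the mean ``z``.  Cells of the full
    factorial with no retained record are logged and simply absent from
    the output (the ANOVA layer rejects incomplete designs explicitly).
    """
    if not isinstance(records, pd.DataFrame):
        records = pd.DataFrame([vars(rec) if not isinstance(rec, dict) else rec for rec in records])
    if records.empty:
        raise ValidationError("no accuracy records to average")
    keys = ["participant", "site", "stim_time", "meaning", "effector", "tracker"]
    out = records.groupby(keys, observed=True)["z"].mean().reset_index()
    n_expected = records[keys].drop_duplicates().shape[0]
    full = np.prod([records[k].nunique() for k in keys])
    if n_expected < full:
        logger.warning("condition means: %d of %d cells are empty", full - n_expected, full)
    return out
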