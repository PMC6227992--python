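"""Cluster-length permutation inference on paired-t time-series.

The model: per participant, per condition, a mean resampled speed curve
(120 samples).  At every sample a paired t statistic compares the two
conditions across participants; maximal runs of consecutive samples with
``|t|`` above the two-tailed critical value (2.201 for df = 11 at
alpha = 0.05) are candidate clusters.  Their significance comes from an
empirical null of the *maximum* supra-threshold run length obtained by
independently sign-flipping each participant's paired difference
(10 000 iterations by default), with add-one smoothing:
``p = (1 + #{null >= observed}) / (n_permutations + 1)``.

This mirrors cluster-based statistics in neuroimaging: a fixed
sample-wise threshold forms clusters, a second (empirical) threshold
decides how long a cluster must be to be significant.

Usage follows the statsmodels model/results convention::

    model = ClusterPermutation(curves_a, curves_b, ClusterSpec(seed=1))
    res = model.fit()
    res.summary()
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datatypes import ValidationError

__all__ = [
    "ClusterSpec",
    "Run",
    "ClusterPermutation",
    "ClusterPermutationResults",
    "critical_t",
    "paired_t_series",
    "find_runs",
    "permutation_null",
    "run_p_value",
    "overlap_with_peaks",
]


def critical_t(df: int, alpha: float = 0.05) -> float:
    """Two-tailed critical t value (2.201 for df = 11, alpha = 0.05)."""
    return float(stats.t.ppf(1.0 - alpha / 2.0, df))


@dataclass(frozen=True)
class ClusterSpec:
    """Parameters of the cluster-length permutation test."""

    n_resample: int = 120
    alpha_samplewise: float = 0.05
    n_permutations: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValidationError("n_permutations must be >= 1")
        if not 0 < self.alpha_samplewise < 1:
            raise ValidationError("alpha must lie in (0, 1)")


@dataclass(frozen=True)
class Run:
    """A maximal supra-threshold run: [start, end] inclusive."""

    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def paired_t_series(cell_a: np.ndarray, cell_b: np.ndarray) -> np.ndarray:
    """Sample-wise paired t across participants of (A - B).

    ``cell_a`` and ``cell_b`` are ``(n_participants, n_samples)`` arrays
    of per-participant mean curves, participants aligned row-wise.
    """
    a = np.asarray(cell_a, dtype=float)
    b = np.asarray(cell_b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError(f"cell shapes differ: {a.shape} vs {b.shape}")
    n = a.shape[0]
    if n < 3:
        raise ValidationError(f"need >= 3 participants, got {n}")
    d = a - b
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
        return np.where(sd == 0, np.where(mean == 0, 0.0, np.inf * np.sign(mean)), t)


def find_runs(t_series: np.ndarray, t_crit: float) -> list[Run]:
    """Maximal consecutive index ranges with ``|t|`` strictly above ``t_crit``."""
    above = np.abs(np.asarray(t_series, dtype=float)) > t_crit
    edges = np.flatnonzero(np.diff(np.concatenate(([0], above.view(np.int8), [0]))))
    return [Run(int(a), int(b) - 1) for a, b in zip(edges[::2], edges[1::2])]


def _max_run_lengths(above: np.ndarray) -> np.ndarray:
    """Per-row maximum run length of True in a boolean matrix (vectorized)."""
    running = np.zeros(above.shape[0], dtype=np.int64)
    best = np.zeros(above.shape[0], dtype=np.int64)
    for j in range(above.shape[1]):
        running = np.where(above[:, j], running + 1, 0)
        np.maximum(best, running, out=best)
    return best


def permutation_null(
    cell_a: np.ndarray,
    cell_b: np.ndarray,
    spec: ClusterSpec = ClusterSpec(),
    t_crit: float | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Empirical null of the maximum supra-threshold run length.

    On each of ``n_permutations`` iterations every participant's A/B
    labels are independently flipped (sign-flip of the paired
    difference), the t-series recomputed, and the maximum run length
    recorded (0 if no sample crosses the threshold).  Deterministic under
    ``spec.seed``.
    """
    a = np.asarray(cell_a, dtype=float)
    b = np.asarray(cell_b, dtype=float)
    d = a - b
    n, m = d.shape
    if n < 3:
        raise ValidationError(f"need >= 3 participants, got {n}")
    if t_crit is None:
        t_crit = critical_t(n - 1, spec.alpha_samplewise)
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    signs = rng.choice([-1.0, 1.0], size=(spec.n_permutations, n))
    # per-permutation paired t, vectorized: sum d_i^2 is sign-invariant
    s2 = np.einsum("ij,ij->j", d, d)  # (m,)
    mean = signs @ d / n  # (P, m)
    var = (s2[None, :] - n * mean**2) / (n - 1)
    var = np.clip(var, 0.0, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / np.sqrt(var / n)
        t = np.where(var == 0, np.where(mean == 0, 0.0, np.inf * np.sign(mean)), t)
    return _max_run_lengths(np.abs(t) > t_crit)


def run_p_value(run: Run | int, null_lengths: np.ndarray) -> float:
    """Tail proportion with add-one smoothing.

    ``p = (1 + #{null >= observed length}) / (n_permutations + 1)``;
    an observed length of 0 gives p = 1.
    """
    length = run.length if isinstance(run, Run) else int(run)
    null_lengths = np.asarray(null_lengths)
    n = null_lengths.size
    if length <= 0:
        return 1.0
    return float((1 + int((null_lengths >= length).sum())) / (n + 1))


def overlap_with_peaks(run: Run, grand_mean_curve: np.ndarray) -> set[str]:
    """Which kinematic phases of the grand-mean curve a run intersects.

    Labels: ``"acceleration"`` (samples before the curve's peak),
    ``"PV"`` (the argmax sample itself), ``"deceleration"`` (after it).
    """
    curve = np.asarray(grand_mean_curve, dtype=float)
    peak = int(np.argmax(curve))
    labels: set[str] = set()
    if run.start < peak:
        labels.add("acceleration")
    if run.start <= peak <= run.end:
        labels.add("PV")
    if run.end > peak:
        labels.add("deceleration")
    return labels


class ClusterPermutation:
    """Cluster-length permutation test on two paired sets of curves.

    Parameters
    ----------
    cell_a, cell_b
        ``(n_participants, n_samples)`` per-participant mean curves of the
        two conditions, participants aligned row-wise.
    spec
        Test parameters (threshold alpha, permutations, seed).
    """

    def __init__(self, cell_a, cell_b, spec: ClusterSpec = ClusterSpec()):
        self.cell_a = np.asarray(cell_a, dtype=float)
        self.cell_b = np.asarray(cell_b, dtype=float)
        if self.cell_a.shape != self.cell_b.shape:
            raise ValidationError("cells must have identical (participants, samples) shape")
        self.spec = spec
        self.n_participants = self.cell_a.shape[0]
        self.df = self.n_participants - 1
        self.t_crit = critical_t(self.df, spec.alpha_samplewise)

    def fit(self) -> "ClusterPermutationResults":
        t_series = paired_t_series(self.cell_a, self.cell_b)
        runs = find_runs(t_series, self.t_crit)
        null_lengths = permutation_null(self.cell_a, self.cell_b, self.spec, self.t_crit)
        p_values = [run_p_value(r, null_lengths) for r in runs]
        return ClusterPermutationResults(
            model=self,
            t_series=t_series,
            runs=runs,
            p_values=p_values,
            null_lengths=null_lengths,
        )


@dataclass
class ClusterPermutationResults:
    """Fitted cluster test: t-series, supra-threshold runs, their p-values
    and the empirical null of maximum run lengths."""

    model: ClusterPermutation
    t_series: np.ndarray
    runs: list
    p_values: list
    null_lengths: np.ndarray

    @property
    def t_crit(self) -> float:
        return self.model.t_crit

    def significant_runs(self, alpha: float = 0.05) -> list[Run]:
        return [r for r, p in zip(self.runs, self.p_values) if p < alpha]

    def summary(self) -> str:
        spec = self.model.spec
        lines = [
            "Cluster-length permutation test",
            f"  participants: {self.model.n_participants}  (df = {self.model.df})",
            f"  sample-wise threshold: |t| > {self.t_crit:.3f} "
            f"(alpha = {spec.alpha_samplewise})",
            f"  permutations: {spec.n_permutations}  (seed = {spec.seed})",
            f"  runs: {len(self.runs)}",
        ]
        for run, p in zip(self.runs, self.p_values):
            lines.append(
                f"    samples {run.start}-{run.end}  length {run.length:3d}  p = {p:.4f}"
            )
        if not self.runs:
            lines.append("    (no supra-threshold samples)")
        return "\n".join(lines)

    def plot(self, ax=None, label: str | None = None):
        """t-series with horizontal lines at the critical values."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.t_series, label=label)
        ax.axhline(self.t_crit, color="k", lw=0.8)
        ax.axhline(-self.t_crit, color="k", lw=0.8)
        ax.set_xlabel("resampled time (samples)")
        ax.set_ylabel("paired t")
        return ax
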