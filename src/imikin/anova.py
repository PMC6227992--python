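"""Fully-within repeated-measures ANOVA, sphericity handling, post-hoc
paired t-tests and Hedges' g for repeated measures.

The model is the classical univariate within-subject ANOVA on a balanced
participant x factor-cell table of means: for an effect S (a subset of
the within factors) the F ratio is ``(SS_S / df_S) / (SS_{SxSubj} /
df_{SxSubj})`` with the participant as the random blocking factor; the
sums of squares come from a general Moebius (inclusion-exclusion)
decomposition over marginal means, which handles any number of factors
(the study needs up to four).  Partial eta^2 is
``SS_effect / (SS_effect + SS_error)``.

Sphericity: for effects with 2+ numerator df the Greenhouse-Geisser
epsilon is computed from the covariance of orthonormal contrast scores,
``eps = tr(Sigma)^2 / (df * tr(Sigma^2))``, and both df are multiplied by
it.  By default the correction applies only when Mauchly's test rejects
at 0.05 (the "auto" convention; "always"/"never" are available), which
reproduces report tables mixing integer and fractional df.

Post-hoc comparisons are two-tailed paired t-tests against a
Bonferroni-corrected alpha (0.05 / 8 trackers displays as 0.0063), with
Hedges' g_rm effect sizes::

    g_rm = (m1 - m2) / sqrt(s1^2 + s2^2 - 2 r s1 s2) * sqrt(2 (1 - r)) * J,
    J = 1 - 3 / (4 (n - 1) - 1).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import round_half_away
from .datatypes import MissingCellError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "AnovaEffect",
    "AnovaResults",
    "RepeatedMeasuresAnova",
    "rm_anova",
    "MultipleComparisons",
    "EffectSize",
    "posthoc_t",
    "hedges_g_rm",
]


@dataclass(frozen=True)
class AnovaEffect:
    """One row of a repeated-measures ANOVA table."""

    effect: str
    F: float
    df_num: float
    df_den: float
    p: float
    partial_eta_sq: float
    epsilon: float  # 1.0 when uncorrected
    mauchly_w: float | None = None
    mauchly_p: float | None = None
    ss_effect: float = float("nan")
    ss_error: float = float("nan")


@dataclass(frozen=True)
class MultipleComparisons:
    """Bonferroni control over a family of tests."""

    family_alpha: float = 0.05
    n_tests: int = 1

    def __post_init__(self) -> None:
        if self.n_tests < 1 or not 0 < self.family_alpha < 1:
            raise ValidationError("need n_tests >= 1 and 0 < family_alpha < 1")

    @property
    def corrected_alpha(self) -> float:
        return self.family_alpha / self.n_tests

    @property
    def display_alpha(self) -> float:
        """Corrected alpha rounded (half away from zero) to 4 decimals:
        0.05 / 8 displays as 0.0063."""
        return round_half_away(self.corrected_alpha, 4)


@dataclass(frozen=True)
class EffectSize:
    """Hedges' g for repeated measures and the pair correlation it uses."""

    g_rm: float
    r_pair: float


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """k x (k-1) orthonormal contrast matrix (orthogonal to the unit vector)."""
    # Helmert contrasts, orthonormalized
    c = np.zeros((k, k - 1))
    for j in range(1, k):
        c[:j, j - 1] = 1.0
        c[j, j - 1] = -j
        c[:, j - 1] /= np.linalg.norm(c[:, j - 1])
    return c


class RepeatedMeasuresAnova:
    """Fully-within ANOVA model on a long table of cell means.

    Parameters
    ----------
    data
        Long DataFrame with one row per (subject, cell): the subject
        column, one column per within factor, and the dependent variable.
    dv, within, subject
        Column names of the dependent variable, the within-subject
        factors, and the subject identifier.
    correction
        Sphericity handling: ``"auto"`` (Greenhouse-Geisser when Mauchly
        rejects at ``mauchly_alpha``), ``"always"`` or ``"never"``.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        dv: str,
        within: list[str],
        subject: str = "participant",
        correction: str = "auto",
        mauchly_alpha: float = 0.05,
    ):
        if correction not in {"auto", "always", "never"}:
            raise ValidationError("correction must be 'auto', 'always' or 'never'")
        self.dv, self.within, self.subject = dv, list(within), subject
        self.correction, self.mauchly_alpha = correction, mauchly_alpha
        self.levels = {f: sorted(data[f].unique()) for f in self.within}
        self.subjects = sorted(data[subject].unique())
        self._cube = self._build_cube(data)

    def _build_cube(self, data: pd.DataFrame) -> np.ndarray:
        """(subjects, l1, ..., lk) array, validated complete and balanced."""
        shape = [len(self.subjects)] + [len(self.levels[f]) for f in self.within]
        cube = np.full(shape, np.nan)
        sidx = {s: i for i, s in enumerate(self.subjects)}
        lidx = {f: {l: i for i, l in enumerate(self.levels[f])} for f in self.within}
        counts = np.zeros(shape, dtype=int)
        for row in data.itertuples(index=False):
            d = row._asdict()
            key = (sidx[d[self.subject]],) + tuple(
                lidx[f][d[f]] for f in self.within
            )
            cube[key] = d[self.dv]
            counts[key] += 1
        if (counts > 1).any():
            raise ValidationError(
                "multiple observations per subject x cell; pass cell means"
            )
        if np.isnan(cube).any():
            miss = np.argwhere(np.isnan(cube))[0]
            cell = {f: self.levels[f][miss[i + 1]] for i, f in enumerate(self.within)}
            raise MissingCellError(
                f"subject {self.subjects[miss[0]]} is missing cell {cell}"
            )
        return cube

    # -- sums of squares by Moebius decomposition over marginal means -----

    def _pure_ss(self) -> dict[frozenset, float]:
        """Pure SS for every non-empty subset of (subject + within factors).

        Axis 0 of the cube is the subject; within factor i sits on axis
        i + 1.  For a subset T of axes, the raw SS is the squared
        deviation of T's marginal means from the grand mean times the
        count of observations each marginal mean averages; the pure SS
        subtracts all proper non-empty sub-subsets.
        """
        cube = self._cube
        n_axes = cube.ndim
        total_cells = cube.size
        grand = cube.mean()
        raw: dict[frozenset, float] = {}
        axes_all = tuple(range(n_axes))
        for r in range(1, n_axes + 1):
            for T in itertools.combinations(axes_all, r):
                other = tuple(ax for ax in axes_all if ax not in T)
                marg = cube.mean(axis=other) if other else cube
                weight = total_cells / marg.size
                raw[frozenset(T)] = weight * float(((marg - grand) ** 2).sum())
        pure: dict[frozenset, float] = {}
        for T in sorted(raw, key=len):
            pure[T] = raw[T] - sum(
                pure[S] for S in pure if S < T
            )
        return pure

    def _axes_of(self, factors: tuple[str, ...]) -> frozenset:
        return frozenset(self.within.index(f) + 1 for f in factors)

    def _df(self, axes: frozenset) -> int:
        sizes = {0: len(self.subjects)}
        sizes.update({i + 1: len(self.levels[f]) for i, f in enumerate(self.within)})
        return int(np.prod([sizes[a] - 1 for a in axes]))

    def _effect_matrix(self, factors: tuple[str, ...]) -> np.ndarray:
        """Subjects x cells-of-effect matrix, averaged over other factors."""
        keep = [0] + sorted(self._axes_of(factors))
        other = tuple(ax for ax in range(self._cube.ndim) if ax not in keep)
        marg = self._cube.mean(axis=other) if other else self._cube
        return marg.reshape(len(self.subjects), -1)

    def _sphericity(self, factors: tuple[str, ...]) -> tuple[float, float | None, float | None]:
        """(GG epsilon, Mauchly W, Mauchly p) for an effect."""
        y = self._effect_matrix(factors)
        contrasts = [_orthonormal_contrasts(len(self.levels[f])) for f in factors]
        c = contrasts[0]
        for nxt in contrasts[1:]:
            c = np.kron(c, nxt)
        u = y @ c
        d = u.shape[1]
        n = u.shape[0]
        sigma = np.cov(u, rowvar=False, ddof=1)
        sigma = np.atleast_2d(sigma)
        tr = np.trace(sigma)
        eps = float(tr**2 / (d * np.trace(sigma @ sigma))) if tr > 0 else 1.0
        eps = min(max(eps, 1.0 / d), 1.0)
        w = p = None
        if d >= 2 and n - 1 > d:
            det = np.linalg.det(sigma)
            if det > 0 and tr > 0:
                w = float(det / (tr / d) ** d)
                df_chi = d * (d + 1) // 2 - 1
                rho = 1.0 - (2 * d**2 + d + 2) / (6.0 * d * (n - 1))
                chi2 = -(n - 1) * rho * math.log(w)
                p = float(stats.chi2.sf(chi2, df_chi))
            else:
                w, p = 0.0, 0.0
        return eps, w, p

    def fit(self) -> "AnovaResults":
        pure = self._pure_ss()
        effects = []
        for r in range(1, len(self.within) + 1):
            for factors in itertools.combinations(self.within, r):
                axes = self._axes_of(factors)
                err_axes = axes | {0}
                ss_eff, ss_err = pure[axes], pure[err_axes]
                df_num, df_den = self._df(axes), self._df(err_axes)
                if ss_err > 0:
                    F = (ss_eff / df_num) / (ss_err / df_den)
                else:
                    F = 0.0 if ss_eff == 0 else np.inf
                eta = ss_eff / (ss_eff + ss_err) if ss_eff + ss_err > 0 else 0.0
                eps, w, mauchly_p = 1.0, None, None
                if df_num >= 2:
                    eps_gg, w, mauchly_p = self._sphericity(factors)
                    correct = self.correction == "always" or (
                        self.correction == "auto"
                        and mauchly_p is not None
                        and mauchly_p < self.mauchly_alpha
                    )
                    if correct:
                        eps = eps_gg
                p_val = float(stats.f.sf(F, df_num * eps, df_den * eps))
                effects.append(
                    AnovaEffect(
                        effect=":".join(factors),
                        F=float(F),
                        df_num=df_num * eps,
                        df_den=df_den * eps,
                        p=p_val,
                        partial_eta_sq=float(eta),
                        epsilon=float(eps),
                        mauchly_w=w,
                        mauchly_p=mauchly_p,
                        ss_effect=float(ss_eff),
                        ss_error=float(ss_err),
                    )
                )
        return AnovaResults(model=self, effects=effects)


@dataclass
class AnovaResults:
    """Fitted repeated-measures ANOVA: one :class:`AnovaEffect` per main
    effect and interaction."""

    model: RepeatedMeasuresAnova
    effects: list

    def __getitem__(self, effect: str) -> AnovaEffect:
        for e in self.effects:
            if e.effect == effect:
                return e
        raise KeyError(effect)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "effect": e.effect,
                    "F": e.F,
                    "df_num": e.df_num,
                    "df_den": e.df_den,
                    "p": e.p,
                    "partial_eta_sq": e.partial_eta_sq,
                    "epsilon": e.epsilon,
                }
                for e in self.effects
            ]
        )

    def summary(self) -> str:
        lines = [
            "Repeated-measures ANOVA "
            f"(n = {len(self.model.subjects)} subjects, dv = {self.model.dv})",
            f"{'effect':<28}{'F':>8}  {'d.f.':>12}  {'p':>8}  {'eta_p^2':>8}",
        ]
        for e in self.effects:
            df_s = (
                f"{e.df_num:.0f}, {e.df_den:.0f}"
                if e.epsilon == 1.0
                else f"{e.df_num:.2f}, {e.df_den:.2f}"
            )
            lines.append(
                f"{e.effect:<28}{e.F:>8.3f}  {df_s:>12}  {e.p:>8.4f}  {e.partial_eta_sq:>8.3f}"
            )
        return "\n".join(lines)


def rm_anova(
    data: pd.DataFrame,
    dv: str,
    within: list[str],
    subject: str = "participant",
    correction: str = "auto",
) -> AnovaResults:
    """Convenience wrapper: build and fit :class:`RepeatedMeasuresAnova`."""
    return RepeatedMeasuresAnova(
        data, dv=dv, within=within, subject=subject, correction=correction
    ).fit()


def hedges_g_rm(x1, x2) -> EffectSize:
    """Hedges' g for repeated measures with small-sample correction.

    ``g_rm = (m1 - m2) / sqrt(s1^2 + s2^2 - 2 r s1 s2) * sqrt(2 (1 - r)) * J``
    with ``J = 1 - 3 / (4 (n - 1) - 1)``; antisymmetric in its arguments
    and zero when the means are equal.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.shape != x2.shape or x1.ndim != 1:
        raise ValidationError("paired samples must be 1-D arrays of equal length")
    n = x1.size
    if n < 3:
        raise ValidationError(f"need n >= 3 pairs, got {n}")
    s1, s2 = x1.std(ddof=1), x2.std(ddof=1)
    if s1 == 0 or s2 == 0:
        raise ValidationError("zero variance in a condition; effect size undefined")
    r = float(np.corrcoef(x1, x2)[0, 1])
    denom = math.sqrt(s1**2 + s2**2 - 2 * r * s1 * s2)
    if denom == 0:
        raise ValidationError("zero denominator; effect size undefined")
    j = 1.0 - 3.0 / (4.0 * (n - 1) - 1.0)
    g = (x1.mean() - x2.mean()) / denom * math.sqrt(2.0 * (1.0 - r)) * j
    return EffectSize(g_rm=float(g), r_pair=r)


def posthoc_t(
    scores: pd.DataFrame,
    comparisons: list[tuple[str, str]],
    mc: MultipleComparisons = MultipleComparisons(),
) -> pd.DataFrame:
    """Two-tailed paired t-tests with Bonferroni-controlled significance.

    ``scores`` is a wide subjects x conditions table; each comparison is a
    pair of its column names.  A comparison is significant iff
    ``p < mc.corrected_alpha``.  Effect sizes are Hedges' g_rm.
    """
    if scores.shape[0] < 3:
        raise ValidationError("need >= 3 subjects for paired t-tests")
    rows = []
    for a, b in comparisons:
        x1 = scores[a].to_numpy(dtype=float)
        x2 = scores[b].to_numpy(dtype=float)
        t, p = stats.ttest_rel(x1, x2)
        if np.allclose(x1, x2):
            t, p = 0.0, 1.0
        try:
            g = hedges_g_rm(x1, x2).g_rm
        except ValidationError:
            g = float("nan")
        rows.append(
            {
                "comparison": f"{a} vs {b}",
                "t": float(t),
                "p": float(p),
                "g_rm": g,
                "significant": bool(p < mc.corrected_alpha),
            }
        )
    return pd.DataFrame(rows)
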