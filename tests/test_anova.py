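"""Repeated-measures ANOVA, sphericity, post-hoc t-tests, Hedges' g_rm.

Independent oracles: the algebraic F = t^2 identity on two-level designs,
a definitional sums-of-squares computation written out longhand, and
pingouin's rm_anova / epsilon / sphericity for 1-2 factor designs.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from imikin.anova import (
    MultipleComparisons,
    hedges_g_rm,
    posthoc_t,
    rm_anova,
)
from imikin.datatypes import MissingCellError, ValidationError


def _long(cube: np.ndarray, factors: dict) -> pd.DataFrame:
    """Long table from a (subjects, l1, ..., lk) array."""
    names = list(factors)
    rows = []
    for idx in np.ndindex(cube.shape):
        row = {"participant": idx[0]}
        for ax, name in enumerate(names):
            row[name] = factors[name][idx[ax + 1]]
        row["y"] = cube[idx]
        rows.append(row)
    return pd.DataFrame(rows)


class TestRmAnova:
    @pytest.mark.parametrize("seed", range(4))
    def test_two_level_f_equals_paired_t_squared(self, seed):
        rng = np.random.default_rng(seed)
        cube = rng.normal(10, 2, (9, 2))
        df = _long(cube, {"cond": ["A", "B"]})
        res = rm_anova(df, dv="y", within=["cond"])
        t = stats.ttest_rel(cube[:, 0], cube[:, 1])
        assert res["cond"].F == pytest.approx(t.statistic**2, abs=1e-9)
        assert res["cond"].p == pytest.approx(t.pvalue, abs=1e-12)
        assert (res["cond"].df_num, res["cond"].df_den) == (1, 8)

    def test_identical_condition_means_f_zero(self):
        cube = np.tile(np.arange(6.0)[:, None], (1, 3))  # constant per subject
        res = rm_anova(_long(cube, {"cond": ["A", "B", "C"]}), dv="y", within=["cond"])
        assert res["cond"].F == pytest.approx(0.0, abs=1e-12)

    def test_three_level_matches_definitional_ss(self):
        """F, df and partial eta^2 against a longhand SS decomposition."""
        rng = np.random.default_rng(11)
        n, k = 10, 3
        cube = rng.normal(0, 1, (n, k)) + np.array([0.0, 0.5, 1.0])
        grand = cube.mean()
        ss_cond = n * ((cube.mean(0) - grand) ** 2).sum()
        ss_subj = k * ((cube.mean(1) - grand) ** 2).sum()
        ss_total = ((cube - grand) ** 2).sum()
        ss_err = ss_total - ss_cond - ss_subj
        F = (ss_cond / (k - 1)) / (ss_err / ((k - 1) * (n - 1)))
        res = rm_anova(
            _long(cube, {"cond": ["A", "B", "C"]}), dv="y", within=["cond"],
            correction="never",
        )
        e = res["cond"]
        assert e.F == pytest.approx(F, abs=1e-9)
        assert (e.df_num, e.df_den) == (2, 18)
        assert e.partial_eta_sq == pytest.approx(ss_cond / (ss_cond + ss_err), abs=1e-12)

    def test_matches_pingouin_with_gg(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(42)
        n = 12
        cube = rng.normal(0, 1, (n, 3)) * np.array([0.5, 1.0, 2.0]) + np.array(
            [0.0, 0.8, 1.6]
        )
        df = _long(cube, {"cond": ["A", "B", "C"]})
        mine = rm_anova(df, dv="y", within=["cond"], correction="always")["cond"]
        ref = pg.rm_anova(
            df, dv="y", within="cond", subject="participant", correction=True
        ).iloc[0]
        assert mine.F == pytest.approx(ref["F"], rel=1e-9)
        assert mine.epsilon == pytest.approx(ref["eps"], rel=1e-9)
        assert mine.p == pytest.approx(ref["p_GG_corr"], rel=1e-6)
        sph = pg.sphericity(df, dv="y", within="cond", subject="participant")
        assert mine.mauchly_w == pytest.approx(sph.W, rel=1e-9)
        assert mine.mauchly_p == pytest.approx(sph.pval, rel=1e-6)

    def test_two_way_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(7)
        cube = rng.normal(0, 1, (10, 3, 2))
        cube[:, 0, 1] += 0.8
        df = _long(cube, {"site": ["PMv", "PMd", "vertex"], "time": ["obs", "imi"]})
        res = rm_anova(df, dv="y", within=["site", "time"], correction="never")
        ref = pg.rm_anova(df, dv="y", within=["site", "time"], subject="participant")
        for effect, source in [("site", "site"), ("time", "time"), ("site:time", "site * time")]:
            row = ref[ref.Source == source].iloc[0]
            assert res[effect].F == pytest.approx(row["F"], rel=1e-9), effect
            assert res[effect].p == pytest.approx(row["p_unc"], rel=1e-6), effect

    def test_four_way_main_effect_equals_marginal_anova(self):
        """In a balanced fully-within design, a main effect's F from the
        4-way decomposition equals the 1-way F on data averaged over the
        other factors."""
        rng = np.random.default_rng(3)
        cube = rng.normal(0, 1, (8, 3, 2, 2, 2))
        cube[:, 0] += 0.4
        factors = {
            "site": ["PMv", "PMd", "vertex"],
            "time": ["obs", "imi"],
            "meaning": ["mf", "ml"],
            "effector": ["hand", "finger"],
        }
        res4 = rm_anova(
            _long(cube, factors), dv="y",
            within=["site", "time", "meaning", "effector"], correction="never",
        )
        marg = cube.mean(axis=(2, 3, 4))
        res1 = rm_anova(
            _long(marg, {"site": factors["site"]}), dv="y", within=["site"],
            correction="never",
        )
        assert res4["site"].F == pytest.approx(res1["site"].F, rel=1e-9)
        assert len(res4.effects) == 15  # all main effects and interactions

    def test_partial_eta_sq_affine_invariant(self):
        rng = np.random.default_rng(9)
        cube = rng.normal(0, 1, (8, 3))
        df1 = _long(cube, {"cond": ["A", "B", "C"]})
        df2 = df1.assign(y=5.0 * df1.y - 3.0)
        e1 = rm_anova(df1, dv="y", within=["cond"], correction="never")["cond"]
        e2 = rm_anova(df2, dv="y", within=["cond"], correction="never")["cond"]
        assert e1.partial_eta_sq == pytest.approx(e2.partial_eta_sq, abs=1e-12)
        assert e1.F == pytest.approx(e2.F, abs=1e-9)

    def test_missing_cell_names_subject_and_cell(self):
        cube = np.random.default_rng(0).normal(size=(5, 2))
        df = _long(cube, {"cond": ["A", "B"]})
        df = df[~((df.participant == 3) & (df.cond == "B"))]
        with pytest.raises(MissingCellError, match=r"3.*B"):
            rm_anova(df, dv="y", within=["cond"])

    def test_duplicate_observations_rejected(self):
        cube = np.random.default_rng(0).normal(size=(5, 2))
        df = _long(cube, {"cond": ["A", "B"]})
        with pytest.raises(ValidationError, match="cell means"):
            rm_anova(pd.concat([df, df.iloc[:1]]), dv="y", within=["cond"])

    def test_null_p_values_uniform(self):
        """Two-level null simulations give uniform p (Kolmogorov-Smirnov)."""
        rng = np.random.default_rng(2024)
        sims = rng.normal(size=(1000, 12, 2))
        d = sims[:, :, 0] - sims[:, :, 1]
        t = d.mean(1) / (d.std(1, ddof=1) / np.sqrt(12))
        p = 2 * stats.t.sf(np.abs(t), 11)
        # spot-check the vectorized oracle against rm_anova on a few sims
        for i in (0, 500, 999):
            res = rm_anova(_long(sims[i], {"cond": ["A", "B"]}), dv="y", within=["cond"])
            assert res["cond"].p == pytest.approx(p[i], abs=1e-10)
        assert stats.kstest(p, "uniform").pvalue > 0.01

    def test_summary_formats_fractional_df(self):
        rng = np.random.default_rng(1)
        cube = rng.normal(0, 1, (12, 3)) * np.array([0.3, 1.0, 3.0])
        res = rm_anova(_long(cube, {"cond": list("ABC")}), dv="y", within=["cond"],
                       correction="always")
        assert res["cond"].epsilon < 1.0
        assert "." in res.summary().splitlines()[2]


class TestPosthoc:
    def test_identical_conditions(self):
        scores = pd.DataFrame({"A": [1.0, 2, 3, 4], "B": [1.0, 2, 3, 4]})
        out = posthoc_t(scores, [("A", "B")])
        assert out.t.iloc[0] == 0.0 and out.p.iloc[0] == 1.0

    def test_bonferroni_display_alpha(self):
        """alpha 0.05 over 8 trackers displays as 0.0063."""
        mc = MultipleComparisons(family_alpha=0.05, n_tests=8)
        assert mc.corrected_alpha == 0.00625
        assert mc.display_alpha == 0.0063

    def test_t_matches_closed_form(self):
        rng = np.random.default_rng(5)
        x1 = rng.normal(10, 2, 12)
        x2 = x1 + rng.normal(0.7, 1.0, 12)
        d = x1 - x2
        expected = d.mean() / (d.std(ddof=1) / np.sqrt(12))
        out = posthoc_t(pd.DataFrame({"A": x1, "B": x2}), [("A", "B")])
        assert out.t.iloc[0] == pytest.approx(expected, abs=1e-10)

    def test_significance_uses_corrected_alpha(self):
        rng = np.random.default_rng(8)
        x1 = rng.normal(0, 1, 12)
        x2 = x1 + 0.6 + rng.normal(0, 0.5, 12)
        scores = pd.DataFrame({"A": x1, "B": x2})
        loose = posthoc_t(scores, [("A", "B")], MultipleComparisons(0.05, 1))
        strict = posthoc_t(scores, [("A", "B")], MultipleComparisons(0.05, 10_000))
        assert bool(loose.significant.iloc[0])
        assert not bool(strict.significant.iloc[0])

    def test_too_few_subjects(self):
        with pytest.raises(ValidationError):
            posthoc_t(pd.DataFrame({"A": [1.0, 2], "B": [2.0, 1]}), [("A", "B")])


class TestHedgesG:
    def test_equal_means_zero(self):
        x1 = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        x2 = np.array([3.0, 1.0, 5.0, 4.0, 2.0])  # same mean, different pairing
        assert hedges_g_rm(x1, x2).g_rm == pytest.approx(0.0, abs=1e-12)

    def test_step_by_step_hand_computation(self):
        x1 = np.array([10.0, 12.0, 9.0, 11.0, 14.0, 8.0])
        x2 = np.array([11.5, 12.5, 10.0, 10.5, 15.5, 9.5])
        s1, s2 = x1.std(ddof=1), x2.std(ddof=1)
        r = np.corrcoef(x1, x2)[0, 1]
        j = 1 - 3 / (4 * 5 - 1)
        expected = (
            (x1.mean() - x2.mean())
            / np.sqrt(s1**2 + s2**2 - 2 * r * s1 * s2)
            * np.sqrt(2 * (1 - r))
            * j
        )
        out = hedges_g_rm(x1, x2)
        assert out.g_rm == pytest.approx(expected, abs=1e-12)
        assert out.r_pair == pytest.approx(r, abs=1e-12)

    def test_antisymmetric(self):
        rng = np.random.default_rng(0)
        x1, x2 = rng.normal(size=(2, 10))
        assert hedges_g_rm(x1, x2).g_rm == pytest.approx(-hedges_g_rm(x2, x1).g_rm)

    def test_degenerate_rejected(self):
        with pytest.raises(ValidationError):
            hedges_g_rm(np.ones(5), np.ones(5) * 2)
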