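"""Factorial (ART-)ANOVA: alignment correctness, calibration, robustness."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm

from glucotrace.factorial import (EFFECTS, FactorialDesignError, art_align,
                                  art_align_rank, art_anova,
                                  check_assumptions, make_factorial_table,
                                  three_way_anova)


class TestTableConstruction:
    def _per_mouse(self):
        rng = np.random.default_rng(0)
        rows = []
        for d in ("LF", "HFS"):
            for p in ("AL", "DR1", "DR2"):
                for a in (4, 9, 15, 21):
                    for i in range(3):
                        rows.append(dict(mouse_id=f"{d}{p}{a}_{i}", diet=d,
                                         provision=p, age_months=a,
                                         k_2=rng.normal(0.03, 0.005)))
        return pd.DataFrame(rows)

    def test_dr_levels_collapse(self):
        t = make_factorial_table(self._per_mouse(), "k_2")
        assert set(t["provision"]) == {"AL", "DR"}

    def test_dropping_nine_months_reduces_age_df(self):
        pm = self._per_mouse()
        full = three_way_anova(make_factorial_table(pm, "k_2"))
        drop = three_way_anova(make_factorial_table(pm, "k_2", drop_ages=(9,)))
        age_df = lambda r: float(  # noqa: E731
            r.table.loc[r.table.effect == "age_months", "df1"].iloc[0])
        assert age_df(full) == 3 and age_df(drop) == 2

    def test_empty_cell_raises_instructive_error(self):
        pm = self._per_mouse()
        pm = pm[~((pm.diet == "LF") & (pm.provision != "AL")
                  & (pm.age_months == 9))]
        with pytest.raises(FactorialDesignError, match="exclude"):
            three_way_anova(make_factorial_table(pm, "k_2"))


class TestParametricAnova:
    def test_detects_pure_diet_effect(self, balanced_table):
        """3-sigma Diet shift, n=8/cell: Diet significant, interactions not,
        in >= 95% of replicates."""
        hits, false_hits = 0, 0
        for rep in range(60):
            rng = np.random.default_rng(100 + rep)
            res = three_way_anova(balanced_table(rng, n=8, diet_shift=3.0))
            hits += res.p("diet") < 0.001
            inter = [res.p(*e) for e in EFFECTS if len(e) > 1]
            false_hits += any(p < 0.05 for p in inter)
        assert hits >= 57  # >= 95%
        assert false_hits <= 60 * 0.25  # 3 interactions at alpha 0.05

    def test_constant_response_is_null(self, balanced_table):
        rng = np.random.default_rng(0)
        t = balanced_table(rng, n=4, sigma=0.0)
        t["response"] = 5.0
        res = three_way_anova(t)
        assert not (res.table["p"].fillna(1.0) < 0.05).any()

    def test_affine_invariance_of_p_values(self, balanced_table):
        rng = np.random.default_rng(3)
        t = balanced_table(rng, n=5, diet_shift=1.0)
        t2 = t.assign(response=7.0 - 3.0 * t["response"])
        p1 = three_way_anova(t).table["p"].to_numpy()
        p2 = three_way_anova(t2).table["p"].to_numpy()
        np.testing.assert_allclose(p1, p2, rtol=1e-8)

    def test_type_iii_equals_sequential_when_balanced(self, balanced_table):
        rng = np.random.default_rng(4)
        t = balanced_table(rng, n=6, diet_shift=1.0)
        res = three_way_anova(t)
        seq = anova_lm(ols("response ~ C(diet, Sum) * C(provision, Sum)"
                           " * C(age_months, Sum)", data=t).fit(), typ=1)
        np.testing.assert_allclose(res.table["F"].to_numpy(),
                                   seq["F"].to_numpy()[:7], rtol=1e-8)


class TestAlignment:
    def test_aligned_column_isolates_target_effect(self, balanced_table):
        """Full ANOVA on the ALIGNED (unranked) column: F ~ 0 for every
        effect except the aligned-for one (canonical ART correctness)."""
        rng = np.random.default_rng(12)
        t = balanced_table(rng, n=6, diet_shift=2.0)
        for effect in EFFECTS:
            aligned = t.copy()
            aligned["response"] = art_align(t, effect)
            res = three_way_anova(aligned)
            for other in EFFECTS:
                if other == effect:
                    continue
                f = float(res.table.loc[res.table.effect == "x".join(other),
                                        "F"].iloc[0])
                assert f < 1e-6

    def test_aligned_responses_sum_to_zero(self, null_factorial_table):
        for effect in EFFECTS:
            assert abs(art_align(null_factorial_table, effect).mean()) < 1e-9

    def test_ranks_are_permutation_without_ties(self, null_factorial_table):
        r = art_align_rank(null_factorial_table, ("diet",))
        assert sorted(r) == list(range(1, len(null_factorial_table) + 1))


class TestArtAnova:
    def test_art_robust_to_monotone_transform(self, balanced_table):
        """exp() of the response (which wrecks normality) leaves the ART
        conclusion intact: the Diet main effect found parametrically on the
        raw data is still detected, and no spurious effect appears."""
        rng = np.random.default_rng(21)
        t = balanced_table(rng, n=8, diet_shift=2.0)
        assert three_way_anova(t).p("diet") < 0.001
        transformed = art_anova(t.assign(response=np.exp(t["response"])))
        assert transformed.p("diet") < 0.001
        others = [transformed.p(*e) for e in EFFECTS if e != ("diet",)]
        assert all(p > 0.01 for p in others)

    def test_art_parametric_concordance_on_gaussian_data(self, balanced_table):
        """On data meeting parametric assumptions the two methods agree on
        each effect's significance in >= 90% of replicates."""
        agree, total = 0, 0
        for rep in range(40):
            rng = np.random.default_rng(300 + rep)
            t = balanced_table(rng, n=8, diet_shift=2.0)
            pa = three_way_anova(t)
            ar = art_anova(t)
            for e in EFFECTS:
                agree += (pa.p(*e) < 0.05) == (ar.p(*e) < 0.05)
                total += 1
        assert agree / total >= 0.90


class TestAssumptionScreen:
    def test_gaussian_residuals_usually_pass(self):
        met = 0
        for rep in range(50):
            rng = np.random.default_rng(rep)
            resid = rng.normal(size=128)
            groups = np.repeat(np.arange(16), 8)
            met += check_assumptions(resid, groups).assumptions_met
        assert met >= 45  # >= 90%

    def test_heavy_tails_usually_fail(self):
        failed = 0
        for rep in range(50):
            rng = np.random.default_rng(rep)
            resid = stats.t.rvs(df=2, size=128, random_state=rng)
            groups = np.repeat(np.arange(16), 8)
            failed += not check_assumptions(resid, groups).assumptions_met
        assert failed >= 45

    def test_identical_spreads_trivially_homoscedastic(self):
        resid = np.tile([-1.0, 0.0, 1.0], 4)
        groups = np.repeat(np.arange(4), 3)
        rep = check_assumptions(resid, groups)
        assert rep.homoscedasticity_p == pytest.approx(1.0)

    def test_too_few_residuals_rejected(self):
        with pytest.raises(ValueError):
            check_assumptions(np.array([0.1, -0.1]), np.array([0, 1]))
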