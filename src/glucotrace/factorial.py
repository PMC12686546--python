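"""Three-way factorial ANOVA and aligned-rank-transform (ART) ANOVA.

Responses are analysed over Diet (LF/HFS) x Provision (AL/DR; the two
restriction depths DR1/DR2 are collapsed) x Age (3 or 4 levels).  The
parametric route is a fixed-effects factorial ANOVA with sum-to-zero
contrasts and partial (Type III) sums of squares, appropriate for the
mildly unbalanced cohorts (6-9 mice).  The nonparametric route is the
classical aligned rank transform: for each of the seven effects the
response is aligned (cell-mean residuals plus that effect's marginal
estimate), midranked, and refit, reporting only the target effect.
Both routes are always computed; an assumption screen (Shapiro-Wilk on
residuals, Brown-Forsythe across cells) indicates when the parametric
p-values should be read with caution.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm

__all__ = [
    "EFFECTS",
    "AnovaResult",
    "AssumptionReport",
    "FactorialDesignError",
    "make_factorial_table",
    "three_way_anova",
    "art_align",
    "art_align_rank",
    "art_anova",
    "check_assumptions",
]

FACTORS = ("diet", "provision", "age_months")
#: the seven testable effects: three mains, three two-way, one three-way
EFFECTS = tuple(
    tuple(c) for r in (1, 2, 3) for c in itertools.combinations(FACTORS, r)
)

_FORMULA = ("response ~ C(diet, Sum) * C(provision, Sum) "
            "* C(age_months, Sum)")

_TERM_NAME = {
    ("diet",): "C(diet, Sum)",
    ("provision",): "C(provision, Sum)",
    ("age_months",): "C(age_months, Sum)",
    ("diet", "provision"): "C(diet, Sum):C(provision, Sum)",
    ("diet", "age_months"): "C(diet, Sum):C(age_months, Sum)",
    ("provision", "age_months"): "C(provision, Sum):C(age_months, Sum)",
    ("diet", "provision", "age_months"):
        "C(diet, Sum):C(provision, Sum):C(age_months, Sum)",
}


class FactorialDesignError(ValueError):
    """Raised for designs the factorial model cannot test."""


@dataclass(frozen=True)
class AssumptionReport:
    normality_p: float  # Shapiro-Wilk on pooled residuals
    homoscedasticity_p: float  # Brown-Forsythe across cells
    assumptions_met: bool


@dataclass(frozen=True)
class AnovaResult:
    """Seven effect rows (F, df pair, p) plus the method tag."""

    table: pd.DataFrame  # columns: effect, df1, df2, F, p
    method: str  # "parametric" or "ART"
    assumptions: AssumptionReport | None = None

    def p(self, *factors: str) -> float:
        key = "x".join(factors)
        row = self.table.loc[self.table["effect"] == key]
        if row.empty:
            raise KeyError(f"no effect {key!r}")
        return float(row["p"].iloc[0])


def make_factorial_table(
    df: pd.DataFrame,
    response: str,
    *,
    drop_ages: tuple[int, ...] = (),
    collapse_dr: bool = True,
) -> pd.DataFrame:
    """Build the long-format analysis table for one response.

    Collapses DR1/DR2 into DR (the two restriction protocols are
    variants of the same intervention), drops rows with the response
    missing, and optionally drops age levels (the study removed the
    9-month level for insulin-derived responses because one cohort's
    insulin assay was unavailable).
    """
    out = df.loc[df[response].notna(),
                 ["mouse_id", "diet", "provision", "age_months", response]].copy()
    if collapse_dr:
        out["provision"] = np.where(out["provision"] == "AL", "AL", "DR")
    if drop_ages:
        out = out[~out["age_months"].isin(drop_ages)]
    out = out.rename(columns={response: "response"})
    out["age_months"] = out["age_months"].astype(int)
    return out.reset_index(drop=True)


def _validate_table(table: pd.DataFrame) -> None:
    for col in ("response", *FACTORS):
        if col not in table.columns:
            raise FactorialDesignError(f"table missing column {col!r}")
    levels = [sorted(table[f].unique()) for f in FACTORS]
    counts = table.groupby(list(FACTORS), observed=True).size()
    empty = [cell for cell in itertools.product(*levels)
             if cell not in counts.index]
    if empty:
        raise FactorialDesignError(
            f"empty design cells {empty}; exclude the offending factor "
            "level(s) before testing (e.g. drop an age level)")
    small = counts[counts < 2]
    if len(small):
        raise FactorialDesignError(
            f"cells with n < 2: {list(small.index)}")
    for f, lv in zip(FACTORS, levels):
        if len(lv) < 2:
            raise FactorialDesignError(f"factor {f!r} has a single level")


def _fit_ols(table: pd.DataFrame):
    return ols(_FORMULA, data=table).fit()


def _anova_table(fit, typ: int) -> pd.DataFrame:
    y = np.asarray(fit.model.endog, float)
    # constant response: every SS is 0 and F ratios are pure round-off
    degenerate = np.sum((y - y.mean()) ** 2) <= 1e-12 * max(1.0, np.sum(y**2))
    aov = None if degenerate else anova_lm(fit, typ=typ)
    df2 = float(fit.df_resid)
    rows = []
    for effect in EFFECTS:
        term = _TERM_NAME[effect]
        rows.append({
            "effect": "x".join(effect),
            "df1": (np.nan if degenerate else float(aov.loc[term, "df"])),
            "df2": df2,
            "F": 0.0 if degenerate else float(aov.loc[term, "F"]),
            "p": np.nan if degenerate else float(aov.loc[term, "PR(>F)"]),
        })
    return pd.DataFrame(rows)


def three_way_anova(table: pd.DataFrame, *, ss_type: int = 3) -> AnovaResult:
    """Parametric factorial ANOVA with Type III (default) partial SS."""
    _validate_table(table)
    fit = _fit_ols(table)
    report = check_assumptions(fit.resid.to_numpy(),
                               _cell_codes(table))
    return AnovaResult(table=_anova_table(fit, ss_type),
                       method="parametric", assumptions=report)


def _cell_codes(table: pd.DataFrame) -> np.ndarray:
    return (table[list(FACTORS)].astype(str).agg("|".join, axis=1)
            .to_numpy())


def _cell_mean_grid(table: pd.DataFrame) -> pd.Series:
    """Unweighted cell means indexed by the full factor crossing."""
    return table.groupby(list(FACTORS), observed=True)["response"].mean()


def _marginal_effect(cell_means: pd.Series, effect: tuple[str, ...],
                     keys: pd.DataFrame) -> np.ndarray:
    """Inclusion-exclusion estimate of one effect from means of cell
    means (the classical ART construction, robust to mild unbalance)."""
    grand = cell_means.mean()
    est = np.zeros(len(keys))
    for r in range(len(effect), 0, -1):
        sign = (-1.0) ** (len(effect) - r)
        for sub in itertools.combinations(effect, r):
            margin = cell_means.groupby(level=list(sub)).mean()
            if len(sub) > 1:
                idx = pd.MultiIndex.from_arrays(
                    [keys[c] for c in sub], names=list(sub))
            else:
                idx = keys[sub[0]]
            est += sign * margin.reindex(idx).to_numpy()
    est += (-1.0) ** len(effect) * grand
    return est


def art_align(table: pd.DataFrame, effect: tuple[str, ...]) -> np.ndarray:
    """Aligned (not yet ranked) response for one effect: cell-mean
    residuals plus the effect's marginal estimate."""
    _validate_table(table)
    if tuple(effect) not in EFFECTS:
        raise FactorialDesignError(f"unknown effect {effect!r}")
    cm = _cell_mean_grid(table)
    cell_idx = pd.MultiIndex.from_arrays(
        [table[f] for f in FACTORS], names=list(FACTORS))
    resid = table["response"].to_numpy() - cm.reindex(cell_idx).to_numpy()
    return resid + _marginal_effect(cm, tuple(effect), table)


def art_align_rank(table: pd.DataFrame, effect: tuple[str, ...]) -> np.ndarray:
    """Aligned-and-midranked response column for one effect."""
    return stats.rankdata(art_align(table, effect), method="average")


def art_anova(table: pd.DataFrame, *, ss_type: int = 3) -> AnovaResult:
    """Aligned rank transform ANOVA: each of the seven effects is tested
    on its own aligned-ranked column; only the target row is kept."""
    _validate_table(table)
    rows = []
    for effect in EFFECTS:
        ranked = table.copy()
        ranked["response"] = art_align_rank(table, effect)
        sub = _anova_table(_fit_ols(ranked), ss_type)
        rows.append(sub.loc[sub["effect"] == "x".join(effect)])
    return AnovaResult(table=pd.concat(rows, ignore_index=True), method="ART")


def check_assumptions(residuals: np.ndarray, groups: np.ndarray,
                      alpha: float = 0.05) -> AssumptionReport:
    """Normality (Shapiro-Wilk) and homoscedasticity (Brown-Forsythe,
    i.e. Levene centred on medians) screens at level ``alpha``."""
    residuals = np.asarray(residuals, float)
    if len(residuals) < 3:
        raise ValueError("need >= 3 residuals to screen assumptions")
    norm_p = float(stats.shapiro(residuals).pvalue)
    by_cell = [residuals[groups == g] for g in np.unique(groups)]
    by_cell = [c for c in by_cell if len(c) >= 2]
    if len(by_cell) >= 2 and any(np.ptp(c) > 0 for c in by_cell):
        homo_p = float(stats.levene(*by_cell, center="median").pvalue)
    else:
        homo_p = 1.0  # identical spreads: trivially homoscedastic
    return AssumptionReport(
        normality_p=norm_p,
        homoscedasticity_p=homo_p,
        assumptions_met=bool(norm_p > alpha and homo_p > alpha),
    )
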