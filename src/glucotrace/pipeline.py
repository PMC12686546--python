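"""End-to-end study pipeline: ingest/simulate -> fit -> EGP -> indices -> stats.

Every stage is a plain function over DataFrames so individual outputs
(per-mouse fits, EGP summaries, sensitivity indices, cohort summaries,
ANOVA tables) can be regenerated and inspected in isolation.  Mice
whose tracer fit fails to converge are excluded from downstream metrics
and logged, which is what makes the per-metric cohort sizes differ —
the same bookkeeping that produces metric-specific n in the study this
pipeline emulates.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .factorial import (FactorialDesignError, art_anova, make_factorial_table,
                        three_way_anova)
from .indices import compute_indices
from .ingest import BolusSpec, MouseTimeCourse, read_study, write_study
from .kinetics import FitError, fit_tracer, reconstruct_egp
from .simulate import default_truth, simulate_study

logger = logging.getLogger("glucotrace")

__all__ = ["StudyConfig", "StudyResult", "run_study", "summarize_cohorts",
           "fit_study", "egp_study", "indices_study", "anova_study"]

#: responses analysed factorially, with age levels dropped for the
#: insulin-derived ones (one cohort's insulin assay is unavailable at 9 months)
DEFAULT_RESPONSES: dict[str, tuple[int, ...]] = {
    "k_2": (), "k_a": (), "v_per_bw": (), "c_peak": (),
    "avg_specific_egp": (), "steady_state_specific_egp": (),
    "avg_insulin": (9,), "is_p": (9,), "is_l": (9,),
}


@dataclass(frozen=True)
class StudyConfig:
    """Everything needed for a reproducible run."""

    input_csv: str | None = None  # read a study instead of simulating
    n_per_cohort: int = 8
    seed: int = 0
    bolus: BolusSpec = field(default_factory=BolusSpec)
    rel_width_threshold: float = 2.0  # identifiability rule
    ci_method: str = "asymptotic"
    egp_window: tuple[float, float] = (5.0, 120.0)
    ss_window: tuple[float, float] = (105.0, 120.0)
    ss_type: int = 3  # ANOVA sums-of-squares type
    alpha: float = 0.05
    responses: dict = field(default_factory=lambda: dict(DEFAULT_RESPONSES))
    out_dir: str | None = None

    def __post_init__(self) -> None:
        for w in (self.egp_window, self.ss_window):
            if not (0 <= w[0] < w[1] <= 120):
                raise ValueError("analysis windows must lie within [0, 120]")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "bolus" in raw:
            raw["bolus"] = BolusSpec(**raw["bolus"])
        for key in ("egp_window", "ss_window"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def digest(self) -> str:
        blob = json.dumps(self, default=lambda o: o.__dict__, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class StudyResult:
    fits: pd.DataFrame  # one row per mouse: kinetics + EGP + indices
    egp_profiles: pd.DataFrame  # long: mouse_id, time_min, egp_specific
    cohort_summaries: pd.DataFrame
    anova_tables: dict[str, pd.DataFrame]  # response -> 14-row table
    manifest: dict
    truth: pd.DataFrame | None = None  # simulation ledger, if simulated


def fit_study(mice: list[MouseTimeCourse], config: StudyConfig
              ) -> tuple[pd.DataFrame, pd.DataFrame, list]:
    """Fit every mouse; returns (per-mouse table, EGP profiles, failures)."""
    rows, profiles, failures = [], [], []
    for tc in mice:
        try:
            fit = fit_tracer(tc, rel_width_threshold=config.rel_width_threshold,
                             ci_method=config.ci_method)
        except FitError as err:
            logger.warning("fit failed: %s", err)
            failures.append(tc.mouse_id)
            continue
        row = {
            "mouse_id": tc.mouse_id, "diet": tc.diet,
            "provision": tc.provision, "age_months": tc.age_months,
            "body_weight_kg": tc.body_weight,
            "k_a": fit.k_a, "k_2": fit.k_2, "V_mL": fit.V,
            "v_per_bw": fit.V_per_bw, "sse": fit.residual_sse,
            "ci_ka_lo": fit.ci_ka[0], "ci_ka_hi": fit.ci_ka[1],
            "ci_k2_lo": fit.ci_k2[0], "ci_k2_hi": fit.ci_k2[1],
            "ci_V_lo": fit.ci_V[0], "ci_V_hi": fit.ci_V[1],
            "identifiable_ka": fit.identifiable_ka,
            "identifiable_k2": fit.identifiable_k2,
            "converged": fit.converged,
            "t_peak": fit.t_peak, "c_peak": fit.c_peak,
        }
        if fit.converged:
            prof = reconstruct_egp(tc, fit, window=config.egp_window,
                                   ss_window=config.ss_window)
            row["avg_specific_egp"] = prof.avg_specific_egp_5_120
            row["steady_state_specific_egp"] = prof.steady_state_specific_egp
            profiles.append(pd.DataFrame({
                "mouse_id": tc.mouse_id, "time_min": prof.times,
                "egp_specific": prof.egp_specific,
            }))
        else:
            logger.warning("non-converged fit excluded downstream: %s",
                           tc.mouse_id)
            failures.append(tc.mouse_id)
        rows.append(row)
    fits = pd.DataFrame(rows)
    prof_df = (pd.concat(profiles, ignore_index=True) if profiles
               else pd.DataFrame(columns=["mouse_id", "time_min",
                                          "egp_specific"]))
    return fits, prof_df, failures


def egp_study(mice, config):  # convenience alias for stage-wise use
    _, profiles, _ = fit_study(mice, config)
    return profiles


def indices_study(mice: list[MouseTimeCourse], fits: pd.DataFrame
                  ) -> pd.DataFrame:
    """Attach avg insulin, IS_P and IS_L columns to the per-mouse table."""
    by_id = {tc.mouse_id: tc for tc in mice}
    records = []
    for _, row in fits.iterrows():
        if not row["converged"]:
            continue
        tc = by_id[row["mouse_id"]]
        records.append({
            "mouse_id": row["mouse_id"], "k_2": row["k_2"],
            "avg_specific_egp": row.get("avg_specific_egp"),
            "times": tc.times, "insulin": tc.insulin,
        })
    idx = compute_indices(records)
    idx_df = pd.DataFrame([{
        "mouse_id": s.mouse_id, "avg_insulin": s.avg_insulin,
        "is_p": s.is_p, "egp_insulin_product": s.egp_insulin_product,
        "is_l": s.is_l,
    } for s in idx])
    return fits.merge(idx_df, on="mouse_id", how="left")


def summarize_cohorts(per_mouse: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- SEM per metric per cohort (DR1/DR2 kept distinct).

    The per-metric n differ because non-converged fits and missing
    insulin remove mice metric by metric; singleton metrics are kept
    with SEM marked NaN.
    """
    metrics = [c for c in ("k_a", "k_2", "v_per_bw", "c_peak",
                           "avg_specific_egp", "steady_state_specific_egp",
                           "avg_insulin", "is_p", "is_l")
               if c in per_mouse.columns]
    rows = []
    converged = per_mouse[per_mouse.get("converged", True) == True]  # noqa: E712
    for (diet, prov, age), grp in converged.groupby(
            ["diet", "provision", "age_months"], sort=True):
        row = {"diet": diet, "provision": prov, "age_months": age}
        for m in metrics:
            vals = grp[m].dropna().to_numpy(float)
            row[f"{m}_n"] = len(vals)
            row[f"{m}_mean"] = vals.mean() if len(vals) else np.nan
            row[f"{m}_sem"] = (vals.std(ddof=1) / np.sqrt(len(vals))
                               if len(vals) > 1 else np.nan)
        for par in ("ka", "k2"):
            flags = grp[f"identifiable_{par}"].to_numpy(bool)
            row[f"identifiable_{par}_prop"] = (flags.mean() if len(flags)
                                               else np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def anova_study(per_mouse: pd.DataFrame, config: StudyConfig
                ) -> dict[str, pd.DataFrame]:
    """Parametric and ART ANOVA tables for every configured response."""
    out = {}
    for response, drop_ages in config.responses.items():
        if response not in per_mouse.columns:
            continue
        table = make_factorial_table(per_mouse, response,
                                     drop_ages=tuple(drop_ages))
        try:
            par = three_way_anova(table, ss_type=config.ss_type)
            art = art_anova(table, ss_type=config.ss_type)
        except FactorialDesignError as err:
            logger.warning("ANOVA skipped for %s: %s", response, err)
            continue
        par_t = par.table.assign(method="parametric",
                                 normality_p=par.assumptions.normality_p,
                                 homoscedasticity_p=par.assumptions
                                 .homoscedasticity_p,
                                 assumptions_met=par.assumptions
                                 .assumptions_met)
        art_t = art.table.assign(method="ART", normality_p=np.nan,
                                 homoscedasticity_p=np.nan,
                                 assumptions_met=np.nan)
        out[response] = pd.concat([par_t, art_t], ignore_index=True)
    return out


def run_study(config: StudyConfig) -> StudyResult:
    """Run the full pipeline; deterministic given the config seed."""
    truth_ledger = None
    if config.input_csv:
        mice = read_study(config.input_csv, bolus=config.bolus)
    else:
        mice, truth_ledger = simulate_study(
            default_truth(config.seed), n_per_cohort=config.n_per_cohort,
            seed=config.seed, bolus=config.bolus)

    fits, profiles, failures = fit_study(mice, config)
    per_mouse = indices_study(mice, fits)
    summaries = summarize_cohorts(per_mouse)
    anovas = anova_study(per_mouse, config)

    manifest = {
        "version": __version__,
        "config_hash": config.digest(),
        "seed": config.seed,
        "n_mice_input": len(mice),
        "n_fits": len(fits),
        "n_converged": int(per_mouse["converged"].sum()),
        "fit_failures": sorted(failures),
        "n_cohorts": len(summaries),
        "responses_tested": sorted(anovas),
    }

    result = StudyResult(fits=per_mouse, egp_profiles=profiles,
                         cohort_summaries=summaries, anova_tables=anovas,
                         manifest=manifest, truth=truth_ledger)
    if config.out_dir:
        _write_outputs(result, mice, Path(config.out_dir))
    return result


def _write_outputs(result: StudyResult, mice, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    fmt = dict(index=False, float_format="%.10g")
    result.fits.to_csv(out_dir / "per_mouse.csv", **fmt)
    result.egp_profiles.to_csv(out_dir / "egp_profiles.csv", **fmt)
    result.cohort_summaries.to_csv(out_dir / "cohort_summaries.csv", **fmt)
    for response, table in result.anova_tables.items():
        table.to_csv(out_dir / f"anova_{response}.csv", **fmt)
    if result.truth is not None:
        result.truth.to_csv(out_dir / "truth_ledger.csv", **fmt)
        write_study(mice, out_dir / "study_data.csv")
    (out_dir / "manifest.json").write_text(
        json.dumps(result.manifest, indent=2, sort_keys=True))
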