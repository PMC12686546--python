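"""Reading and validating per-mouse OGTT tracer studies.

The study design crosses Diet (LF: low fat; HFS: high fat + sucrose),
Provision (AL: ad libitum; DR1/DR2: two depths of dietary restriction)
and Age (4, 9, 15, 21 months).  Each mouse receives an oral bolus of
0.7 g/kg unlabelled glucose plus 0.3 g/kg [6,6-2H2]-glucose tracer and
is sampled every 15 min from 0 to 120 min for labelled and unlabelled
plasma glucose (mM) and plasma insulin (mU/L).

Two input routes are supported: pre-split pool concentrations
(tracer + unlabelled, the layout of the study's supplementary tables)
or a raw isotopologue-enrichment table that is corrected for natural
abundance and split into pools here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BolusSpec",
    "MouseTimeCourse",
    "IsotopologueSeries",
    "StudyValidationError",
    "correct_natural_abundance",
    "split_pools",
    "read_study",
    "read_enrichment_study",
    "write_study",
]

DIETS = ("LF", "HFS")
PROVISIONS = ("AL", "DR1", "DR2")
AGES_MONTHS = (4, 9, 15, 21)

#: default long-format column names; remappable via ``column_map``
DEFAULT_COLUMNS = {
    "mouse_id": "mouse_id",
    "diet": "diet",
    "provision": "provision",
    "age_months": "age_months",
    "body_weight_g": "body_weight_g",
    "time_min": "time_min",
    "tracer_mM": "tracer_mM",
    "unlabelled_mM": "unlabelled_mM",
    "insulin_mU_L": "insulin_mU_L",
}


class StudyValidationError(ValueError):
    """Raised when an input table violates the study contract."""


@dataclass(frozen=True)
class BolusSpec:
    """Oral glucose bolus, dosed per body weight.

    The default 0.7 g/kg unlabelled + 0.3 g/kg [6,6-2H2] tracer sums to
    the standard 1 g/kg OGTT dose.  Molar masses convert gram doses to
    micromoles for the kinetic model.
    """

    dose_unlabelled: float = 0.7  # g per kg body weight
    dose_tracer: float = 0.3  # g per kg body weight
    molar_mass_unlabelled: float = 180.156  # g/mol
    molar_mass_tracer: float = 182.17  # g/mol, two deuteriums

    def __post_init__(self) -> None:
        for name in ("dose_unlabelled", "dose_tracer"):
            if getattr(self, name) < 0:
                raise ValueError(f"BolusSpec.{name} must be >= 0")
        for name in ("molar_mass_unlabelled", "molar_mass_tracer"):
            if not getattr(self, name) > 0:
                raise ValueError(f"BolusSpec.{name} must be > 0")

    def tracer_dose_umol(self, body_weight_kg: float) -> float:
        """Tracer amount given to a mouse, in micromoles."""
        grams = self.dose_tracer * body_weight_kg
        return grams / self.molar_mass_tracer * 1e6

    def unlabelled_dose_umol(self, body_weight_kg: float) -> float:
        """Unlabelled glucose amount given to a mouse, in micromoles."""
        grams = self.dose_unlabelled * body_weight_kg
        return grams / self.molar_mass_unlabelled * 1e6


@dataclass(frozen=True)
class MouseTimeCourse:
    """One animal's OGTT: sampled pools, insulin, cohort labels, bolus.

    ``insulin`` is ``None`` for animals whose insulin assay is missing
    (the study retained such animals for all non-insulin metrics).
    """

    mouse_id: str
    diet: str
    provision: str
    age_months: int
    body_weight: float  # kg
    times: np.ndarray  # min, ascending, first = 0
    tracer_conc: np.ndarray  # mM
    unlabelled_conc: np.ndarray  # mM
    insulin: np.ndarray | None = None  # mU/L
    bolus: BolusSpec = field(default_factory=BolusSpec)

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, float))
        object.__setattr__(self, "tracer_conc", np.asarray(self.tracer_conc, float))
        object.__setattr__(self, "unlabelled_conc",
                           np.asarray(self.unlabelled_conc, float))
        if self.insulin is not None:
            object.__setattr__(self, "insulin", np.asarray(self.insulin, float))
        self._validate()

    def _validate(self) -> None:
        mid = self.mouse_id
        if self.diet not in DIETS:
            raise StudyValidationError(f"{mid}: unknown diet {self.diet!r}")
        if self.provision not in PROVISIONS:
            raise StudyValidationError(f"{mid}: unknown provision {self.provision!r}")
        if int(self.age_months) not in AGES_MONTHS:
            raise StudyValidationError(f"{mid}: age {self.age_months} not in study grid")
        if not self.body_weight > 0:
            raise StudyValidationError(f"{mid}: body weight must be > 0 kg")
        t = self.times
        if t.ndim != 1 or len(t) < 2:
            raise StudyValidationError(f"{mid}: need >= 2 timepoints")
        if not np.all(np.diff(t) > 0):
            raise StudyValidationError(f"{mid}: times not strictly increasing")
        if t[0] != 0:
            raise StudyValidationError(f"{mid}: first sample must be at t = 0")
        for name in ("tracer_conc", "unlabelled_conc", "insulin"):
            series = getattr(self, name)
            if series is None:
                continue
            if len(series) != len(t):
                raise StudyValidationError(f"{mid}: {name} length != times length")
            if np.any(series < 0):
                raise StudyValidationError(f"{mid}: negative values in {name}")
        if abs(self.tracer_conc[0]) > 1e-9:
            raise StudyValidationError(
                f"{mid}: tracer concentration at t=0 must be 0 after correction")
        if not self.unlabelled_conc[0] > 0:
            raise StudyValidationError(f"{mid}: fasting unlabelled glucose must be > 0")

    @property
    def provision_group(self) -> str:
        """DR1 and DR2 collapsed to DR (used for factorial statistics)."""
        return "AL" if self.provision == "AL" else "DR"

    @property
    def cohort(self) -> tuple[str, str, int]:
        return (self.diet, self.provision, int(self.age_months))

    def with_insulin_removed(self) -> "MouseTimeCourse":
        return replace(self, insulin=None)


@dataclass(frozen=True)
class IsotopologueSeries:
    """Glucose isotopologue mole fractions (M+0..M+4, m/z 408-412) over time."""

    times: np.ndarray
    fractions: np.ndarray  # shape (n_times, 5)

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, float))
        object.__setattr__(self, "fractions", np.asarray(self.fractions, float))
        f = self.fractions
        if f.ndim != 2 or f.shape != (len(self.times), 5):
            raise StudyValidationError("fractions must have shape (n_times, 5)")
        if np.any(f < 0) or np.any(f > 1):
            raise StudyValidationError("mole fractions must lie in [0, 1]")
        if np.any(np.abs(f.sum(axis=1) - 1.0) > 1e-9):
            raise StudyValidationError("each fraction vector must sum to 1")


def correct_natural_abundance(
    series: IsotopologueSeries, *, renormalize: bool = True
) -> tuple[np.ndarray, int]:
    """Baseline-correct M+2 enrichment for natural isotope abundance.

    The t=0 (pre-bolus) sample carries only naturally occurring M+2;
    subtracting it and, by default, renormalizing by the non-natural
    fraction gives the tracer mole fraction

        x(t) = (e(t) - e(0)) / (1 - e(0))

    where e is the M+2 mole fraction.  Returns ``(x, n_clipped)`` where
    ``n_clipped`` counts points clipped into [0, 1] (a warning is issued
    when any are).
    """
    idx0 = np.flatnonzero(series.times == 0)
    if idx0.size == 0:
        raise StudyValidationError("no t=0 baseline sample in isotopologue series")
    e = series.fractions[:, 2]
    e0 = e[idx0[0]]
    if e0 >= 1:
        raise StudyValidationError("baseline M+2 fraction >= 1; cannot correct")
    x = e - e0
    if renormalize:
        x = x / (1.0 - e0)
    clipped = int(np.sum((x < 0) | (x > 1)))
    if clipped:
        warnings.warn(f"{clipped} enrichment value(s) clipped into [0, 1]",
                      stacklevel=2)
    x = np.clip(x, 0.0, 1.0)
    x[idx0[0]] = 0.0
    return x, clipped


def split_pools(
    total_glucose: Sequence[float], tracer_fraction: Sequence[float]
) -> tuple[np.ndarray, np.ndarray]:
    """Split total glucose into tracer and unlabelled pools.

    tracer = x * total, unlabelled = (1 - x) * total; the two pools sum
    back to the input exactly.
    """
    total = np.asarray(total_glucose, float)
    x = np.asarray(tracer_fraction, float)
    if total.shape != x.shape:
        raise StudyValidationError("total and fraction series differ in length")
    if np.any((x < 0) | (x > 1)):
        raise StudyValidationError("tracer fractions must lie in [0, 1]")
    tracer = x * total
    return tracer, total - tracer


def _remap(df: pd.DataFrame, column_map: Mapping[str, str] | None) -> pd.DataFrame:
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    rename = {v: k for k, v in cols.items() if v in df.columns}
    return df.rename(columns=rename)


def read_study(
    path: str | Path | pd.DataFrame,
    *,
    bolus: BolusSpec | None = None,
    column_map: Mapping[str, str] | None = None,
) -> list[MouseTimeCourse]:
    """Read a long-format study CSV into validated per-mouse records.

    Expected columns (remappable): mouse_id, diet, provision, age_months,
    body_weight_g, time_min, tracer_mM, unlabelled_mM, insulin_mU_L
    (nullable).  Animals whose insulin column is entirely missing are
    retained with insulin absent.  Duplicate (mouse_id, time), non-finite
    times and negative concentrations are hard errors.
    """
    df = (path if isinstance(path, pd.DataFrame)
          else pd.read_csv(path, float_precision="round_trip"))
    df = _remap(df, column_map)
    required = ["mouse_id", "diet", "provision", "age_months",
                "body_weight_g", "time_min", "tracer_mM", "unlabelled_mM"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise StudyValidationError(f"input table missing columns: {missing}")
    bolus = bolus or BolusSpec()

    for col in ("tracer_mM", "unlabelled_mM", "insulin_mU_L"):
        if col in df.columns:
            bad = df.index[df[col].notna() & (df[col] < 0)]
            if len(bad):
                raise StudyValidationError(
                    f"negative {col} at rows {list(bad[:10])}")

    mice: list[MouseTimeCourse] = []
    for mouse_id, grp in df.groupby("mouse_id", sort=True):
        grp = grp.sort_values("time_min")
        times = grp["time_min"].to_numpy(float)
        if len(np.unique(times)) != len(times):
            raise StudyValidationError(f"{mouse_id}: duplicated sample times")
        insulin = None
        if "insulin_mU_L" in grp.columns and grp["insulin_mU_L"].notna().any():
            if grp["insulin_mU_L"].isna().any():
                raise StudyValidationError(
                    f"{mouse_id}: insulin series partially missing")
            insulin = grp["insulin_mU_L"].to_numpy(float)
        mice.append(MouseTimeCourse(
            mouse_id=str(mouse_id),
            diet=str(grp["diet"].iloc[0]),
            provision=str(grp["provision"].iloc[0]),
            age_months=int(grp["age_months"].iloc[0]),
            body_weight=float(grp["body_weight_g"].iloc[0]) / 1000.0,
            times=times,
            tracer_conc=grp["tracer_mM"].to_numpy(float),
            unlabelled_conc=grp["unlabelled_mM"].to_numpy(float),
            insulin=insulin,
            bolus=bolus,
        ))
    return mice


def read_enrichment_study(
    enrichment: str | Path | pd.DataFrame,
    metadata: str | Path | pd.DataFrame,
    *,
    bolus: BolusSpec | None = None,
    renormalize: bool = True,
) -> list[MouseTimeCourse]:
    """Assemble a study from an isotopologue-enrichment table.

    ``enrichment`` columns: mouse_id, time_min, m0..m4, total_glucose_mM.
    ``metadata`` columns: mouse_id, diet, provision, age_months,
    body_weight_g and optionally per-time insulin_mU_L.  M+2 enrichment
    is natural-abundance corrected against each mouse's baseline and the
    total is split into tracer/unlabelled pools.
    """
    enr = (enrichment if isinstance(enrichment, pd.DataFrame)
           else pd.read_csv(enrichment, float_precision="round_trip"))
    meta = (metadata if isinstance(metadata, pd.DataFrame)
            else pd.read_csv(metadata, float_precision="round_trip"))
    rows = []
    for mouse_id, grp in enr.groupby("mouse_id", sort=True):
        grp = grp.sort_values("time_min")
        series = IsotopologueSeries(
            times=grp["time_min"].to_numpy(float),
            fractions=grp[["m0", "m1", "m2", "m3", "m4"]].to_numpy(float),
        )
        x, _ = correct_natural_abundance(series, renormalize=renormalize)
        tracer, unlab = split_pools(grp["total_glucose_mM"].to_numpy(float), x)
        rows.append(pd.DataFrame({
            "mouse_id": mouse_id,
            "time_min": series.times,
            "tracer_mM": tracer,
            "unlabelled_mM": unlab,
        }))
    long = pd.concat(rows, ignore_index=True).merge(meta, on=_merge_keys(meta))
    return read_study(long, bolus=bolus)


def _merge_keys(meta: pd.DataFrame) -> list[str]:
    keys = ["mouse_id"]
    if "time_min" in meta.columns:
        keys.append("time_min")
    return keys


def write_study(mice: Iterable[MouseTimeCourse], path: str | Path) -> pd.DataFrame:
    """Write per-mouse records back to the long CSV dialect ``read_study`` reads."""
    frames = []
    for tc in mice:
        frames.append(pd.DataFrame({
            "mouse_id": tc.mouse_id,
            "diet": tc.diet,
            "provision": tc.provision,
            "age_months": tc.age_months,
            "body_weight_g": np.round(tc.body_weight * 1000.0, 6),
            "time_min": tc.times,
            "tracer_mM": tc.tracer_conc,
            "unlabelled_mM": tc.unlabelled_conc,
            "insulin_mU_L": tc.insulin if tc.insulin is not None else np.nan,
        }))
    df = pd.concat(frames, ignore_index=True)
    df.to_csv(path, index=False)
    return df
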