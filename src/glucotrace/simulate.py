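"""Synthetic dual-tracer OGTT studies with known ground truth.

The generator produces full factorial studies (Diet x Provision x Age,
16 cohorts, 8 mice each by default) whose per-mouse curves come from
the same forward model the fitting stage assumes:

* tracer pool: Bateman absorption-elimination curve;
* unlabelled pool: linear one-compartment ODE driven by the unlabelled
  bolus and a time-varying EGP that starts at its basal rate and
  relaxes exponentially toward a suppressed plateau,
  EGP(t) = basal * (1 - depth * (1 - 2^(-t / halftime)));
* insulin: baseline plus a gamma-shaped pulse (only its time average
  enters any downstream index, so the pulse shape is a free choice);
* measurement error: mean-one multiplicative lognormal noise.

The default cohort means emulate the mouse dietary-restriction study
this pipeline reproduces: restricted (DR) cohorts get higher glucose
elimination, higher basal EGP and markedly lower insulin than ad
libitum (AL) cohorts, with age trends that erode the DR advantage on a
high-fat/sucrose diet.  Every study returns a per-mouse truth ledger so
downstream stages can be tested closed-loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .ingest import BolusSpec, MouseTimeCourse
from .kinetics import bateman_conc

__all__ = [
    "CohortTruth",
    "SimTruth",
    "default_truth",
    "simulate_mouse",
    "simulate_study",
    "egp_time_course",
]

#: standard sampling grid: 0-120 min at 15-min intervals
STUDY_TIMES = np.arange(0.0, 121.0, 15.0)

#: insulin masked for this cohort by default (assay unavailable in the study)
DEFAULT_INSULIN_MASK = (("LF", "DR2", 9),)


@dataclass(frozen=True)
class CohortTruth:
    """Generative means for one Diet x Provision x Age cohort."""

    diet: str
    provision: str  # AL, DR1 or DR2
    age_months: int
    k_a: float  # 1/min
    k_2: float  # 1/min
    basal_egp_specific: float  # umol/kg/min at t=0
    egp_suppression_depth: float  # fraction of basal suppressed at plateau
    egp_recovery_halftime: float  # min
    insulin_baseline: float  # mU/L
    insulin_peak: float  # mU/L
    insulin_peak_time: float  # min
    body_weight: float  # kg
    fasting_glucose: float  # mM; pins V via the basal steady state
    v_per_bw: float = field(init=False)  # mL/kg, derived

    def __post_init__(self) -> None:
        if not (self.k_a > self.k_2 > 0):
            raise ValueError("cohort truth requires k_a > k_2 > 0")
        if not 0 <= self.egp_suppression_depth <= 1:
            raise ValueError("suppression depth must lie in [0, 1]")
        # basal steady state: C0 * V * k_2 = EGP(0), per kg of body weight
        object.__setattr__(self, "v_per_bw",
                           self.basal_egp_specific
                           / (self.k_2 * self.fasting_glucose))

    @property
    def label(self) -> str:
        return f"{self.diet}{self.provision}_{self.age_months}m"


@dataclass(frozen=True)
class SimTruth:
    """A study design: cohort means plus between-mouse and assay variability."""

    cohorts: tuple[CohortTruth, ...]
    between_cv: dict = field(default_factory=lambda: {
        "k_a": 0.12, "k_2": 0.12, "v_per_bw": 0.10,
        "basal_egp_specific": 0.10, "insulin": 0.15, "body_weight": 0.07,
    })
    measurement_cv: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for cv in self.between_cv.values():
            if not 0 <= cv <= 0.5:
                raise ValueError("between-mouse CVs must lie in [0, 0.5]")
        if not 0 <= self.measurement_cv <= 0.5:
            raise ValueError("measurement CV must lie in [0, 0.5]")


# Cohort mean tables for the default study.  Ages are columns (4, 9, 15,
# 21 months); LFDR uses the DR1 protocol at 4/15 months and the deeper
# DR2 restriction at 9/21 months, as in the emulated study design.
_K2 = {  # 1/min; DR elevated, declining with age, steeply so on HFS+DR
    ("LF", "AL"): (0.0297, 0.026, 0.022, 0.018),
    ("HFS", "AL"): (0.027, 0.022, 0.018, 0.0147),
    ("LF", "DR"): (0.038, 0.040, 0.037, 0.034),
    ("HFS", "DR"): (0.0408, 0.033, 0.024, 0.0151),
}
_KA = {  # 1/min; mildly higher under DR, mild age decline
    ("LF", "AL"): (0.062, 0.060, 0.058, 0.056),
    ("HFS", "AL"): (0.060, 0.058, 0.056, 0.054),
    ("LF", "DR"): (0.076, 0.074, 0.072, 0.070),
    ("HFS", "DR"): (0.076, 0.073, 0.070, 0.068),
}
_AVG_EGP = {  # umol/kg/min time-averaged over 5-120; DR elevated, HFS lowered
    ("LF", "AL"): (174.0, 160.0, 145.0, 125.0),
    ("HFS", "AL"): (150.0, 135.0, 122.0, 113.0),
    ("LF", "DR"): (199.0, 185.0, 170.0, 155.0),
    ("HFS", "DR"): (175.0, 160.0, 140.0, 127.0),
}
_AVG_INSULIN = {  # mU/L time-averaged; DR strongly reduced, rising with age
    ("LF", "AL"): (30.0, 38.0, 48.0, 60.0),
    ("HFS", "AL"): (62.0, 78.0, 98.0, 123.0),
    ("LF", "DR"): (8.0, 8.5, 10.5, 14.3),
    ("HFS", "DR"): (8.1, 12.0, 18.0, 28.0),
}
_BODY_WEIGHT = {  # kg
    ("LF", "AL"): (0.030, 0.033, 0.035, 0.036),
    ("HFS", "AL"): (0.038, 0.044, 0.048, 0.050),
    ("LF", "DR"): (0.024, 0.024, 0.025, 0.025),
    ("HFS", "DR"): (0.026, 0.027, 0.028, 0.028),
}

_DEPTH = 0.4
_HALFTIME = 20.0  # min
_INSULIN_PEAK_TIME = 15.0  # min
_AGES = (4, 9, 15, 21)


def _egp_window_factor(depth: float, halftime: float,
                       lo: float = 5.0, hi: float = 120.0) -> float:
    """Ratio of time-averaged (over [lo, hi]) to basal EGP for the
    exponential-suppression shape; used to convert target averages to
    basal rates."""
    lam = np.log(2.0) / halftime
    mean_exp = (np.exp(-lam * lo) - np.exp(-lam * hi)) / (lam * (hi - lo))
    return 1.0 - depth * (1.0 - mean_exp)


def _insulin_pulse_weight(peak_time: float, t_end: float = 120.0) -> float:
    """Time-average of the unit gamma pulse (t/tp)^2 exp(2 (1 - t/tp))."""
    t = np.linspace(0.0, t_end, 2001)
    g = (t / peak_time) ** 2 * np.exp(2.0 * (1.0 - t / peak_time))
    return float(np.trapezoid(g, t) / t_end)


def default_truth(seed: int = 0) -> SimTruth:
    """The default 16-cohort study design.

    Cohort means for elimination, EGP and insulin are set to the
    cohort-level values observed in the emulated study; basal EGP and
    insulin baseline/peak are back-calculated so that the *time-averaged*
    quantities the pipeline reports land on those targets.  Fasting
    glycaemia is ~9 mM (LF) / 10 mM (HFS), slightly lower under DR, and
    the apparent distribution volume follows from the basal steady state.
    """
    egp_f = _egp_window_factor(_DEPTH, _HALFTIME)
    ins_w = _insulin_pulse_weight(_INSULIN_PEAK_TIME)
    cohorts = []
    for diet in ("LF", "HFS"):
        for prov_group in ("AL", "DR"):
            for j, age in enumerate(_AGES):
                if prov_group == "AL":
                    provision = "AL"
                elif diet == "LF":
                    provision = "DR1" if age in (4, 15) else "DR2"
                else:
                    provision = "DR1"
                key = (diet, prov_group)
                avg_ins = _AVG_INSULIN[key][j]
                baseline = 0.5 * avg_ins
                peak = baseline + (avg_ins - baseline) / ins_w
                fasting = (9.0 if diet == "LF" else 10.0)
                if prov_group == "DR":
                    fasting -= 0.5
                cohorts.append(CohortTruth(
                    diet=diet, provision=provision, age_months=age,
                    k_a=_KA[key][j], k_2=_K2[key][j],
                    basal_egp_specific=_AVG_EGP[key][j] / egp_f,
                    egp_suppression_depth=_DEPTH,
                    egp_recovery_halftime=_HALFTIME,
                    insulin_baseline=baseline, insulin_peak=peak,
                    insulin_peak_time=_INSULIN_PEAK_TIME,
                    body_weight=_BODY_WEIGHT[key][j],
                    fasting_glucose=fasting,
                ))
    return SimTruth(cohorts=tuple(cohorts), seed=seed)


def egp_time_course(t, basal: float, depth: float, halftime: float):
    """EGP(t) = basal (1 - depth (1 - 2^(-t/halftime))): starts at basal,
    suppressed toward basal (1 - depth) with the given half-time."""
    t = np.asarray(t, float)
    lam = np.log(2.0) / halftime
    return basal * (1.0 - depth * (1.0 - np.exp(-lam * t)))


def _unlabelled_solution(t, dose_umol, V, k_a, k_2,
                         egp0_abs, depth, halftime):
    """Closed-form unlabelled concentration.

    Linear ODE V dC/dt = D k_a e^(-k_a t) + EGP(t) - V k_2 C with the
    basal steady-state initial condition C(0) = EGP(0)/(V k_2); the
    forcing is a sum of exponentials, so the solution is too.
    """
    t = np.asarray(t, float)
    lam = np.log(2.0) / halftime
    a = dose_umol * k_a / V  # bolus forcing amplitude, mM/min
    b = egp0_abs * (1.0 - depth) / V  # plateau EGP, mM/min
    c = egp0_abs * depth / V  # decaying EGP component
    c0 = egp0_abs / (V * k_2)

    def part(coef, mu):
        # particular solution coefficient for forcing coef * e^(-mu t)
        if abs(k_2 - mu) < 1e-10 * k_2:
            return None  # resonant; caller falls back to numerical
        return coef / (k_2 - mu)

    pa, pc = part(a, k_a), part(c, lam)
    if pa is None or pc is None:
        return _unlabelled_numerical(t, dose_umol, V, k_a, k_2,
                                     egp0_abs, depth, halftime, c0)
    const = b / k_2
    k_hom = c0 - const - pa - pc
    return (const + pa * np.exp(-k_a * t) + pc * np.exp(-lam * t)
            + k_hom * np.exp(-k_2 * t))


def _unlabelled_numerical(t, dose_umol, V, k_a, k_2,
                          egp0_abs, depth, halftime, c0):
    from scipy.integrate import solve_ivp

    def rhs(tt, C):
        egp = egp_time_course(tt, egp0_abs, depth, halftime)
        return dose_umol * k_a * np.exp(-k_a * tt) / V + egp / V - k_2 * C

    sol = solve_ivp(rhs, (t[0], t[-1]), [c0], t_eval=t,
                    rtol=1e-10, atol=1e-12, method="LSODA")
    return sol.y[0]


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-one multiplicative lognormal noise with the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return np.exp(rng.normal(-0.5 * sigma**2, sigma, size))


def simulate_mouse(
    truth_draw: CohortTruth,
    bolus: BolusSpec,
    body_weight: float,
    times: np.ndarray = STUDY_TIMES,
    *,
    measurement_cv: float = 0.0,
    rng: np.random.Generator | None = None,
    mouse_id: str = "sim",
    include_insulin: bool = True,
) -> MouseTimeCourse:
    """Forward-simulate one mouse at the given (already drawn) parameters.

    ``truth_draw.v_per_bw`` scales to the animal's volume; the tracer is
    a noiseless Bateman curve and the unlabelled pool the closed-form
    ODE solution, both then multiplied by mean-one lognormal noise with
    CV ``measurement_cv`` (the t=0 tracer sample stays exactly zero).
    """
    rng = rng or np.random.default_rng(0)
    times = np.asarray(times, float)
    V = truth_draw.v_per_bw * body_weight  # mL
    d_tr = bolus.tracer_dose_umol(body_weight)
    d_un = bolus.unlabelled_dose_umol(body_weight)
    egp0_abs = truth_draw.basal_egp_specific * body_weight  # umol/min

    tracer = (bateman_conc(times, d_tr, V, truth_draw.k_a, truth_draw.k_2)
              if d_tr > 0 else np.zeros_like(times))
    if d_un > 0 or truth_draw.egp_suppression_depth > 0:
        unlab = _unlabelled_solution(
            times, d_un, V, truth_draw.k_a, truth_draw.k_2, egp0_abs,
            truth_draw.egp_suppression_depth, truth_draw.egp_recovery_halftime)
    else:
        unlab = np.full_like(times, egp0_abs / (V * truth_draw.k_2))

    tracer = tracer * _lognormal_factor(rng, measurement_cv, times.shape)
    unlab = unlab * _lognormal_factor(rng, measurement_cv, times.shape)
    tracer[times == 0] = 0.0

    insulin = None
    if include_insulin:
        tp = truth_draw.insulin_peak_time
        pulse = (times / tp) ** 2 * np.exp(2.0 * (1.0 - times / tp))
        insulin = (truth_draw.insulin_baseline
                   + (truth_draw.insulin_peak - truth_draw.insulin_baseline)
                   * pulse)
        insulin = insulin * _lognormal_factor(rng, measurement_cv, times.shape)

    return MouseTimeCourse(
        mouse_id=mouse_id, diet=truth_draw.diet,
        provision=truth_draw.provision, age_months=truth_draw.age_months,
        body_weight=body_weight, times=times, tracer_conc=tracer,
        unlabelled_conc=unlab, insulin=insulin, bolus=bolus,
    )


def _draw_mouse_truth(cohort: CohortTruth, cvs: dict,
                      rng: np.random.Generator) -> tuple[CohortTruth, float]:
    """Draw one animal's parameters around the cohort means (mean-one
    lognormal between-mouse variation), re-drawing the rare combinations
    where the absorption/elimination gap collapses."""
    for _ in range(100):
        k_a = cohort.k_a * _lognormal_factor(rng, cvs["k_a"], ())
        k_2 = cohort.k_2 * _lognormal_factor(rng, cvs["k_2"], ())
        if k_a / k_2 >= 1.2:
            break
    else:  # pragma: no cover
        k_a, k_2 = cohort.k_a, cohort.k_2
    egp = cohort.basal_egp_specific * _lognormal_factor(
        rng, cvs["basal_egp_specific"], ())
    ins_scale = _lognormal_factor(rng, cvs["insulin"], ())
    bw = cohort.body_weight * _lognormal_factor(rng, cvs["body_weight"], ())
    fg = cohort.fasting_glucose * _lognormal_factor(rng, cvs["v_per_bw"], ())
    draw = replace(
        cohort, k_a=float(k_a), k_2=float(k_2),
        basal_egp_specific=float(egp),
        insulin_baseline=float(cohort.insulin_baseline * ins_scale),
        insulin_peak=float(cohort.insulin_peak * ins_scale),
        fasting_glucose=float(fg),
    )
    return draw, float(bw)


def simulate_study(
    truth: SimTruth | None = None,
    n_per_cohort: int = 8,
    seed: int | None = None,
    *,
    times: np.ndarray = STUDY_TIMES,
    bolus: BolusSpec | None = None,
    insulin_missing_cohorts=DEFAULT_INSULIN_MASK,
) -> tuple[list[MouseTimeCourse], pd.DataFrame]:
    """Simulate a full study and return (mice, per-mouse truth ledger).

    ``insulin_missing_cohorts`` lists (diet, provision, age) cohorts
    whose insulin series is withheld, emulating the missing LFDR2
    9-month insulin assay.  Deterministic given the seed.
    """
    if n_per_cohort < 2:
        raise ValueError("need n_per_cohort >= 2 (cohort SEM undefined)")
    truth = truth or default_truth()
    seed = truth.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    bolus = bolus or BolusSpec()
    masked = {tuple(c) for c in insulin_missing_cohorts}

    mice: list[MouseTimeCourse] = []
    ledger_rows = []
    for cohort in truth.cohorts:
        has_insulin = (cohort.diet, cohort.provision,
                       cohort.age_months) not in masked
        for i in range(n_per_cohort):
            draw, bw = _draw_mouse_truth(cohort, truth.between_cv, rng)
            mouse_id = f"{cohort.label}_{i:02d}"
            mice.append(simulate_mouse(
                draw, bolus, bw, times,
                measurement_cv=truth.measurement_cv, rng=rng,
                mouse_id=mouse_id, include_insulin=has_insulin))
            ledger_rows.append({
                "mouse_id": mouse_id, "diet": cohort.diet,
                "provision": cohort.provision,
                "age_months": cohort.age_months,
                "body_weight_kg": bw,
                "true_k_a": draw.k_a, "true_k_2": draw.k_2,
                "true_v_per_bw": draw.v_per_bw,
                "true_basal_egp_specific": draw.basal_egp_specific,
                "true_egp_suppression_depth": draw.egp_suppression_depth,
                "true_egp_recovery_halftime": draw.egp_recovery_halftime,
                "true_insulin_baseline": draw.insulin_baseline,
                "true_insulin_peak": draw.insulin_peak,
                "true_fasting_glucose": draw.fasting_glucose,
            })
    return mice, pd.DataFrame(ledger_rows)
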