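# glucotrace

Per-mouse analysis of dual-tracer oral glucose tolerance tests (OGTTs)
in long-term dietary-restriction studies: one-compartment tracer
kinetics, endogenous glucose production (EGP) reconstruction, hepatic
and peripheral insulin-sensitivity indices, and Diet × Provision × Age
factorial statistics — plus a synthetic-study generator with known
ground truth so every stage can be validated closed-loop.

## The problem

A mouse receives an oral bolus of 0.7 g·kg⁻¹ unlabelled glucose plus
0.3 g·kg⁻¹ [6,6-²H₂]-glucose tracer and is sampled every 15 min from 0
to 120 min for labelled and unlabelled plasma glucose (mM) and plasma
insulin (mU·L⁻¹). Because the deuterated tracer cannot come from the
liver, its time course isolates absorption and elimination; the
unlabelled pool then reveals how much glucose the liver adds on top.

**Tracer kinetics.** The tracer follows the Bateman solution of
first-order absorption into a single compartment with first-order
elimination:

    C(t) = (D/V) · k_a/(k_a − k₂) · (e^{−k₂ t} − e^{−k_a t})

with apparent absorption constant k_a (true absorption and gut loss
lumped; only the sum is observable), elimination constant k₂, and
apparent distribution volume V (absorbs oral bioavailability). Fits
use concentration-proportional weighting, multistart, and the flip-flop
convention k_a ≥ k₂; 95 % CIs come from the Jacobian (profile
likelihood optional) and drive per-parameter identifiability flags.

**EGP reconstruction.** With (k_a, k₂, V) fixed, the unlabelled-pool
mass balance is solved for production:

    EGP(t) = V·(dĈ/dt + k₂ Ĉ(t)) − D_un·k_a·e^{−k_a t}

where Ĉ is a shape-preserving (PCHIP) interpolant of the unlabelled
measurements. Reported per mouse: the 5–120 min trapezoidal average of
body-weight-specific EGP (the first 5 min are excluded as unreliable)
and a steady-state average over 105–120 min.

**Sensitivity indices.** IS_P = k₂ / ⟨insulin⟩ (peripheral: clearance
obtained per unit insulin); IS_L inverts the ⟨EGP⟩ × ⟨insulin⟩ product
and is normalised to study mean 1 (hepatic: a liver that keeps
producing glucose despite high insulin scores low).

**Statistics.** Each response is tested with a three-way fixed-effects
ANOVA (sum-to-zero contrasts, Type III sums of squares) *and* an
aligned-rank-transform (ART) ANOVA — seven effects each — with
Shapiro–Wilk/Brown–Forsythe assumption screens. The two restriction
protocols (DR1/DR2) are collapsed to DR for testing; the 9-month age
level is dropped for insulin-derived responses.

## Worked example

```python
from glucotrace import BolusSpec, fit_tracer
from glucotrace.simulate import STUDY_TIMES, default_truth, simulate_mouse

cohort = default_truth(seed=0).cohorts[0]          # LF, ad libitum, 4 months
mouse = simulate_mouse(cohort, BolusSpec(), cohort.body_weight,
                       STUDY_TIMES, measurement_cv=0.0, mouse_id="demo")
fit = fit_tracer(mouse)
```

prints (see `examples/01_tracer_fit.py`):

```
cohort LFAL_4m: true k_a=0.0620 1/min, k_2=0.0297 1/min, V/BW=953 mL/kg
fitted            : k_a=0.0620 1/min, k_2=0.0297 1/min, V/BW=953 mL/kg
tracer peak 0.88 mM at t = 22.8 min; k_2 95% CI (0.0297, 0.0297), identifiable: True
```

A noise-free curve is recovered exactly; the peak time and CI widths
tell you how well the 9-point design pins each constant. The other
`examples/` scripts walk through EGP reconstruction, the sensitivity
indices and the factorial tables; `glucotrace run-all --seed 7 --out
results/` runs everything from the shell.

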