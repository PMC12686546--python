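# Methods

## Kinetic model

The tracer pool is modelled as a two-stage linear scheme: gut amount
G(t) with dG/dt = −k_a G, plasma concentration C(t) with
V dC/dt = k_a G − V k₂ C, G(0) = dose, C(0) = 0. Its closed form is
the Bateman function; at k_a = k₂ the expression degenerates to its
limit (D/V)·k·t·e^{−kt}, used whenever the rates agree to within 1e-8
relative, which keeps the function continuous across the diagonal.
Doses are converted to micromoles with molar masses 180.156 g·mol⁻¹
(unlabelled) and 182.17 g·mol⁻¹ (two deuteriums), both configurable,
so that dose/V is in mM when V is in mL.

The model is deliberately minimal: k₂ is constant per mouse (no
insulin-dependent elimination), and k_a lumps true absorption with gut
loss — the data cannot separate them, and the apparent V absorbs the
unknown bioavailability. The Bateman curve is symmetric under swapping
k_a ↔ k₂ with V rescaled by k₂/k_a (flip-flop); fits are reported
under the convention k_a ≥ k₂, which makes k₂ the terminal-slope
constant.

### Fitting

Nonlinear least squares (scipy `least_squares`, TRF) with bounds
k_a, k₂ ∈ [1e-4, 1] min⁻¹ and V ∈ [1, 500] mL, multistarted from up to
five seeds: k₂ from a log-linear regression on the last three points,
k_a from multiples of that and from the observed peak time, V from
matching the observed peak height. Residuals are weighted by
1/max(y, 0.05·y_peak). The weighting matters: tracer assay error is
relative (a CV), so the small late concentrations — which carry
essentially all the information about k₂ — deserve the same relative
influence as the peak. With unit weights the optimum frequently slides
onto the flip-flop ridge under realistic 5 % noise and k₂ recovery
degrades badly; with relative weights ~93 % of fits land within 15 %
of truth in the generator's identifiable regime. Unit weights remain
available (`weighting="unit"`). The reported SSE is unweighted, in
mM².

Confidence intervals default to asymptotic Wald intervals from the
Jacobian at the optimum with a t quantile on n − 3 df; profile
likelihood (SSE threshold 1 + F₁,ₙ₋₃/(n−3), multiplicative scan plus
bisection) is available via `ci_method="profile"` for identifiability
tables. A parameter is called identifiable when its 95 % interval is
finite, positive at both ends, and narrower than 2× the estimate
(threshold configurable).

## EGP reconstruction

Given a converged fit, the unlabelled balance is solved algebraically
for production: EGP(t) = V(dĈ/dt + k₂Ĉ) − D_un·k_a·e^{−k_a t} on a
1-min grid, with Ĉ a monotone shape-preserving piecewise cubic
(PCHIP) through the nine unlabelled samples. PCHIP avoids the spline
overshoot that a natural cubic would inject into dĈ/dt and hence into
EGP. Negative reconstructed values are retained — clipping would bias
the windowed averages. Two summaries are reported per mouse: the
trapezoidal mean of body-weight-specific EGP over 5–120 min (the first
5 min are excluded because a derivative estimated from sparse early
samples is unreliable there) and a steady-state mean over the final
15-min interval, 105–120 min — a named quantity whose window had to be
fixed somewhere; the last sampling interval is the natural choice.

## Sensitivity indices

⟨insulin⟩ is the trapezoidal time-average over the observed window.
IS_P = k₂/⟨insulin⟩ needs no normalisation. For the hepatic index any
monotone-decreasing, scale-free transform of P = ⟨EGP_specific⟩·⟨insulin⟩
preserves every ordinal comparison; we use IS_L_i = (1/P_i)/mean_j(1/P_j),
which makes the study mean exactly 1, the index dimensionless, and the
result invariant under global rescaling of either input's units. Mice
without insulin data are excluded from the normalising mean and carry
no insulin-dependent fields.

## Factorial statistics

Fixed-effects three-way ANOVA (statsmodels OLS) with sum-to-zero
contrasts and Type III (partial) sums of squares — the appropriate
choice for cohorts of 6–9 mice, where mild unbalance makes sequential
SS order-dependent; Type II is available by config. The ART route
aligns the response for each of the seven effects (cell-mean residuals
plus the effect's inclusion–exclusion estimate from means of cell
means), assigns midranks, refits the full factorial model on the ranks
and keeps only the target effect's row. Alignment from unweighted cell
means is the classical construction; under strong unbalance it is only
approximate, a documented limitation. Both routes are always computed;
a Shapiro–Wilk test on pooled residuals and a Brown–Forsythe test
across cells (α = 0.05) flag when the parametric p-values rest on
shaky assumptions. A constant response is reported as F = 0 with
undefined p rather than as round-off noise. No multiple-testing
correction is applied across effects or responses; p-values are raw.
The two restriction depths (DR1, DR2) are collapsed to a single DR
level for testing, and the 9-month age level is dropped for
insulin-derived responses (insulin, IS_P, IS_L) because one cohort's
insulin assay is missing there — dropping the level, rather than the
cohort, keeps the design fully crossed.

## Synthetic studies

The generator exists so that every downstream stage can be tested
against known truth. It forward-simulates exactly the model the
pipeline assumes — Bateman tracer, linear unlabelled ODE (solved in
closed form; numerically only at resonant parameter coincidences) —
plus two components the pipeline does *not* assume and must recover:

* **EGP dynamics**: EGP(t) = basal·(1 − depth·(1 − 2^{−t/halftime})),
  i.e. production starts at the basal rate and relaxes toward a
  suppressed plateau. Defaults: depth 0.4, half-time 20 min. The
  unlabelled curve starts at the exact basal steady state
  C(0) = EGP(0)/(V·k₂).
* **Insulin**: baseline plus a gamma-shaped pulse (t/t_p)²e^{2(1−t/t_p)}
  peaking at 15 min. Only the time-average enters any index, so the
  pulse shape is a free choice; baseline and peak are back-calculated
  so the time-average lands on each cohort's target.

Measurement error is mean-one multiplicative lognormal (default CV
5 %) — concentrations are positive and assay CVs are relative — and
between-mouse variation is mean-one lognormal per parameter (CV 0.12
for rates, 0.15 for insulin, 0.10 for EGP, 0.07 for body weight),
with the rare draws collapsing the k_a/k₂ gap below 1.2 redrawn.

The default design is the 16-cohort grid (LF/HFS × AL/DR × 4/9/15/21
months, 8 mice per cohort; the LF-restricted arm uses the DR1 protocol
at 4/15 months and the deeper DR2 at 9/21 months, and the LFDR2
9-month cohort's insulin is withheld). Cohort means are set to the
study-scale values the pipeline is meant to resolve: k₂ spanning
0.0147–0.0297 min⁻¹ (AL) and 0.0151–0.0408 min⁻¹ (DR) with the
high-fat restricted arm declining to 0.37 of its young value by 21
months; time-averaged specific EGP 113–174 (AL) and 127–199 (DR)
μmol·kg⁻¹·min⁻¹; time-averaged insulin 30–123 (AL) and 8–28 (DR)
mU·L⁻¹, chosen so the LFDR/HFSDR peripheral-sensitivity ratio moves
from ≈0.94 at 4 months to ≈4.4 at 21 months. The apparent volume is
not an independent dial: it is derived per cohort from a target
fasting glycaemia (≈9 mM LF, ≈10 mM HFS, 0.5 mM lower under DR) via
the basal steady state, which enforces the steady-state invariant
exactly and yields volumes of ~900–1200 mL·kg⁻¹ — large because V is
apparent and absorbs bioavailability.

What the generator does **not** emulate: insulin–glucose feedback
(insulin is exogenous, as in the analysis model), within-mouse
autocorrelated assay drift, non-lognormal outliers, and any model
mismatch between truth and fit (the tracer truly is a Bateman curve).
Passing closed-loop tests therefore demonstrates correctness of the
estimation machinery under the stated noise, not robustness to
structural misspecification in real data.

## Numerical choices and degenerate inputs

* Bateman degenerate branch at |k_a − k₂| < 1e-8·k₂; continuity tested.
* Simulation sizes: parameter-recovery checks use 208 mice (13 per
  cohort) at 5 % noise; null-calibration of the ANOVA routes uses
  1000 (parametric) and 500 (ART) replicates of a 2×2×2, n=4 design.
* All-zero tracer series, fewer than 5 timepoints, duplicate sample
  times, negative concentrations, non-zero corrected tracer baseline
  and empty design cells are hard errors naming the offending mouse or
  cell; a non-converged fit is retained with identifiability flags
  False and excluded from downstream metrics, which is what makes the
  per-metric cohort n differ.
* End-to-end runs are deterministic given the seed; output CSVs are
  byte-identical across repeated runs.

## Known limitations

* The hepatic index's exact transform is a convention; only ordinal
  statements (DR above AL, etc.) are transform-independent.
* ART alignment uses unweighted cell means; heavily unbalanced designs
  would call for a model-based alignment.
* Asymptotic CIs can be optimistic for k_a when absorption is fast
  relative to the sampling grid; the profile option is the remedy.
* The EGP derivative inherits interpolation error of order a few
  percent near sharp early transients; the 5-min exclusion absorbs
  most of it.
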