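# Methods

## Two-state life-course model

An individual's cardiometabolic history between ages 18 and 65 is a
continuous-time Markov process on {healthy, MetS} with age-dependent
incidence hazard λ(a) (healthy→MetS, per person-year) and recovery hazard
μ(a) (MetS→healthy). The state at age 18 is Bernoulli with the stratum's
entry prevalence p₀. Mortality is not modelled: below 65 Dutch mortality is
low, and differential mortality by MetS status and education cannot be
estimated from the source design; every simulated trajectory therefore
spans exactly 47 years. All quantities are computed separately for the four
sex × education strata (education dichotomized at 10 versus 16 schooling
years, a minimal labour-market qualification versus university).

## Rate estimation from two-wave data

The data design observes MetS status at two waves ~4 years apart, so what is
identified per 5-year age group is the interval transition probability, not
the hazard itself. Three estimators, per stratum:

* **Entry prevalence.** Logistic regression of baseline status on baseline
  age, evaluated at age 18; delta-method SE. Degenerate strata (all one
  status) fall back to an Agresti-style (x+0.5)/(n+1) proportion with a
  warning.
* **Interval probabilities.** Among the at-risk records (incidence: free of
  MetS at baseline; recovery: MetS at baseline), logistic regression of the
  transition indicator on 5-year age-group indicators plus the four
  modifiable factors. The age-group probability is the mean predicted
  probability over the group's at-risk records at their observed covariates
  (marginal standardization); its SE comes from the delta method,
  ∇ = mean(p̂(1−p̂)x), var = ∇ᵀ V ∇. Cells with zero (or only) transitions
  use the continuity-corrected proportion and are flagged; a non-converged
  or separated model downgrades the whole stratum to cell proportions with
  a warning.
* **Annualization.** Assuming a constant hazard within the interval,
  r = −ln(1−p)/Δt̄ with Δt̄ the cell-mean follow-up;
  SE_r = SE_p/((1−p)Δt̄).

Age groups are [18,20), [20,25), …, [60,65): 47 years is not divisible by
5 and the two-year remainder forms the first bin. Records are binned by
baseline age (event timing within the interval is unobserved). Curve
fitting uses bin midpoints.

**Identification caveat.** When both hazards are active, some transitions
reverse before the follow-up wave, so the annualized status-change rate is
attenuated relative to the generating hazard (for hazards of ~0.03/yr
against recovery of ~0.1/yr the attenuation is roughly 20–25%). This is a
property of two-wave status data, not of the estimator; parameter-recovery
tests therefore validate each hazard on cohorts with the reverse flow
switched off, where 1−e^(−rΔt) is exact. Applied results inherit the
attenuation as part of what "incidence rate" means under this design.

## Continuous-age parameterization

Incidence: three-parameter logistic L/(1+e^{−k(a−a₀)}) fitted by nonlinear
least squares with multi-start initialization (a₀ ∈ {30,40,50},
k ∈ {0.05,0.2}, L = 1.5·max rate; best residual wins; bounds keep L ≥ 0).
The asymptote is free; "logistic in age" fixes only the family. Recovery:
fourth-degree polynomial by OLS on (1,a,…,a⁴) at bin midpoints, with the
age axis rescaled by 50 to condition the normal equations. Evaluations are
clipped below at 0; a clipped region means hazard exactly 0 there. Fit
quality is reported as the mean absolute error at bin midpoints.

## Simulation by thinning

Waiting times are drawn by Lewis–Shedler thinning: candidates arrive as a
homogeneous Poisson process at rate B, an upper bound of the current
state's hazard over the remaining age range, and a candidate at age t is a
real transition with probability h(t)/B. B is the suffix maximum of the
curve on a 0.1-year grid times a 1.001 safety factor; a runtime guard
raises if any evaluation exceeds its bound. Thinning is exact for bounded
hazards — no discretization or quadrature error — which is why the
simulator can be tested against the forward equations at Monte-Carlo
precision.

Each individual owns a Philox counter-based stream keyed by (master seed,
stratum index, individual index). Trajectories are therefore reproducible,
independent of cohort size and simulation order, and shared across
scenarios: counterfactual contrasts are computed with common random
numbers, so an identity counterfactual reproduces the observed scenario
exactly.

## Summary measures

* **Life-course prevalence**: fraction whose trajectory ever contains a
  MetS episode (including those entering at 18 with MetS).
* **Mean age of onset**: mean age of the first healthy→MetS transition;
  individuals entering with MetS and individuals never affected are
  excluded.
* **Mean duration**: mean total MetS-years (censored at 65) among the
  ever-affected.

The analytic twins used in tests: ever-prevalence 1−S(65) with S′ = −λS,
S(18) = 1−p₀; onset density f(a) = λ(a)S(a) normalized on [18,65]; mean
duration (∫₁₈⁶⁵ P da)/(1−S(65)) — never-affected individuals contribute
zero occupancy, so the ratio equals the mean among experiencers. All five
forward quantities are integrated as one ODE system (LSODA, rtol 1e-8).

## Sensitivity transform: short episodes

Diagnostic blips — episodes shorter than 6 months (configurable) — are
treated as measurement fluctuation around the cut-offs: scanning forward
from 18, a short episode is absorbed into the nearest preceding episode
that meets the threshold (the pre-blip state persists); short episodes
before any valid one are absorbed forward into the first valid episode;
same-state neighbours are then coalesced. The transform is idempotent,
never increases episode count, conserves the 47-year span, and collapses a
trajectory with no valid episode to its majority state (with a warning).
Whether the source procedure absorbed mid-trajectory blips backward or
forward is not documented; backward absorption is this package's reading of
"the first valid state", and the forward rule is used only where no
preceding valid state exists.

## Counterfactuals and mediation

The counterfactual estimand: the low-education group's transition rates if
its distribution of chosen modifiable factors equalled the high-education
group's, all else fixed. Implemented as distribution-ratio reweighting —
each low-education at-risk record gets weight
w = Π_f P_high(category)/P_low(category) over the scenario's factors, and
the cell's counterfactual probability is the weighted mean of the fitted
model's predictions at observed covariates. This is marginal
standardization in closed form: deterministic, and exactly the identity
when the target equals the source distribution. Factor marginals are
computed on the stratum-wide at-risk set by default (a per-cell switch
exists; stratum-wide stabilizes weights in sparse cells). High-education
rates are untouched by construction. A category present in the low group
but absent in the target raises an error naming the category.

Factor importance is ranked by the difference method: the percentage
attenuation of the low-education coefficient in a logistic transition model
(education + age group) when the factor is added,
100·(β_without − β_with)/β_without, averaged over incidence and recovery.
Values can exceed 100% or be negative (inconsistent mediation) and are
reported as-is; an education coefficient below 1e-6 makes the percentage
undefined. No exposure–mediator interactions or natural direct/indirect
effect decomposition are attempted.

## Uncertainty

Sampling error in the estimated rates propagates by ensemble: each
replicate redraws every age-group rate from N(estimate, SE) clipped at 0
(hazards cannot be negative; the clip, rather than a renormalized truncated
normal, is the package's choice where the source is silent), perturbs the
entry prevalence the same way clipped to [0,1], refits the curves,
simulates a reduced cohort and recomputes the three measures per stratum.
The 2.5/97.5 empirical percentiles (linear interpolation) across replicates
form the interval. A replicate whose curve fit fails is redrawn once, then
skipped and counted. Intervals bracket an independent ensemble, so
containing the main-run point is a statistical expectation, not a
structural guarantee. The full-scale procedure is 1000 replicates × 50,000
individuals; tests and the desk-scale driver use 100 × 10,000, which leaves
Monte-Carlo noise visible in the interval endpoints but preserves coverage.

## Synthetic cohort: what it does and does not emulate

The generator reproduces the source design's structure: n = 93,249 (58.9%
female, education split 50/50 where the source does not publish a split),
baseline ages uniform on [18,61], follow-up gap N(4,1) truncated to [1,8]
years, the published modifiable-factor distributions by education
(renormalized — the published high-education alcohol column sums to 111.8%,
beyond rounding, so intent is ambiguous and uniform renormalization is a
flagged guess), and logistic/log-linear ground-truth models for baseline
prevalence and the two hazards. Between waves each person follows the exact
time-homogeneous two-state solution at hazards frozen at baseline age, so
every estimand has a closed-form truth. Hazard-model intercepts were set
once so the synthetic world matches published magnitudes (~14% baseline
MetS; life-course prevalences ≈0.40–0.64; onsets ≈44–45; durations
≈8–11 years).

Not emulated: missing data and multiple imputation (the synthetic cohort is
complete; the source imputed with chained equations), the three-generation
family structure, intermediate education levels, measurement error beyond
the classifier's needs, and within-interval ageing of hazards. Passing
tests therefore demonstrate correctness of the estimators and simulator
under the stated model, not robustness to missingness or hazard
misspecification. One visible consequence of the default calibration: the
synthetic onset gaps are small (±0.5 years), so percent reductions of the
onset gap are unstable in the synthetic world even where prevalence- and
duration-gap reductions are well behaved.

## MetS classification

NCEP-ATPIII, ≥3 of 5: waist ≥102 cm (men) / ≥88 cm (women); SBP ≥130 or
DBP ≥85 mmHg or antihypertensive medication; triglycerides ≥1.7 mmol/L or
triglyceride-lowering medication; HDL <1.0 (men) / <1.3 (women) mmol/L or
lipid-lowering medication; fasting glucose ≥5.6 mmol/L or type-2 diabetes
diagnosis or glucose-lowering medication. Concentrations are carried in
mmol/L. The classifier is monotone in the criterion indicators and rejects
non-positive or non-finite measurements.

## Numerical choices and problem sizes

Thinning grid 0.1 years with a 1.001 bound safety factor; forward equations
at rtol 1e-8/atol 1e-12; logistic fits bounded L ∈ [0,10], k ∈ [−5,5];
percentile convention linear interpolation; reported decimals rounded
half-away-from-zero in decimal arithmetic (matching how one-decimal
published tables combine: (26.8+28.3)/2 → 27.6). Default problem sizes —
cohort 93,249; 50,000 simulated life courses per stratum in the observed
run; 25,000 per group per counterfactual scenario; ensemble 100 × 10,000 —
were chosen so the full analysis runs on a laptop in minutes; every size is
a flag or config field, and the full-scale settings (125,000 per group;
1000 × 50,000) are one option away.
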