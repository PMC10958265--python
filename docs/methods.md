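# Methods

## The model

`needsmsm` models a person's movement among three states in continuous
time: **1** unmet healthcare needs, **2** met healthcare needs, and
**3** dead (absorbing).  Four transitions are estimable: 1→2
(remission out of unmet needs), 2→1 (onset of unmet needs), 1→3 and
2→3 (death from either living state).  The process is Markov with age
as the time scale, and each transition intensity is log-linear in age
(Gompertz) and in covariates:

    q_rs(a, z) = exp( β0_rs + ξ_rs (a − 60) + β_rs' z ),

with `z = (female, edu_mid, edu_high, multi_P, multi_PM)` relative to
the reference profile male / low education / no multimorbidity.  `β0`
is the log baseline intensity per year at age 60 and the reference
profile; `ξ` is the age slope per year of age (exp(ξ) is the per-year
hazard ratio for age); `β` are log hazard ratios.  Age is centred at 60
purely for numerical conditioning.  Setting every `ξ = 0` gives the
time-homogeneous model; the same code path serves both the
covariate-HR view and the age-varying-intensity view of the model.

The proportional (log-linear) action of covariates is an assumption of
this package: transition-specific hazard ratios are the quantities the
model reports, so multiplicative covariate effects are the natural
parameterisation.

## Likelihood for interval-censored panel data

Living states are observed only at interview waves; deaths carry an
exact (or imputed) age; a subject can leave observation alive.  Under
the Markov assumption, consecutive observation pairs are conditionally
independent given the earlier state, and each pair `(r at a0) → (· at a1)`
contributes:

* living endpoint `s`: `P_rs(a0, a1)`;
* exactly dated death at `a1`: `Σ_s P_rs(a0, a1) q_s3(a1)` — the death
  time is known, the living state just before death is not;
* alive with unknown state (code 0, terminal only): `Σ_s P_rs(a0, a1)`;
* death somewhere in the interval (undated deaths, or the
  `death_convention: interval` option): `P_r3(a0, a1)`.

`P(a0, a1)` is a product of matrix exponentials over bands of width at
most `h_lik` (default 1.0 year) with the generator frozen at each band's
**midpoint** age, giving second-order accuracy in the band width; when
the model is homogeneous a single exact exponential is used.  Because
death is absorbing the 3×3 exponential reduces to a closed-form 2×2
exponential of the living-state block, written in the traceless
decomposition `exp(tA) = e^{tr·t/2}(cosh Δ · I + sinch Δ · M)`; both
exponents in `e^{tr·t/2±Δ}` are non-positive, so the evaluation cannot
overflow, and the Δ→0 (coincident-eigenvalue) limit is handled by
series.  The general 3×3 path through `scipy.linalg.expm` is kept as an
independent cross-check and is what `expm_probability` exposes.

Deaths with a masked date are either imputed first (an age drawn
uniformly inside the reporting interval, the default pipeline) or left
interval-censored.  Which convention the likelihood applies to dated
deaths is configurable (`exact` by default): treating dated deaths as
exact uses the death-density contribution above, which is the
appropriate likelihood when vital-status follow-up records dates.

## Estimation

The negative log-likelihood is minimised by L-BFGS-B within generous
parameter boxes (`β0 ∈ [−14, 4]`, `ξ ∈ [−2, 2]`, `β ∈ [−8, 8]`, all on
the log scale) followed by damped Newton polishing.  Gradients are
exact: a reverse-mode pass propagates the adjoint of the living-state
occupancy vector backwards through the band products, using the
closed-form derivative of the 2×2 exponential with respect to its four
rates; the cost is a small multiple of one likelihood evaluation,
independent of the parameter count.  The Hessian is a central finite
difference of this gradient and doubles as the basis of the reported
covariance matrix (inverse Hessian).

Convergence is declared on the **Newton decrement** — the predicted
remaining improvement of the negative log-likelihood, restricted to
coordinates free of their bounds — falling below 1e−5.  An absolute
gradient-norm criterion is not meaningful here: the age-slope
coordinates are so steeply scaled that double-precision function values
limit the attainable gradient norm to ~1e−3 even at machine-precision
optima.  A parameter pinned at its box bound (typically a covariate on
the rare unmet→death transition in small samples) is a legitimate
boundary optimum; the KKT-projected gradient is used for the reported
gradient norm, and the positive-definiteness check for `converged`
applies to the free coordinates.  Wald standard errors for bound-pinned
parameters are not trustworthy and are typically enormous, which makes
the intervals conservative rather than anti-conservative in the
recovery experiments.

Starting values are crude occurrence/exposure rates (pair counts over
person-years by origin state) on the log scale with covariate
coefficients at zero; optional seeded multi-start guards against local
optima.  The 95% intervals use the 1.96 normal quantile throughout, and
`AIC = −2loglik + 2k` holds as an exact identity of the fit object.

The full specification — age slope plus all five covariates on each of
the four transitions — has `k = 4 × (1 + 1 + 5) = 28` free parameters.
"Unadjusted" hazard ratios are produced by refitting single-covariate
specifications (the age row from the covariate-free Gompertz model)
through the same fitting path.

## Life expectancies

State occupancy from a starting age is accumulated by forward products
of band exponentials (same midpoint freezing) on a grid of step `h`
(default 0.5 years, distinct from `h_lik`) up to a maximum age of 115
years, where the distribution is truncated.  State-specific residual
life expectancies `e_rs` are trapezoid-rule integrals of occupancy over
age.  Marginal LEs weight `e_rs` by a model-based initial living-state
distribution — a logistic regression of baseline state on baseline age
(covariates optional), evaluated at the starting age; an explicit
`(π1, π2)` pair can be supplied instead.  Total LE is the sum of the
two marginals and %UMLE is `100 · marginal_unmet / TLE`; these
identities hold by construction, not by separate estimation.

Confidence intervals are simulation-based: B (default 1000) parameter
vectors are drawn from N(θ̂, vcov), clipped to the admissible parameter
box, every LE quantity is recomputed per draw — vectorised across
draws through the same 2×2 band engine — and 2.5/97.5 percentile
intervals are reported.  The initial-state distribution is held at its
point estimate, so the intervals reflect intensity-parameter
uncertainty only.  A covariance matrix that fails positive
semi-definiteness is rejected unless `repair_vcov=True` clips its
spectrum at zero.

In LE estimation multimorbidity is treated as fixed at baseline
(piecewise-constant covariates cannot vary over the occupancy forward
integration), matching the fitting option that uses time-fixed
covariates.

## Synthetic cohorts

The generator emulates a three-wave ageing-cohort panel:

* **Subjects.** 18 075 by default; baseline ages uniform on 45–85.
* **Covariates.** Female 50.9%; education low/middle/high 67/23/10%;
  multimorbidity none/P/PM 46.1/45.6/8.3%.  Covariates are drawn
  independently of each other and of age; an optional flag lets
  multimorbidity progress none→P→PM between waves with configurable
  per-wave probabilities.
* **Baseline state.** logit P(unmet) = −2.0 + 0.01·(age − 60), i.e.
  about 12% unmet at age 60, rising slowly with age.
* **Trajectories.** Exact competing-risks simulation with intensities
  frozen over 0.01-year bands: within a band the waiting time is
  exponential in the total exit rate, the destination is drawn
  proportionally to the cause-specific rates (equivalent to the minimum
  of per-transition exponentials), and multiple events within one band
  are handled by redrawing from the event time.
* **Observation.** Waves at 0, 2 and 4 years with ±0.25-year uniform
  jitter (follow-up offsets snapped to the 0.01-year simulation grid so
  recorded ages and recorded states refer to the same instant); living
  states recorded at attended waves; deaths reported at the next
  attended wave with their exact age, except that with probability 0.30
  the date is masked and only vital status is kept; per-wave dropout
  probability 0.12 (monotone: once gone, gone); probability 0.05 that a
  contact yields vital status only (a terminal state-0 record).

The generating intensities default to baselines (per year, age 60,
reference profile) of 0.81 for 1→2, 0.092 for 2→1, 0.0067 for 1→3 and
0.0075 for 2→3, with age slopes 0.010, 0, 0.049 and 0.104 and covariate
log hazard ratios echoing effect sizes typical of reported
needs-transition analyses (e.g. physical multimorbidity HR 1.85 into
unmet needs, 0.58 out of it; PM 1.45/0.64; female 1.28 into unmet;
per-year age HRs 1.05/1.11 on the two death transitions).  The
baselines were calibrated once, from the closed-form two-state
transition law, so that the implied 2-year transition probabilities at
typical covariate mixes are ≈0.78 out of unmet needs, ≈0.09 into them
and ≈0.01 to death at age 60 — the magnitudes such cohort analyses
print — and they are not tuned afterwards.

What the generator does **not** emulate: survey weights and multistage
sampling, household clustering, informative (health-dependent) dropout,
misclassification of the needs state, covariate measurement error, and
age-dependent covariate prevalence (available only through the
progression flag).  Passing tests therefore demonstrate correctness of
the estimation machinery under the model's own assumptions, not
robustness to the ways real survey data violate them.

## Numerical choices and problem sizes

* Likelihood banding `h_lik = 1.0` year; LE grid `h = 0.5` years;
  max-age 115; all configurable.  Banding and integration errors are
  O(h²) (verified by h-halving tests).
* Simulation band 0.01 years — exact up to the band-freezing of the
  Gompertz age dependence within 0.01 years.
* Likelihood floor 1e−300 before taking logs; a structurally impossible
  pair reports an infinite −2loglik with the offending subject named in
  a warning.  Log intensities are capped at 200 and the gradient's
  adjoint is floored far above the log floor so optimisation remains
  finite-valued everywhere in the admissible box.
* The test suite runs its recovery experiment at 18 replicates of
  2 000 subjects and its CI-coverage experiment at 25 replicates of 500
  subjects; the acceptance script fits the full 18 075-subject study
  once and adds an 8-replicate recovery run.  These sizes were chosen
  to keep the whole suite within a few minutes while leaving the
  binomial noise of the coverage checks well below the margins asserted.
* The death-date imputation distribution is uniform on the reporting
  interval; nothing in the observation scheme identifies a better
  within-interval law, and uniformity is the standard convention.

## Known limitations

* Wald intervals (and hence the simulation CIs seeded by the Hessian)
  are first-order; with very few events on a transition the likelihood
  is far from quadratic and the MLE may sit on the parameter box.
* Marginal-LE uncertainty ignores the sampling error of the baseline
  logistic model.
* The PM-multimorbidity grouping rule ("mixed": ≥2 conditions in total
  with at least one physical and one mental) is one reading of the
  standard convention; a strict variant (≥2 physical and ≥2 mental) is
  provided as a switch because the field's usage is not uniform.
  Mental-only condition profiles fall into "none" under both rules.
* The condition checklist ships with a 14-item default list (12
  physical, 2 mental) plus CES-D-based depression as a 15th mental
  condition; the list and its physical/mental split are configurable.
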