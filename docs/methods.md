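# Methods

`sedmix` implements a population pharmacokinetic–pharmacodynamic (PK-PD)
analysis of a single intravenous midazolam bolus (0.05 mg/kg) in sedated
children, of the kind performed with Monolix-class tools: a two-compartment
mixed-effects PK model estimated by SAEM, a sequential effect-compartment
Imax stage for the Bispectral Index (BIS), hysteresis analysis, and
simulation-based diagnostics. This note records the models, the assumptions
behind the synthetic cohorts, the numerical choices, and the known limits of
what the test suite demonstrates.

## Units

Time in minutes, amounts in ng, volumes in mL, clearances and flows in
mL/min, concentrations in ng/mL, BIS on its native 0–100 scale. With these
units the published pediatric parameter set is usable verbatim
(Cl 0.48 mL/min, V1 23.59 mL, Q 5091.62 mL/min, V2 6792.42 mL; E0 57.63,
Imax 0.088, IC50 13.57 ng/mL). A 0.05 mg/kg dose for a 20 kg child is
1 mg = 10⁶ ng.

## Structural models

One- and two-compartment IV bolus disposition in closed form. The
two-compartment solution is the biexponential
`C(t) = (D/V1)(A e^{-αt} + B e^{-βt})` with hybrid rates computed without
cancellation (`α` from the stabilized quadratic, `β = k10·k21/α`). The
biophase (effect-site) concentration solves `dCe/dt = ke0 (C − Ce)`,
`Ce(0)=0`, as an explicit sum of exponentials; when `ke0` falls within
relative 10⁻⁶ of a hybrid rate the confluent limit `t·e^{-λt}` replaces the
unstable quotient. "Zero-order insertion" is interpreted as an instantaneous
bolus (the study gave a single IV push and reports no infusion duration); a
zero-order infusion of configurable duration is provided as an option, with
its own closed-form plasma and biophase profiles. All closed forms are
cross-checked in the tests against a Radau integration of the mass-balance
ODEs at relative tolerance 10⁻¹¹ (agreement ≤10⁻⁸ demanded, ≈10⁻¹¹
achieved).

No ke0 estimate is available for this population; the package default for simulation is
ke0 = 0.1 min⁻¹ (biophase equilibration half-time ≈7 min, inside the 5–120
min observation window), configurable everywhere.

## Population model and SAEM

Between-subject variability is lognormal, `θ_ij = θ_pj e^{η_ij}` with
`η ~ N(0, ω_j²)`; parameters bounded in (0,1) (Imax) use a logit-normal
law. Residual error is additive, proportional, or combined. The reported
correlation formula for two random effects is implemented as the standard
`R = cov/(ω₁ω₂)` (the printed variant is not a valid correlation and is
treated as a typographical corruption). Correlated random effects are
available behind a `full_covariance` flag; the default is diagonal, matching
a report that lists only SDs.

SAEM alternates a Metropolis–Hastings E step on the transformed individual
parameters with stochastic-approximation smoothing of the complete-data
sufficient statistics (step 1 for the exploratory phase, `1/(k−K1)` after)
and closed-form M updates. Defaults: 2 chains, 300 exploratory + 200
smoothing iterations, variances allowed to shrink by at most 5% per
exploratory iteration and floored (ω ≥ 10⁻³), seeds mandatory.

Three MH kernels run per iteration, and the combination matters for sparse
or weakly identifying designs:

1. a full-vector independence proposal from the current population law;
2. componentwise *independence* refreshment (one coordinate redrawn from
   the population law) — this keeps the chain dispersed at prior width in
   directions the subject's data do not constrain, which a shared-scale
   random walk systematically fails to do;
3. componentwise random walks with acceptance-rate adaptation (target 35%)
   plus a joint adaptive random walk whose proposal covariance is learned
   from the across-subject sample cloud (scaled 2.38/√p) — this moves along
   curved ridges such as the V1+V2 (total volume) trade-off that
   single-coordinate moves cannot traverse.

Chains start at the per-subject posterior modes and are re-localized once
mid-exploration; parameters declared without between-subject variability are
sampled with a small annealed auxiliary spread so their fixed effects can
still move.

The marginal likelihood (OFV = −2 log L) uses per-subject importance
sampling with a normal proposal centred at the empirical Bayes mode and
spread 1.5× the population SD, reporting a Monte-Carlo SE; it is verified
against Gauss–Hermite quadrature on a one-dimensional lognormal toy model.
Information criteria: `AIC = OFV + 2P`, `BIC = OFV + P ln N_subjects`, and
the hybrid `BICc = OFV + P_subject ln N_subjects + P_residual ln N_obs`
(subject-level parameters are the fixed effects and random-effect SDs;
residual-level parameters the error magnitudes). RSE% uses the BHHH
(score outer-product) estimator on the importance-sampled per-subject
log-likelihood contributions with common random numbers — chosen over a
linearized Fisher information because it needs no model linearization and
inherits the verified likelihood machinery.

## Sequential PD stage

Individual PK parameters are fixed at their empirical Bayes estimates; the
BIS rows are then fit with `E = E0 (1 − Imax·Ce/(Ce+IC50))` (plain Imax) or
its Hill generalization, lognormal variability on E0 and IC50, logit-normal
on Imax, additive residual error. E0 is a fitted parameter, not the first
observed BIS. ke0 is either fixed (known or from a hysteresis collapse) or
estimated as a fixed effect; IC50 carries concentration units (ng/mL). The
Hill midpoint identity `E(IC50) = E0(1−Imax/2)` holds for every exponent,
and γ=1 reproduces the plain model to machine precision.

## Hysteresis

The loop analysis plots effect against exposure in time order and measures
the signed shoelace area of the closed polygon. Two geometric points are
easy to get wrong:

* A loop only closes when exposure **rises and falls** inside the
  observation window. After an instantaneous bolus, plasma concentration
  only declines over 5–120 min, so the raw BIS-vs-concentration polygon is
  dominated by the closing chord. The study's *observed mean* concentration
  rose until ≈30 min before declining (sparse-sampling and assay effects),
  which is what makes its published loop close; the package's hysteresis
  demonstration reproduces that shape with a 30-min zero-order input.
* BIS is an *inhibitory* readout: it falls as exposure rises. On raw BIS
  coordinates a textbook biophase lag traces a **clockwise** polygon — the
  classical "counterclockwise = effect lags" rule refers to the response
  scale. Direction is therefore classified after orienting the effect axis
  by the sign of the effect–exposure association, so a distributional lag is
  reported counterclockwise and an acute-tolerance (proteresis) trajectory
  clockwise regardless of readout polarity. The raw signed area is reported
  unmodified. Loops below 5% of the bounding-box area are classified "none"
  (on a ~10-point grid an immediate effect still leaves ≈2% of box area
  from chord discretisation of the curved exposure-response relation).

The collapse scans ke0 over a log grid, refines with bounded scalar
minimisation of |area|, warns when asked to collapse a clockwise loop (a
biophase cannot produce one), and never returns a collapse worse than the
no-biophase limit. In a noise-perturbed recovery at ke0 = 0.1 min⁻¹ the
collapse returns ke0* within 1% and removes >99.99% of the loop area.

The demonstration scenario uses Cl 40, V1 1000, Q 50, V2 3000 (mL, mL/min)
with Imax 0.3 and IC50 300 ng/mL: under the published pediatric values the
typical concentration varies by barely ~1 ng/mL across the sampling grid
(see "Identifiability", below), which makes the loop area numerically
degenerate; the demonstration needs visible exposure dynamics to be a
meaningful test of the machinery.

## Diagnostics

NPDE: `nsim` replicate cohorts are simulated under the model with the
original design; per subject, observed and simulated vectors are
decorrelated by the inverse Cholesky factor of the empirical simulated
covariance (variance-only fallback with a logged warning if singular); the
rank of each decorrelated observation among its decorrelated simulations,
with seeded uniform jitter inside ties, maps through Φ⁻¹. pc-VPC:
observations and simulations are rescaled by `median(bin population
prediction)/row population prediction`; bins default to edges midway between
the design times; observed 5th/50th/95th percentiles are compared with 95%
confidence bands of the same percentiles across replicates, and the
out-of-band fraction is reported per run. Observed-vs-IPRED reports the
trend line and the fraction of points inside the 90% prediction interval
implied by the residual-error model. All diagnostics are deterministic
given (dataset, model, seed).

## Synthetic cohorts

The generator emulates the study design: three age strata (26 preschoolers
2–5 y, 40 schoolchildren 6–12 y, 31 adolescents 13–17 y), one 0.05 mg/kg
bolus at t=0, three sampling times per subject drawn uniformly without
replacement from {5,10,15,20,25,30,45,60,90,120} min, and a BIS reading at
every blood draw. Concentrations follow the two-compartment model with the
published fixed effects and random-effect SDs and 20% proportional error;
BIS follows the effect-compartment Imax model with the published PD values,
ke0 = 0.1 min⁻¹ and additive SD 4, truncated to [0,100]. Reported pediatric estimates of this kind come
without residual-error magnitudes or body weights (only BMI): the error
magnitudes above and the weight law (lognormal around age-typical medians
16/32/55 kg, CV 15%) are package assumptions, configurable on the design.
Concentrations under 10 ng/mL (the assay's validated lower limit) are kept
in the dataset but flagged MDV=1 and excluded from likelihoods by default.

What the generator does **not** emulate: assay bias of dried-blood-spot
sampling, age- or sex-dependent parameters (the generating law is identical
across strata apart from weight), adverse events, concomitant medication,
and any within-subject time-varying physiology. Passing recovery tests
therefore show that the estimator is calibrated for data that follow the
model — not that the model is correct for real children.

## Calibration experiments and problem sizes

The experiments behind `scripts/acceptance.py` and
`tests/test_acceptance.py` (identical code paths):

* **PK recovery** — 500 subjects, fixed 20 kg weight (exact 1 mg bolus),
  all 10 grid times observed, 20% proportional error, published values as
  truth; 5 seeded replicates; no quantification floor (the experiment
  probes estimator calibration, and an LLOQ would selectively censor the
  most informative high-clearance subjects).
* **PD recovery** — 200 subjects, BIS at all grid times, published PD truth,
  ke0 known, additive SD 4; individual PK fixed at simulation truth;
  3 replicates.
* **Model selection** — 20 replicates × 100 subjects simulated from a
  two-compartment law with both phases visible on the grid (Cl 40, V1 1000,
  Q 50, V2 3000; ω 0.3; 15% proportional error), 1- vs 2-compartment fits
  compared by BIC. Under the published values the distribution phase
  (α ≈ 216 min⁻¹) is finished before the first 5-min sample, so such data
  cannot distinguish the models for information-theoretic reasons unrelated
  to the estimator; the selection experiment needs a regime where the extra
  compartment is actually expressed in the observable window.
* **Diagnostics calibration** — the default 97-subject sparse cohort under
  the true model (NPDE moments and tail fractions; pc-VPC band coverage).

Recovery fits initialize at one-significant-figure roundings of the
generating values (fixed effects *and* random-effect SDs: Cl 0.5, V1 20,
Q 5000, V2 7000, ω {3,3,2,1}; E0 60, Imax 0.1, IC50 10, ω {0.2,0.8,3}):
the experiments measure estimator calibration, not global-search
robustness. A data-driven initializer is the right choice for real data.

## Identifiability of the published regime

The published parameter set implies α ≈ 216 min⁻¹ (distribution complete
within seconds) and β ≈ 7·10⁻⁵ min⁻¹ (terminal half-life ≈ 7000 min), so
the typical concentration profile is essentially **flat** at
`dose/(V1+V2)` ≈ 147 ng/mL across 5–120 min. Consequences, all visible in
the package's own outputs:

* V1 and Q are individually unidentifiable (only their combination with V2
  shapes the curve after the first sample); the total volume — hence V2 —
  is well identified.
* Clearance is informed only by the upper tail of its lognormal
  distribution (the few-percent of subjects whose decay exceeds the 20%
  noise floor over 115 min). The importance-sampled OFV changes by only
  tens of units (of ≈50,000) when the population Cl moves across a 2.5×
  range, and the per-dataset estimates scatter accordingly. This matches
  the source table, which reports RSE ≈ 148% for Cl, 138% for V1 and 147%
  for Q, against 16% for V2.
* The sampler itself is verified calibrated: with the population parameters
  fixed at the generating values, the long-run E-step reproduces the
  random-effect mean and SD to within 1%; on regimes where both phases are
  observable the same estimator recovers every parameter accurately, and
  noise-free data are recovered to <0.1%.

The practical reading: from this design one can estimate the total volume
of distribution and the PD parameters well, while clearance-type parameters
carry order-of-magnitude uncertainty — a caveat inherited by any dosing
conclusions drawn from such a study.

## Known limitations

* Left-censored (BLQ) observations are excluded, not modelled (no M3-style
  censored likelihood).
* RSE by BHHH assumes per-subject score independence; no bootstrap.
* The hysteresis direction test requires a rise-and-fall exposure profile;
  it will return "none" (correctly, but uninformatively) on strictly
  monotone data.
* Covariate (age, sex, weight) models on the PK/PD parameters are out of
  scope; covariates travel with the dataset for stratified summaries only.
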