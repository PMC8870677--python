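# Methods

## Scope and data

The package models a *virtual cohort*: the eight treatment arms of the four
randomized Ra-223 trials in mCRPC (labelled A–D), shipped as a transcribed
CSV fixture (`alphalq/data/table2_arms.csv`) holding per-arm activity
(kBq/kg and MBq/cycle), cycle counts, the fraction receiving EBRT, and the
two outcome counts (two-year survivors; grade ≥ 2 neutropenia events, not
reported by study D). No patient-level data exist; every analysis is
arm-level. A second fixture (`reference_eqd2_rn.csv`) carries the published
per-arm radionuclide EQD2 values used for exact table reproduction.

## Dose model

### EBRT

Standard LQ: `BED = D(1 + (D/n_f)/(αβ))`, `EQD2 = BED/(1 + d/αβ)`.
Defaults (config-overridable): α/β = 10 Gy (tumour/acute), d = 2 Gy per
reference fraction. A schedule already delivered in 2 Gy fractions is its
own EQD2, which the tests verify as a round-trip property.

### Ra-223 mixture

The alpha course is treated as a permanent-implant (exponentially decaying
dose-rate) LQ exposure generalised to the seven-member decay chain, all
members sharing one effective decay constant λ and one residence time
(secular equilibrium with the parent; the rare Po-215 beta branch is
dropped and recorded as an omitted branch on the chain object). The mixture
double sum over nuclide pairs collapses algebraically to the square of the
summed dose rates; both the closed form and the explicit nested-loop form
are implemented and asserted equal to 1e-12 relative, because the closed
form is the only reading that reduces to the standard single-nuclide
permanent-implant BED. Sublethal-damage repair enters through μ = 1.4 h⁻¹,
assumed independent of dose level. The alpha linear term is weighted by
RBE_max = RBE_exp + (d/αβ)(RBE_exp² − 1)/RBE_exp = 5.96 at the defaults
(RBE_exp = 5 for alphas, RBE 1 for photons/electrons). By default the
global RBE_max weights the whole chain (its dose is alpha-dominated); an
emission-resolved option weights beta/gamma members by the photon RBE
instead.

Units: per-nuclide dose coefficients are mGy/MBq; conversion to Gy happens
once at the model boundary, before the quadratic term is formed (the
quadratic term is unit-sensitive).

λ is stored as a rate (h⁻¹) with helpers converting to/from half-life. The
default is the Ra-223 physical value ln 2 / (11.43 d) = 2.527e-3 h⁻¹: an
effective (biological + physical) value would be larger, but no effective
value is identifiable from arm-level data, and λ only enters the small
quadratic term. Residence time uses the single-phase convention
τ = uptake_fraction/λ; two-phase bone kinetics are out of scope.

### Calibrated activity pathway

The published per-arm EQD2_RN values grow super-linearly in administered
activity in a way that cannot be pinned to specific (unpublished) dose
coefficients and kinetics. The package therefore also offers an *effective*
re-parameterisation: per-cycle EQD2_RN = c₁A + c₂A², mirroring the
linear + quadratic structure of the mixture BED with the unknowns absorbed
into two constants. Back-solved exactly from the 25 and 50 kBq/kg arms
(c₁ = 0.396, c₂ = 0.0024), it predicts the 80 kBq/kg arm's per-cycle EQD2
within 0.15 Gy of the published value and the 55 kBq/kg arm within
0.05 Gy/cycle. Dose-table reproduction itself uses the published per-arm
values directly (the `reference` pathway), with the calibration exercised
as a consistency check.

### Combination and rounding

EQD2_TOT = EQD2_RN + f·EQD2_EBRT per arm. `f` is the *printed percentage*
of the arm receiving EBRT; the printed patient count is stored alongside
(count/n can differ from the percentage after rounding, e.g. 98/614 =
15.96 % vs the printed 16 %), but the percentage is what reproduces every
published table cell, so it is the default. All internal math is full
precision; printed tables round half-up to one decimal at report time only.
Study D's "up to 6 cycles" is encoded as 6 cycles for all patients; its
printed 4.125 MBq/cycle overrides the 70 kg reference-weight conversion.

## Outcome models

Arm-level events/n at dose EQD2_TOT (taken from the report-rounded dose
table, since published fits were run on the printed values):

* **fixed** — grouped-binomial logistic GLM (statsmodels). "Weighting by
  sample size" is likelihood-exact here: grouped counts equal the expanded
  per-patient Bernoulli fit, which the tests verify to 1e-8.
* **random_intercept** — binomial-normal mixed model
  `logit p_i = β₀ + β₁ dose_i + u_i`, `u_i ~ N(0, τ²)`, the standard
  mixed-effects logistic meta-regression for arm-level proportions. The
  marginal likelihood is integrated by **adaptive Gauss–Hermite
  quadrature** (25 nodes; per-group conditional mode by damped Newton with
  analytic derivatives, then re-centred/re-scaled nodes) and maximised by
  Nelder–Mead from three τ starting values. Non-adaptive quadrature is
  *not* adequate here: the n = 614 arm makes the integrand far sharper than
  the prior scale. Grouping defaults to one group per arm (τ is residual
  inter-arm heterogeneity / overdispersion); a coarser grouping, e.g. per
  study, can be passed.

Wald inference throughout: SEs from the fixed-effect block of the inverse
observed information over (β₀, β₁, log τ) at the MLE (falling back to the
fixed-τ information if τ sits on the boundary), z = β/SE, two-sided normal
p, 0.05 threshold, no multiplicity correction. The random-intercept variant
is the **reference** for reproducing the published coefficient table — on
the toxicity endpoint, with three zero-event arms and substantial
heterogeneity (τ̂ ≈ 1.14), the fixed GLM gives materially different
coefficients, while the mixed model matches an independent mixed-model
implementation (R metafor/lme4) to four decimals; both variants are always
reported. Degenerate data (all-zero events, complete separation) are
flagged `converged=False` with diagnostics rather than corrected or
silently returned; prediction refuses such fits.

Prediction curves transform the delta-method normal band on the linear
predictor through the inverse logit, so bands stay in (0, 1) and contain
the point estimate by construction.

`compare_schedule_effect` tabulates slope inference across EBRT scenarios;
interpretation is left to the reader (with identical RN doses and only the
small f-weighted EBRT term changing, the three scenarios give nearly
identical slopes).

## Synthetic data

* **Lesion dosimetry** emulates the kind of planar-image MIRD evaluation
  the cohort's absorbed doses derive from: 24 lesions over 9 patients by
  default, masses log-uniform on 1–60 g, dose-per-activity a·e^(−b·mass)
  with a = 2.0 Gy/MBq, b = 0.05 g⁻¹ and multiplicative lognormal noise
  (CV 0.2). The source lesion table was never published; these defaults
  are placeholders with realistic orders of magnitude, set once. The
  generator does not emulate intra-patient mass correlation, imaging
  noise structure, or organ-level dosimetry — passing tests show the
  fit/generate loop is self-consistent, not that real lesion data follow
  this law.
* **Outcomes** are Binomial(n, expit(β₀ + β₁·dose)) per arm from a known
  truth. Recovery experiments inflate arm sizes ×100 because the real
  sizes leave wide sampling error on a two-parameter fit; the real-size
  design is also exercised to show that wide CIs there are expected
  behaviour.

All generators are pure functions of (parameters, seed).

## Numerical choices and problem sizes

* Quadrature: 25 adaptive Gauss–Hermite nodes (agrees with a 100-node
  reference to well below reporting precision); Newton mode search capped
  at 100 damped steps, tolerance 1e-12.
* Optimiser: Nelder–Mead, xatol 1e-9 / fatol 1e-11, three starts
  (τ₀ ∈ {0.2, 0.6, 1.5}); best likelihood wins.
* Hessians by central differences with parameter-scaled steps.
* The λ→0 closed-form limit (BED → n_c·RBE_max·D_tot) is validated at
  λ = 1e-9 h⁻¹ to 1e-6 relative.
* Recovery runs default to 200 replicates at ×100 arm-size inflation
  (a few seconds with the fixed-variant GLM); the pipeline's recovery
  stage is configurable.

## Known limitations

* Everything is arm-level; f-weighting of the EBRT dose is a population
  average, not patient assignment.
* The effective decay constant and per-nuclide dose coefficients are not
  identifiable from the published arm data; the mechanistic RN pathway is
  therefore exact only up to user-supplied coefficients, and the
  calibrated pathway is an effective description.
* Kaplan–Meier-extracted survival proportions (studies C, D) are treated
  as binomial despite censoring; the extraction mode is recorded per arm.
* The per-arm random intercept absorbs heterogeneity but cannot separate
  study-level from arm-level sources with only eight arms.
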