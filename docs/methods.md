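# Methods

## Mortality model

Adult mortality is modelled on the time scale t = calendar age − 15 years.
The baseline hazard is either Gompertz, h(t) = α·e^{βt}, or
Gompertz–Makeham, h(t) = α₁ + α₂·e^{βt}, with α (α₂) the level of senescent
mortality at entry, β (per year) the rate of its exponential increase, and
α₁ (per year) a constant age-independent component. Defining the model on
t ≥ 0 conditions implicitly on survival to age 15, so the left truncation of
an adults-only skeletal sample is exact without an extra conditioning term.
Whether a published fit measures age from birth or from entry is often left
unstated; the entry-age-15 origin is this package's convention, and α-level
parameters are therefore "hazard at age 15", not at birth.

A binary covariate enters proportionally: h_i(t) = h(t)·e^{x_i ρ} with
x_i ∈ {0, 1} (0 = male, 1 = female here, but the code is generic). The PH
assumption means the covariate multiplies mortality identically at every
age; age-specific (non-proportional) differences are invisible to ρ by
construction, a known limitation of this specification.

## Likelihood and estimation

Deaths are treated as exactly observed at their point age estimate — no
right censoring (everyone in a cemetery died) and no interval uncertainty
(point estimates are taken at face value, mirroring common practice with
transition-analysis point ages). Each individual contributes
ln f_i = x_i ρ + ln h(t_i) − e^{x_i ρ} H(t_i), with
H(t) = α₁t + (α₂/β)(e^{βt} − 1) the cumulative hazard. For |β| < 1e−8 the
(e^{βt} − 1)/β factor switches to its series limit t, avoiding catastrophic
cancellation; the constant-hazard limit H = (α₁+α₂)t is exact there to
first order and the switch point is far below any β of practical interest.

Maximisation is by L-BFGS-B on an unconstrained reparameterisation: log for
α₂ (α) and β, softplus (with a 1e−12 floor) for α₁ so the Makeham term can
sit essentially on its zero boundary, ρ untransformed. Initials are
moment-based (hazard components scaled to the crude death rate 1/mean(t),
β₀ = 0.06) with 10 multistarts by default, jittered 20% on the transformed
scale from a fixed seed (20250409); the best optimum is kept and
non-convergence is flagged on the result rather than raised.

Standard errors come from the inverse of a central-finite-difference Hessian
of the log-likelihood in the *original* parameterisation (relative step
1e−3). A singular or indefinite Hessian yields missing standard errors with
a warning. Wald intervals for ρ are symmetric on its own scale; positive
baseline parameters are intervalled on the log scale and back-transformed
(delta method), with the exponent clamped at 500 because a boundary α₁ has
enormous relative uncertainty. Profile-likelihood intervals for ρ (bisection
on the profiled log-likelihood to the χ²₁ quantile) are available by flag;
published asymmetric intervals for such models suggest likelihood-based
intervals, but since the construction is rarely stated both are offered and
neither is claimed canonical. Endpoints the profile never reaches within
the search range are reported as ±inf.

The likelihood-ratio statistic is the standard 2(ln L_full − ln L_reduced),
clamped at zero, with df the difference in free parameters and the p-value
the χ² upper tail. (Sources that print the statistic as
−2[ln L_full − ln L_reduced] obtain its negative; the magnitude and p-value
are identical.) Significance defaults to α = 0.1. The Gompertz-vs-GM
comparison (is the Makeham term needed?) uses the same machinery; note its
null puts α₁ on the boundary of the parameter space, so the naive χ²₁
p-value is conservative — it is reported as the conventional diagnostic with
that caveat. Stratified (early/late period) fits are compared by confidence-
interval overlap, and overlap is always worded as *failing to indicate* a
difference, never as evidence of none.

## Age estimation

Each ordinal trait follows a cumulative-link model
Pr(stage ≥ j+1 | age) = F((age − μ_j)/s) with strictly increasing mean
transition ages μ_j, common dispersion s, and F logistic or probit.
Per-trait models are fitted to a known-age reference sample by ordinal
maximum likelihood (statsmodels' `OrderedModel`; the slope maps to 1/s and
the cutpoints to μ_j/s). Stages never observed in the reference are merged
with their lower neighbour, with a warning.

The posterior over age combines the trait likelihoods (conditionally
independent given age) with a prior on a calendar-age grid of 15–110 years
at 0.25-year steps. The prior is uniform or the age-at-death density of a GM
mortality model conditioned on surviving to 15 — the latter standing in for
an informative "pre-industrial mortality profile" prior. Point estimate is
the posterior mean by default (mode available; reference implementations
differ and rarely say which they use). The credible interval is
highest-posterior-density, computed by density thresholding with linear
interpolation at the cut. Computation is in log space; a stage combination
whose likelihood underflows everywhere raises an error naming the
combination rather than silently renormalising noise.

No attempt is made to reproduce any proprietary reference calibration or
prior; the module reimplements the method class and is parameterised
entirely by configuration.

## Sex estimation

Sectioning points are per-measurement sample means over non-missing values.
Votes are male strictly above the point, female at or below it (the boundary
rule is deliberate and regression-tested). "Combining" femoral and humeral
scores is not standardised in the literature; the implementation uses a
simple majority across available measurements with exact ties indeterminate
— the simplest symmetric rule consistent with per-measurement sectioning.
Morphological estimates are consumed as an external categorical column with
pelvis/cranium availability flags (the upstream trained classifier is out of
scope); reconciliation prefers the metric call over cranium-only morphology
and retains pelvis-backed morphology, on the evidence that post-cranial
estimates outperform skull-only ones. Indeterminate individuals carry no 0/1
code and are excluded from hazard fitting, with the exclusion logged.

## Synthetic assemblages

`SimConfig` defaults are the study conditions the package is designed
around: n = 335 adults, female probability 161/335, ten sites (three early-
period with weights ∝ 47/34/16, seven late-period ∝ 2/35/10/67/42/72/10),
GM baseline α₁ = 0.005, α₂ = 0.015, β = 0.08 (mean adult age-at-death ≈ 35
years, a typical attritional pre-industrial profile), true ρ = 0 (matching
the null-like finding the design emulates), 10% per-cell missingness on
traits and measurements, age cap 110. Five ordinal age indicators with
dispersions of 7–12 years and six measurements with 5–8 mm (or ~25 mm for
lengths) sex differences at 2.3–14 mm SDs emulate realistic trait
informativeness and dimorphism.

Ages are drawn by inverting the PH survival function: solve
e^{xρ}H(t) = −ln U by Brent's bracketed root-finding (tolerance 1e−10
years) on [0, cap−15]; draws beyond the cap are resampled and counted, and
parameter sets placing most mass beyond the cap raise an error. One master
seed spawns independent child streams for sexes, ages, site assignment,
trait stages, measurements, and missingness, so toggling one component never
shifts another — assemblages are bit-reproducible from their provenance
block.

What the generator does *not* emulate: catastrophic (epidemic/famine)
mortality mixtures, burial/preservation taphonomy, age heaping, interval
age uncertainty, or correlated trait missingness. Passing tests therefore
demonstrate statistical correctness of the estimation chain under the
attritional model's own assumptions, not robustness to those real-data
features.

## Verification sizes and numerical choices

The recovery harness fits each replicate with 3 multistarts (the objective
is well-behaved at these n; 10 starts are the single-fit default). Headline
simulation sizes: covariate-effect recovery at 100 replicates × n = 1000
(median bias of ρ̂ within ±0.05, 95% Wald coverage in [0.90, 0.99]); null
LRT calibration at 500 replicates × n = 335 (rejection at α = 0.1 within
the binomial band [0.07, 0.13]); sampler checks at 1000 draws against the
closed-form Gompertz inverse (1e−8) and 20 000 draws for the S₁ = S₀⁴
power-law under ρ = ln 4. Analytic cumulative hazards are verified against
adaptive quadrature at relative tolerance 1e−8 over 1000 random
parameter/age draws, and the likelihood against a per-individual ln-density
sum at 1e−10.

Power on re-estimated ages (transition-analysis posterior means) is never
larger than on true ages — age-estimation error attenuates the covariate
signal — and the recovery harness reports both side by side; at n = 335 and
ρ = 0.5 both are near saturation, so the attenuation is visible mainly at
smaller effects.

## Known limitations

Point-age fitting ignores age-estimation uncertainty (interval-censored
likelihoods are an explicit non-goal), which biases β̂ toward flatter
senescence and inflates the variance of ρ̂. The PH specification cannot
detect age-specific covariate effects. The binary sex code excludes
indeterminate individuals, and the boundary behaviour of α₁ makes its Wald
interval unreliable near zero (the profile interval or the LRT diagnostic is
preferable there).
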