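# Methods

## The model

`rxmix` jointly models, for each patient *i* in a single-drug cohort,

* the first-prescription time *Y\_i* > 0 — years between the drug's initial
  marketing and the patient's first filled prescription — and
* a binary indicator *X\_i* of risk-mitigating behavior at that first
  prescription (e.g. an appropriate first dose under the drug's labeling).

Prescribing of a newly marketed drug often arrives in waves (marketing
pushes, prescriber awareness, formulary changes), so a single unimodal law
for *Y* is too rigid. The marginal model is an *m*-component finite mixture

    Y_i ~ Σ_k α_ik F_k(θ_k),   k = 1..m,

where every component *F\_k* comes from one positive, unimodal,
two-parameter family — Bass, lognormal, or Weibull — and the mixture
weights follow a multinomial logit in patient covariates *Z\_i* (payer
type, etc.), with the last component as reference:

    α_ik = exp(Z_i β_k') / (1 + Σ_{c<m} exp(Z_i β_c')),  k < m.

The Bass family is the adoption-time distribution of
diffusion-of-innovation theory,

    f(y | p, q) = (p+q)²/p · e^{-(p+q)y} / (1 + (q/p) e^{-(p+q)y})²,

with coefficient of innovation *p* > 0 (spontaneous adoption) and
coefficient of imitation *q* ≥ 0 (adoption driven by the installed base);
its mode is log(q/p)/(p+q) when q > p. Its CDF has the closed form
F(y) = (1−E)/(1+(q/p)E) with E = e^{−(p+q)y}, which the package inverts
exactly for sampling. Bass moments have no closed form and are computed by
adaptive quadrature (relative tolerance 1e−8, integration range split at
the mode); lognormal and Weibull moments use their closed forms.

The behavior submodel is a Bernoulli whose success probability depends on
the *posterior* component membership given the observed time,

    π_k(Y_i) = α_ik f_k(Y_i) / Σ_c α_ic f_c(Y_i),
    X_i | Y_i ~ Bernoulli( logit⁻¹( Σ_k γ_k π_k(Y_i) ) ).

The π-weights are the only channel linking the two responses: patients
whose timing places them in an early adoption wave can have a different
behavior rate (γ₁) than late-wave patients (γ₂). Covariates enter the
mixture weights only — a covariate path into γ would be nearly collinear
with π(Y) and is deliberately not provided. The direction of *X* is the
user's choice; the package attaches no meaning to X=1 beyond "event".

### Assumptions

* Times are strictly positive; y = 0 is outside the support and rejected at
  load time rather than nudged.
* All m components share one family within a fit.
* Patients are exchangeable given covariates; within-prescriber clustering
  is not modelled in the likelihood but corrected for in the standard
  errors (below).
* No censoring or truncation of times.

## Estimation

The full likelihood Π_i f(Y_i) · P(X_i|Y_i) is maximized by BFGS on an
unconstrained scale: log transforms for p, q, σ², k, λ, identity for μ, β,
γ (for the intercept-only two-component model the single weight
coordinate is the logit of α). Starting values are sequential:

1. *Marginal stage* — the time mixture alone is fit by ML, started from
   quantile-partition moment matching (split the sorted times into m
   equal slices; per-slice moment estimates per family; for Bass, the
   spread sets p+q through the logistic-tail scale π/(√3·sd) and the
   median sets q/p through the mode formula).
2. *Behavior stage* — γ is fit by Bernoulli ML with π(Y) frozen at the
   stage-1 values.
3. The concatenation starts the joint BFGS run.

Mixture likelihoods are invariant to permuting component labels; fits are
reported in a canonical order (ascending component mode, mean as
tie-break), with β re-expressed against the new reference component and γ
permuted alongside. This makes estimates comparable across replications,
which the coverage bookkeeping requires.

Numerical choices: BFGS gradient tolerance 1e−6 (central finite-difference
gradients cannot support a much tighter one on this likelihood), maximum
500 iterations; convergence is declared on optimizer success or a
finite-difference gradient check at the returned point, and nonconvergence
is flagged on the result, never silently retried. The observed information
is a central finite-difference Hessian with per-coordinate step
1e−5·(1+|θ|). Degenerate fits (a mixture weight at the boundary because
the data carry one wave) are flagged with a warning, not an error.

### Inference

Wald intervals are formed on the unconstrained scale and back-transformed,
so positive parameters get positive intervals and α stays inside (0, 1);
the back-transform is monotone, so coverage statements on either scale
coincide. Constrained-scale point SEs are reported via the delta method
for readability. For clustered data the covariance is the Huber sandwich
H⁻¹ (Σ_g s_g s_g') H⁻¹ with cluster-summed finite-difference scores s_g;
with singleton clusters this is exactly the heteroscedasticity-robust
(Huber–White) estimator. No small-sample cluster correction factor is
applied. Nested models are compared by likelihood-ratio tests (χ² with df
= parameter-count difference; a self-comparison returns p = 1), non-nested
families by AIC = 2k − 2ℓ — for equal parameter counts the AIC ranking is
the likelihood ranking.

## Synthetic data and what it does (not) show

The reference truth used throughout the studies places two adoption waves
with means 1 and 3 years and sd 0.5 each — per family:
Bass (p, q) = (0.0583, 4.36) and (3.86e−5, 3.84);
lognormal (μ, σ²) = (−0.112, 0.223) and (1.09, 0.0274);
Weibull (k, λ) = (2.38, 1.15) and (6.80, 3.24) —
with early-wave weight α = logit⁻¹(−0.5) ≈ 0.38 and behavior weights
γ = (−2.5, −1), the second switchable to +1. These scales match
prescription times measured in years for recently marketed drugs.

Three generators:

* **base** — membership ~ categorical(α), time from the drawn component,
  X from the conditional Bernoulli at the *true* π(Y);
* **covariate** — one standard-normal covariate per patient with
  α_i = logit⁻¹(−0.5 + 1·Z_i);
* **clustered** — 300 patients in prescriber clusters of 10: Gaussian
  copulas, compound-symmetric with ρ = 0.9 inside each cluster, drive the
  uniforms behind the patient-level *binary* draws — component membership
  and the behavior flag — so one prescriber's patients tend to adopt in
  the same wave and to share behavior beyond what their times explain,
  while times stay independent draws from the patient's component.
  Marginally every uniform is standard, so the laws of Y and X|Y are
  exactly those of the base design for any ρ. Where exactly to attach the
  copula is a genuine design choice: coupling it through the
  marginal-mixture quantile instead (the package's `mixture_quantile`
  inverts the mixture CDF by bracketed root-finding, CDF-scale tolerance
  ~1e−10, for exactly such uses) correlates times *within* components and
  was measured to collapse naive coverage for every parameter, including
  the component shapes. Coupling only the binary draws reproduces the
  signature that motivates the sandwich correction — naive CIs for the
  mixture weight and behavior weights collapse (≈0.51/0.53–0.68 observed
  at 300 reps) while component-parameter coverage stays near nominal
  (0.92–0.95), and robust intervals restore the mixture weight to ≈0.95 —
  which is what prescriber-level adoption clustering looks like. Real
  clustering need not take either form exactly.

The generators emulate the *statistical shape* of claims cohorts (wave
structure, behavior rates, payer mix, cluster sizes), not their content:
no MME/dose computation, no opioid-tolerance phenotyping, no real claims
artifacts (duplicate fills, censoring at the data window, measurement
error in fill dates). Passing studies therefore demonstrate that the
estimator and its inference are calibrated *when the model holds*, not
that the model describes any particular drug.

## Study scales and tolerances

Replicated studies are sized for a single-CPU desk run: base-design
coverage 300 replicates per family at n = 100; clustered contrast 300
replicates at n = 300 (Bass generating family — the three families behave
near-identically here); family-recovery 200 replicates per γ₂ setting per
generating family (γ₂ ∈ {−1, +1} pooled); LRT type-I 200 null replicates.
Tolerances in the acceptance tests are the binomial Monte Carlo bands
implied by these counts (e.g. ±3σ ≈ ±0.038 for a 95% coverage estimate at
300 reps). Nonconverged replicates are dropped and counted, never
re-seeded (re-seeding would bias coverage); a drop rate above 5% flags the
study. All randomness flows from per-study integer seeds through
`numpy.random.SeedSequence`, so every aggregate is bit-reproducible and
can be regenerated from the rep-level audit records.

## Known limitations

* Direct quasi-Newton ML only; no EM, no Bayesian machinery, and no
  profile-likelihood intervals.
* The finite-difference Hessian can be indefinite for near-degenerate
  mixtures; the fit is then flagged rather than repaired.
* Component count m is user-chosen; nothing selects it automatically.
* Analysis of deviance is not offered (no natural saturated model for
  two-parameter mixture components); use LRT/AIC.
* Weibull shapes k < 1 (monotone density, mode at 0) are admitted with a
  warning since the mixture is meant to be built from unimodal components.
* At n = 100 with an early-wave weight of ~0.38, each wave is estimated
  from a few dozen patients; Wald intervals for shape-like component
  parameters (most visibly the Weibull shape) then undercover mildly
  (high 0.80s instead of 0.95), while the mixture-weight and behavior
  parameters stay at nominal coverage. Quasi-separation in the behavior
  submodel (no events observed in one wave) occasionally sends a γ to a
  boundary; the resulting wide intervals keep γ coverage conservative,
  matching the intended behavior of Wald inference under separation.
* A single binary response; no censoring; no time-varying covariates; no
  random effects (clustering is an SE correction, not a model component).
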