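# Methods

## Model and timing conventions

The package implements a discrete-event model of a mother's reproductive
history with four linked equations — first-born infant mortality, later-born
infant mortality, the log birth interval, and the decision to have another
birth — tied together by a trivariate normal vector of mother-level random
effects (αₘ, α_b, α_f) ~ N(0, Σ).  Infant mortality means death within 12
months of a live birth.  Dates are real-valued months since the window start
(1 July 1982 by convention); the window ends at month 282 (December 2005) by
default and is configurable; ages are in years and enter the equations
unscaled.  The reproductive span ends at age 45, beyond which no birth is
modelled.

Events unfold in the order: birth *t* (with its sex and mortality outcome) →
continuation decision F_t → if continuing, the interval to birth *t*+1.  The
spacing and continuation equations therefore share one **decision epoch**:
both use the state after birth *t* — survival and sex of child *t*,
parity *t*, the mother's age at birth *t*, and the counts of surviving boys
and girls among births 1..*t* (coded as "at least one" indicators plus
counts in excess of one).  The later-born mortality equation at birth *t*
uses the preceding log interval and its square, their interaction with the
previous sibling's death, parity, and the mother's age at birth *t*.

Two codings are genuinely open and resolved as follows:

* **Which age enters the interval equation.**  Default: the age at the
  decision epoch (birth *t*−1), the moment the spacing process starts.  A
  switch (`interval_age="at_birth"`) uses the age at birth *t* instead; the
  censored next-interval term always uses the epoch age, since the age at a
  never-observed birth is undefined.
* **Parity in the spacing equation.**  The epoch parity (*t*−1), consistent
  with the decision-epoch reading.  Because parity advances by exactly one
  per birth, the alternative (*t*) is an equivalent reparameterization
  (absorbed by the constant and the linear/quadratic parity terms), so
  nothing of substance depends on this.

"Previous sibling died" always uses the final infant-death status of the
preceding birth, even when the next interval is shorter than 12 months
(fewer than 2% of intervals).

## Likelihood

Conditional on α, a history contributes: probit terms for each observed
mortality outcome (the first-born equation carries the loading θ on αₘ);
normal density terms for each observed log interval; log Φ(μ_f) for each
non-final birth; and, for the final birth, the partial-observability term

log[ Φ(−μ_f) + Φ(μ_f) (1 − Φ((log c − μ_b′)/σ_b)) ],

where c = min(window end, mother turns 45) − last birth date (months) and
μ_b′ is the index of the unobserved next interval.  A child whose 12-month
follow-up extends past the window end contributes no mortality term (its
death status would be informatively censored otherwise).  c ≤ 0 is rejected
as an input error.  In the no-fertility-equation variant the continuation
terms are dropped and the final birth contributes only the censored-interval
survival term; in the logistic variant the two mortality equations use the
standard logistic CDF at its natural scale (no rescaling to match the probit
variance), leaving all other terms probit/normal.

The marginal likelihood integrates α by quasi-Monte-Carlo: Halton triples
(bases 2, 3, 5) with a mother-specific uniform random shift, mapped through
Φ⁻¹ and the Cholesky factor of Σ, with antithetic pairing; R = 100 draws by
default.  Draw streams are derived from (seed, mother id), fixed for the
whole fit (common random numbers across optimizer iterations — the standard
device that keeps the simulated likelihood smooth), and independent of
mother order, so the dataset log-likelihood is bit-identical under
permutation of the input.  With Σ = 0 every draw collapses to α = 0 and the
simulated likelihood equals the conditional one for any R.

Σ is parameterized by its Cholesky factor with log-diagonal, which keeps it
positive semi-definite unconstrained; σ_b is log-parameterized.  θ is left
free: its sign is identified through the cross-equation correlation of
first-born and later-born outcomes whenever Σ has a nonzero mortality row
(flipping θ alone, or together with the αₘ row of the factor, changes the
likelihood unless the mortality covariances vanish).

Free-parameter counts: benchmark and logistic 88 (15 + 21 + 22 + 22
coefficients, θ, σ_b, 6 covariance terms); no heterogeneity 81; no fertility
equation 63 (the fertility block's 22 coefficients and the α_f row of the
covariance, 3 terms, are removed).

## Estimation

Fits maximize the simulated log-likelihood by L-BFGS with the analytic
score (assembled per term and validated against central finite differences
in the test suite, which doubles as the smoothness check).  Design columns
are internally rescaled to unit RMS during optimization — the age-squared
column has magnitude ~600 and unscaled quasi-Newton steps crawl — a pure
reparameterization invisible in reported results.  Defaults: relative
function tolerance 1e-7, gradient tolerance 1e-4, 600 iterations maximum;
non-convergence returns the best point flagged.  Starting values are the
usual two-step warm start: single-equation probits (statsmodels) for the
mortality and naively-uncensored continuation outcomes, least squares for
the log intervals, Σ = 0.1 I, θ = 1.  Standard errors are
outer-product-of-gradients from the per-mother analytic scores; a singular
OPG flags them unavailable.  σ_b's standard error is delta-method from the
log scale.  AIC = 2k − 2LL; BIC = −2LL + k log(n) with n the number of
children.

## Synthetic population and data-generating process

The generator draws mother-level covariates independently from the published
sample marginals of either study area (religion, education, occupation,
water source; distance ~ normal truncated at 0; age at first birth ~ normal
truncated to [15, 40]; first-birth date uniform on [0, window − 12] so every
first-born's infancy is observed; child sex Bernoulli per birth).  The
mother's birth cohort is derived from her age and first-birth date rather
than drawn, which precludes impossible combinations.  Truncation lifts the
two continuous means slightly above their published targets (≈ +0.2 years,
≈ +0.38 km); the configured values are the published means, and the
truncated-law means are what the generator is tested against.

What the generator does **not** emulate: cross-correlations among covariates
(independence keeps strict exogeneity transparent and recovery tests clean),
village/spatial clustering, secular covariate trends, stillbirths, and
multiple births.  Passing tests therefore demonstrate internal correctness
of the estimator and simulator under the model's own assumptions — not
robustness to the richer dependence of real surveillance data.

The preset parameter set is the published comparison-area benchmark
estimate table plus the published heterogeneity covariance; θ, which is not
reported, is set to 1 (the later-born loading is 1 by construction).  One
internal inconsistency in the published table matters for simulation: with
ages in years — the scale confirmed by the reported age-27 mortality minimum
(0.1507/(2·0.0028) ≈ 26.9) — the printed first-born constant (−0.6178)
implies ≈0.4% first-born mortality, against the published sample rate of
8.90%.  `presets.calibrated_dgp` therefore re-solves **only that constant**
(by Gauss–Hermite integration of the heterogeneity and a root find) so the
population-average first-born mortality matches the published rate for the
chosen area; all other coefficients stay printed.  Simulation experiments
use the calibrated process — at the printed constant, first-born deaths are
so rare that the 15 first-born coefficients are unidentifiable at any
practical sample size.

The forward simulator runs the four equations recursively with one α draw
per mother, flooring intervals at 9 months (a gestation bound; the
likelihood models the interval as unfloored lognormal, and under the preset
the mass below 9 months is ≈0.2%, a deliberate, documented approximation)
and stopping at the window end or age 45 — exactly the censoring event the
likelihood's final term integrates over, so the estimator is consistent for
the simulator's process.

## Counterfactual scenarios

All scenario columns are computed under common random numbers: every
(mother, replication) has a draw bundle indexed by birth slot, regenerated
deterministically from (seed, mother index, replication), so switches change
linear indices only.  Semantics:

* **replacement off** — spacing and continuation treat the previous child as
  alive and count all children as survivors (no effect of realized mortality
  on either decision);
* **state dependence off** — the lagged-mortality main effect and its
  log-interval interaction are removed from the later-born mortality
  equation only;
* **all boys** — composition counts and the child-sex regressor in the
  spacing/continuation equations treat every child as a boy; drawn sexes
  still enter the mortality equations.

Summary statistics: infant deaths per 1000 live births, the pooled median of
all observed intervals (per-replication medians averaged on request), and
mean births/survivors per mother; scenario columns report percent deviations
from benchmark.

## Numerical choices and test design

* Quadrature oracle: 15³ tensor Gauss–Hermite, which is converged to seven
  decimals on the toy used (15 vs 25 vs 35 nodes identical).  The agreement
  test uses a two-birth history with moderate event probabilities and a
  correlated covariance with variances 0.2–0.5; integrands with
  deep-tail event probabilities (e.g. 0.4% mortality) have quasi-Monte-Carlo
  errors at R = 1e5 far above 1e-4 for any stream and cannot discriminate a
  correct implementation.
* Outcome-space coherence: enumerating all outcomes of a 2-birth-maximum toy
  (death/survival × stop/censor/continue × a 4001-point interval grid plus
  censored mass plus the continue-beyond lump) reproduces total probability
  1 to 1e-4; σ_b = 0.3 keeps the interval mass below the 9-month floor
  (which observable histories cannot represent) near 3e-5.
* Problem sizes: recovery uses two independent populations of 1000 mothers
  with R = 48 (160 structural coefficients pooled; ≥95% within 3 SE
  required, ~99% observed); the model-ranking experiment uses 2500 mothers
  with R = 32; counterfactual sign checks use 2000 mothers × 6 replications;
  the acceptance script simulates 3000 mothers × 10 replications and one
  recovery fit at 1000 mothers.  These sizes were chosen for a single-CPU
  run; the statistical criteria scale their Monte-Carlo error bands
  accordingly.

## Known limitations

* The interval floor creates a small likelihood/DGP mismatch (≈0.2% of
  intervals under the preset); a censored-at-floor density would remove it
  at the cost of a kink in the score.
* θ and the mortality heterogeneity variance are weakly identified at
  n ≈ 1000 (few first-born deaths carry the signal); their OPG standard
  errors are large and honest.
* The published BIC values match no standard convention (the implied
  per-parameter constant corresponds to no printed sample size); the package
  reports the standard BIC and treats the printed one as non-reproducible.
* The published parameter count for the no-fertility-equation variant (64)
  exceeds the faithful count (63 = 88 − 22 fertility coefficients − 3
  covariance terms); the package reports the true count.
* The reported 63.3-month mortality-minimizing interval for surviving
  previous siblings is not recoverable from the printed coefficients (which
  give 61.3); the package does not force agreement.
* Benchmark simulation *levels* depend on the covariate distribution; on the
  synthetic population they land close to, but not exactly at, the published
  levels (e.g. 68–69 vs 68.5 infant deaths per 1000).
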