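# replsim

Joint dynamics of infant mortality, birth spacing and fertility in a
high-fertility population, as a reusable, tested Python package: a
three-process dynamic family model with correlated mother-specific random
effects, estimated by simulated maximum likelihood, plus the forward
microsimulation used to quantify **replacement effects** (extra births caused
by infant deaths) and related counterfactuals.

It is written for demographers and applied econometricians who want to
estimate or probe this class of model on birth-history data — or, since the
motivating surveillance data (Matlab, Bangladesh, 1982–2005) are not public,
on synthetic populations calibrated to the published sample composition.

## The model

For mother *i* with consecutive live births *t* = 1, …, *T*ᵢ:

* infant mortality (first born):  M\*ᵢ₁ = X ᵢ₁β₁ + θ αₘᵢ + uₘᵢ₁, Mᵢ₁ = 1{M\*ᵢ₁ > 0}
* infant mortality (later born):  M\*ᵢₜ = Xᵢₜβₘ + Zᵢₜγₘ + αₘᵢ + uₘᵢₜ
* log birth interval:             bᵢₜ = Xᵢₜβ_b + Z⁽ᵇ⁾ᵢₜγ_b + α_bᵢ + u_bᵢₜ, u_b ~ N(0, σ_b²)
* another birth after t:          F\*ᵢₜ = Xᵢₜβ_f + Z⁽ᶠ⁾ᵢₜγ_f + α_fᵢ + u_fᵢₜ, Fᵢₜ = 1{F\*ᵢₜ > 0}

with probit errors, strictly exogenous covariates X (religion, parental
education, occupation, water source, distance to health facility, mother's
cohort), endogenous state variables Z built from the history prefix (the
preceding log interval and its square, survival of the preceding sibling,
parity, maternal age, counts of surviving boys and girls), and a trivariate
normal heterogeneity vector (αₘ, α_b, α_f) ~ N(0, Σ) shared across a
mother's births — the channel that separates causal state dependence from
family-level frailty.

The continuation outcome is only partially observed: after the last observed
birth, "no further birth" is a mixture of stopping (F = 0) and a next
interval censored by the observation window or age 45,

log P(no more births) = log[ Φ(−μ_f) + Φ(μ_f) · (1 − Φ((log c − μ_b)/σ_b)) ],

where *c* is the months remaining to the earlier bound.  The marginal
likelihood integrates the three random effects by antithetic shifted-Halton
quasi-Monte-Carlo, maximized by L-BFGS with an analytic score; standard
errors come from the outer product of per-mother scores.  Four model
variants are supported: the benchmark, no heterogeneity, no fertility
equation (pure censored-interval model), and logistic errors in the
mortality equations.

## Worked example

Simulate a comparison-area population from the published estimates and
tabulate the counterfactual scenarios (`examples/03_counterfactuals.py`):

```text
benchmark column = levels; scenario columns = % deviation

                           benchmark  replacement_off  state_dependence_off  all_boys
infant_mortality_per_1000      68.89            -2.72                  0.99      0.68
median_interval_months         38.11             4.43                 -0.04      1.24
mean_births                     2.95            -4.38                  0.04     -2.83
mean_survivors                  2.75            -4.19                 -0.03     -2.88

Eliminating replacement removes 4.38% of births at a mortality rate of
68.9/1000, i.e. 0.64 extra births per infant death under the estimated
behaviour.
```

Reading: the benchmark column reproduces the published comparison-area
levels (≈68.5 infant deaths per 1000 live births, ≈36-month median
interval, ≈2.75 births per mother).  Switching off replacement — families
space and plan as if every child survived — lengthens the median interval,
removes ~4% of births, and (because short post-death intervals are risky)
lowers infant mortality itself; the implied replacement effect is on the
order of half an extra birth per infant death.  Removing the direct effect
of a sibling's death on the next child's risk (negative here) raises
mortality; planning "as if all children were boys" lengthens intervals and
cuts births, the signature of son preference.

The other examples cover the synthetic population (`01`), forward simulation
(`02`), the quadrature check of the simulated likelihood (`04`), parameter
recovery by simulated ML (`05`), and the closed-form derived quantities
(`06`).  A thin CLI mirrors the pipeline:

```bash
replsim simulate-covariates --area comparison --n 5000 --seed 1 --out mothers.csv
replsim simulate --mothers mothers.csv --seed 1 --out histories.csv
replsim fit --data histories.csv --variant benchmark --draws 100 --seed 3 --out fit.json
replsim counterfactual --mothers mothers.csv --reps 25 --seed 7 --out table.csv
replsim report --fit fit.json --table table.csv --out report.md
```

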