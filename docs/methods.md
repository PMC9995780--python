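# Methods

## Generative model

Each simulated cohort of size `n` draws, independently per individual:

1. genotype dosage `g ~ Binomial(2, maf)` — a single biallelic variant under
   Hardy-Weinberg equilibrium, no linkage, no missingness;
2. true disease status `D ~ Bernoulli(expit(β₀ + g·βg))` — logistic
   penetrance, no covariates;
3. observed status `D* = D · 1[U ≥ π]`, `U ~ Uniform(0,1)` — case-only
   thinning at misclassification rate `π`.

One uniform is drawn per individual and compared against `π`, so holding the
stream fixed and raising `π` removes observed cases monotonically (this
coupling is property-tested). False positives are structurally impossible:
`D* ≤ D` elementwise, and the 2×2 tabulation type carries an `n01` cell only
for generality.

Default parameters are the study design: `βg = 0.1`, `β₀ ∈ {−1.5, −1,
−0.5}` (marginal prevalences 0.1917, 0.2811, 0.3918, printed as ≈19/28/39%),
`maf = 0.3`, `π ∈ {0.4, 0.6, 0.8}`, `n = 20 000`, 1000 replicates per cell.
All are dimensionless (log odds, probabilities) except `n` (individuals).

## Estimation and power

Each replicate is analysed twice: logistic regression of the true status and
of the observed status on allele count (maximum likelihood via statsmodels).
Power is the fraction of replicates whose two-sided Wald p-value for the
slope is strictly below .05; the Wald test (rather than likelihood-ratio or
score) is used because the target of inference is the slope estimate itself.
Replicates with a degenerate outcome (possible only at π = 1) or a
non-converged fit are excluded from mean-estimate aggregation and counted as
non-significant for power; at the default sample sizes and prevalences this
never occurs. Bias is reported as `βg − mean(β̂g observed)`, so positive
values mean attenuation toward the null.

## Seeding and reproducibility

Each `Scenario` carries one root seed; per-replicate generators are spawned
from it via `numpy.random.SeedSequence`, making replicates independent and
results invariant to execution order or parallel scheduling. Grid runs
derive per-cell seeds from a single study seed the same way (all derived
seeds are kept below 2³¹). The shipped default study seed is 20221215.
Identical scenario + seed reproduces cohorts bit for bit.

## The expected-score attenuation oracle

The mean misclassified-outcome estimate in any cell is a Monte-Carlo average
whose limit can be computed exactly. With stratum weights
`P(g) = Binomial(2, maf).pmf(g)` and observed-case probabilities
`q_g = (1−π)·expit(β₀ + βg·g)`, the large-sample misclassified MLE maximizes

```
L(b₀, b₁) = Σ_g P(g) [ q_g log expit(b₀+b₁g) + (1−q_g) log(1−expit(b₀+b₁g)) ]
```

solved by Newton iteration with the analytic gradient and Hessian from the
true parameters, to gradient norm < 1e−12 (guaranteed < 1e−10; a damped
gradient step covers the singular-Hessian corner, and π = 1 is returned as a
flagged degenerate result rather than solved). The oracle is supporting
engineering — a deterministic surface for checking stochastic results — not
an asymptotic analysis with any claim beyond these three genotype strata.
Tests cross-check it against a derivative-free optimizer and against the
simulation means (which agree within 3 Monte-Carlo standard errors in all
nine cells at 1000 replicates).

Because published per-cell means at 1000 replicates have Monte-Carlo
standard errors of ~0.0013–0.0018, third-decimal agreement between any
reproduction (or the oracle's limit) and a particular published run is not
generally expected; agreement within a few of those standard errors is.

## Reverse mediation

For a variant `g` whose effect on a well-recorded symptom is completely
mediated by the underdiagnosed disease (`g → disease → symptom`, no direct
path), the package's point estimator is the log-odds quotient

```
log ÔR(g→disease) = log OR(g→symptom) / log OR(disease→symptom)
```

chosen as the minimal formalization of chain inversion; both input
odds ratios are fitted marginally, since that is what a population without
reliable disease labels can estimate. The estimator preserves the null and
satisfies its defining algebraic round trip exactly, but for a **binary**
mediator its large-sample limit is far below the conditional per-allele
log-OR at any outcome rarity: a one-allele shift moves the disease
*probability* by roughly `p(1−p)·βg`, and only that probability-scale shift
propagates to the symptom's log-odds. The `population_quotient` oracle
computes the limit exactly (expected-score fit of the symptom on genotype
over the strata, divided by the symptom model's disease coefficient), and
`mediation_recovery_study` measures the finite-sample behaviour; under the
reference chain (disease prevalence 5%, symptom prevalence 5%, disease →
symptom log-OR 1, true `βg = 0.1`) the limit is ≈ 0.0072 — ~93%
attenuation — and the simulated mean tracks the limit, not the generating
value. Non-collapsibility at common outcome prevalences attenuates it
further. The estimator is therefore shipped as a *lower-bound screening
quantity with a calibration harness*, not as an unbiased recovery method; no
standard-error propagation is provided (a delta-method CI is a natural
extension point).

## Synthetic data vs reality

The generator emulates the statistical skeleton of a biobank association
test and nothing else: one variant, no linkage disequilibrium or polygenic
background, no covariates (age, sex, BMI, ancestry PCs), non-differential
misclassification (`π` independent of genotype — real underdiagnosis
plausibly varies with symptom-related genotypes), and no genotype error.
Passing tests therefore demonstrate the mechanics and magnitude of
misclassification bias under these assumptions, not the behaviour of any
real cohort.

## Numerical and design choices

* Genotypes are redrawn each replicate (fully independent replicates);
  `redraw_genotypes=False` freezes them for variance-decomposition
  experiments.
* Significance at the .05 boundary is resolved by the strict inequality.
* The significance level is configurable but the default study reproduction
  uses .05 only; no genome-wide (5e−8) threshold simulation is attempted.
* Fits are flagged non-converged (estimates NaN) on separation rather than
  raising; constant outcomes or predictors raise typed errors instead.
* Problem sizes used by the shipped checks: the full-scale suite runs the
  nine-cell grid at 1000 replicates of n = 20 000 (≈18 000 logistic fits);
  the example scripts use 200 replicates; the mediation harness defaults to
  n = 100 000 per replicate. Monte-Carlo standard errors are reported
  alongside every power and mean so tolerances can be derived rather than
  guessed.

## Known limitations

Single-variant scope (no multi-variant or genome-wide simulation);
case-only misclassification only (no false positives, no differential
error); no analytic power formula (simulation is the power instrument); the
mediation estimator is deliberately the simplest defensible one and is
biased for binary mediators as documented above.
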