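# Methods

## The model

`corrbf` tests hypotheses about the association between pairs of variables
measured on continuous, ordinal (3+ ordered categories) or binary scales.
Every pair is related through a latent bivariate-normal correlation; the
observed-scale combination determines its conventional name:

|                | continuous     | ordinal        | binary      |
|----------------|----------------|----------------|-------------|
| **continuous** | product–moment | polyserial     | biserial    |
| **ordinal**    |                | polychoric (I) | polychoric (II) |
| **binary**     |                |                | tetrachoric |

Each row of the data is a realization of a latent normal vector
`W ~ N(m, D R D)`.  Continuous variables are observed directly, with free
mean and scale carrying Jeffreys priors `p(mu, sigma) ∝ 1/sigma`.  Ordinal
and binary variables are observed as the category into which their latent
score falls relative to a strictly increasing vector of free thresholds;
the latent scale is fixed to mean 0 and variance 1 for identification
(binary variables have one free threshold, K-category ordinal variables
K−1).  With covariates present, each variable's (latent) mean is a linear
function of the centered covariates with flat coefficient priors, so `R`
holds partial correlations given the covariates.  Independent groups get
independent correlation matrices.

The correlation matrix `R` of each group carries the *jointly uniform*
prior: constant density over the set of positive-definite correlation
matrices.  Its marginal for any single correlation in dimension `P` is a
stretched beta(P/2, P/2) on (−1, 1), so the prior automatically
concentrates around zero as variables are added.  No other prior for the
correlations is offered; this is a deliberate reference-analysis design.

## Hypothesis testing

Hypotheses are conjunctions of equality and order constraints on the named
correlations, e.g. `pa_with_bmi = 0` or `Y_with_X1 > Y_with_X2`.  Every
hypothesis is compared against the unconstrained encompassing model:

- **Equality constraints** use the Savage–Dickey density ratio evaluated on
  the Fisher scale (`zeta = atanh rho`): BF(H, u) is the posterior density
  of the constrained combinations at the null point divided by the prior
  density there.  The posterior density comes from a multivariate normal
  fitted to the pooled, Fisher-transformed MCMC draws.  The prior density
  does **not** need that approximation: where a constraint pins a single
  correlation its prior marginal is the stretched beta, known in closed
  form, and for combinations (e.g. `zeta_1 − zeta_2`) a Gaussian kernel
  density estimate over 100,000 exact prior draws is used.  Using the exact
  prior density matters: the normal fit underestimates the prior's peak at
  zero by ~12% in the bivariate case (0.44 vs the exact 0.5), which would
  bias every two-sided Bayes factor by the same factor.
- **Order constraints** use the encompassing probability ratio: posterior
  over prior probability of the constrained region, computed from the
  stored posterior/prior draws (conditioned on the equality part via
  normal-approximation conditioning when both are present).
- **The complement hypothesis** covers the region not claimed by any stated
  order constraint; equality-only hypothesis sets make it identical to the
  unconstrained model.  Its mass is one minus the union mass of the stated
  order regions under the respective draws.

BFs between hypotheses follow by transitivity, `BF(i, j) = BF(iu)/BF(ju)`,
and posterior hypothesis probabilities by Bayes' rule from the prior
weights: `P(Hi | Y) ∝ BF(iu) · w_i`.  The standard test runs
`H0: rho = 0`, `H−: rho < 0`, `H+: rho > 0` per correlation with default
weights (2, 1, 1), i.e. prior probabilities (1/2, 1/4, 1/4); the one-sided
prior masses are exactly 1/2 by symmetry and are used exactly rather than
estimated.

## The sampler

A Gibbs sampler cycles per group: latent scores → thresholds → nuisance
(means, scales, coefficients) → correlations.

- *Latent scores*: truncated-normal full conditionals (inverse-CDF,
  vectorized over rows).
- *Thresholds*: each cutpoint uniform between the adjacent latent order
  statistics (standard cutpoint step); monotonicity is preserved by
  construction.
- *Scales*: the full conditional of `phi = 1/sigma` is
  `phi^{n−1} exp(−a phi²/2 − b phi)`; it is sampled by inverse-CDF on a
  300-point grid spanning ±8 conditional standard deviations around its
  mode (available in closed form).
- *Correlations*: each entry in turn is drawn from its full conditional by
  discretized inverse-CDF on a 200-point grid ("griddy Gibbs").  The
  support is the interval on which `R` stays positive definite given all
  other entries — obtained exactly from the roots of the determinant, which
  is quadratic in the entry — intersected with (−nugget, nugget).  Because
  the jointly uniform prior is flat precisely on that interval, the
  conditional is the latent likelihood restricted to the support; with the
  likelihood switched off the chain reproduces the prior, which the tests
  verify against the stretched-beta marginals.

Grid densities are integrated with the trapezoid rule before inversion;
sampling from point masses at the grid nodes instead would bias draws by
up to half a grid cell, which is visible in the Bayes factors.

Defaults: 10,000 iterations, 2 chains, burn-in 20% of iterations, nugget
0.999, grid 200 (doubling the grid moves the bivariate Bayes factors by
well under 1%).  Report-grade runs use 100,000 iterations.  Convergence is
monitored with the classic split-chain R-hat (via `arviz`, method
`"split"`); values above 1.05 emit a warning.  The *nugget* truncates every
conditional support to (−nugget, nugget): it keeps the sampler out of the
degenerate corners near |rho| = 1 (a real risk with small discrete tables)
at the price of slight shrinkage toward zero, so smaller values (.995,
.99, …) should be used only to fix convergence problems.

For continuous data the sampler's stationary distribution is the exact
joint posterior under the Jeffreys nuisance priors.  It was validated
against the closed-form marginal posterior of a bivariate correlation,
`p(rho | r) ∝ (1−rho²)^{(n−1)/2} (1−rho r)^{−(n−3/2)} · 2F1(½, ½; n−½;
(1+rho r)/2)`: Fisher-scale posterior moments agree to three decimals at
n = 44.

## Synthetic data

The worked examples in this literature are defined by their *sample*
correlations (raw data unavailable), so the generator produces data whose
sample correlation matrix equals the target **exactly**: draw standard
normals, center, whiten with the inverse Cholesky factor of the empirical
covariance, recolor with the Cholesky factor of the target.  Continuous
Bayes factors depend on the data only through (n, r), so these fixtures
reproduce the published analyses exactly up to Monte-Carlo error.
Discretized columns are cut at the conventional BMI thresholds
(16.5/18.5/25/30) and steps-per-day thresholds (5000/7500/10000/12500)
after rescaling to plausible BMI (mean 24, SD 4) and step-count (mean
9000, SD 2500) scales; intervals are left-closed/right-open.

What the generator does *not* emulate: non-normal margins, outliers,
missing data, and the specific discretization margins of the original
studies' files.  Passing tests therefore demonstrate correctness of the
machinery under the latent-normal model, not robustness to model
violation.  The discrete-scale analyses of the original example data are
additionally not identified by published numbers alone (the category
margins were never printed), so they are covered by parameter-recovery
tests at n = 500 rather than by value reproduction.

## Numerical choices and problem sizes

- Prior Monte Carlo: 100,000 onion-method draws (exact, i.i.d.); the fitted
  prior normal approximation zeroes cross-group covariance blocks exactly.
- Posterior moments: chains pooled after burn-in; degenerate (constant)
  draw columns raise instead of being regularized — they indicate a stuck
  sampler, which the nugget is the remedy for.
- Prior-only Gibbs checks thin by 10 in P = 3 (the KS test assumes
  independent draws; P = 2 conditionals are already i.i.d.).
- Quantiles: linear interpolation of order statistics.
- Evidence labels use the 1/3/20/150 cutoffs.
- Test-suite problem sizes: the two worked examples run at 100,000
  post-burn-in draws and 2 chains; parameter recovery runs n = 500 with
  1,500 iterations and a single chain per scale combination; oracle
  comparisons use n ≤ 50 where grid integration is cheap and accurate.

## Limitations

- The Fisher-scale normal approximation of the posterior degrades for very
  small samples (the same caveat applies to classical tests).
- Ordinal variables with more than 10 observed levels are auto-typed
  continuous; missing data are handled by listwise deletion only.
- Classical p values are provided for the product–moment case only.
- Combined equality+order hypotheses condition the order probability on
  the equality through the normal approximations on both sides; with very
  non-normal priors in high dimensions this is an approximation without an
  exact fallback.
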