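# corrbf

Default Bayesian hypothesis tests for correlation coefficients.

Applied researchers routinely ask whether an association between two
variables is zero, negative or positive, whether two correlations are
equal, or whether a correlation replicated across independent samples.
Classical p values cannot quantify evidence *for* a null hypothesis and
cannot separate absence of evidence from evidence of absence.  `corrbf`
answers these questions with Bayes factors and posterior hypothesis
probabilities, for every common correlation type between continuous,
ordinal and binary variables — product–moment, polyserial, biserial,
polychoric and tetrachoric — including grouped data (independent
correlation matrices per group) and covariate adjustment (partial
correlations).

## The method in brief

For variables Y₁, Y₂ with correlation ρ, the two-sided test

&nbsp;&nbsp;&nbsp;&nbsp;H₀: ρ = 0  vs  H₁: ρ ≠ 0

is quantified by the Bayes factor BF(H₁, H₀) = p(Y | H₁) / p(Y | H₀).
Under H₁ the correlation matrix carries a *jointly uniform* prior over
the positive-definite set, whose per-correlation marginal in dimension P
is a stretched beta(P/2, P/2) on (−1, 1); nuisance means and scales carry
Jeffreys priors.  Posterior draws of the correlations come from a Gibbs
sampler over latent normal scores (mixed scales), thresholds, nuisance
parameters and the correlations themselves ("griddy Gibbs" on the
positive-definiteness interval).  Bayes factors are then computed on the
Fisher scale ζ = atanh ρ: a Savage–Dickey density ratio for equality
constraints (normal approximation of the posterior; exact stretched-beta
or kernel-density prior), and posterior/prior region-probability ratios
for order constraints such as ρ₁ > ρ₂.  Prior weights w_i turn Bayes
factors into posterior hypothesis probabilities
P(H_i | Y) ∝ BF(i, u) · w_i.

See `docs/methods.md` for the full model, sampler and design notes.

## Worked example

The bundled fixture reproduces a classic example: n = 44 observations of
body-mass index and pedometer-measured physical activity with sample
correlation exactly r = −0.38.

```bash
corrbf fixture bmi_pa --out bmi_pa.csv --seed 3
corrbf run --data bmi_pa.csv --vars bmi,pa \
    --hypothesis "pa_with_bmi = 0" --iterations 10000 --seed 1 --format text
```

```
Posterior probabilities for standard hypothesis test
  parameter    P(H0|Y)  P(H-|Y)  P(H+|Y)
  pa_with_bmi  0.190    0.805    0.005

BFs: standard hypothesis test for pa_with_bmi (best: H- (rho < 0))
  against       BF       evidence
  H0 (rho = 0)  8.466    positive evidence
  H+ (rho > 0)  158.307  very strong evidence

Evidence matrix
      H1     H2
  H1  1.000  0.235
  H2  4.260  1.000

Posterior model probability
  hypothesis  P(H|Y)
  H1          0.190
  H2          0.810

Estimates
  parameter    mean    median  2.5%    97.5%
  pa_with_bmi  -0.353  -0.361  -0.587  -0.078
```

Reading the output: the data are about 4.3 times more likely under a
nonzero correlation than under the null (H2 vs H1 in the evidence
matrix), giving the two-sided hypothesis a posterior probability of .81
against .19 for the null — positive but not decisive evidence.  The
standard three-way test splits the alternative by sign: a negative
correlation is favored over a zero one by a factor ~8.5 and over a
positive one by a factor ~158, and the 95% credible interval of ρ is
(−0.59, −0.08).  Note the null retains ~19% posterior probability even
though the classical p value (.011) would reject it at the 5% level.

Correlations are named `<later>_with_<earlier>` in the order the
variables are listed (so `--vars bmi,pa` yields `pa_with_bmi`), with
`_in_g1`, `_in_g2`, … suffixes when a `--group` column is given.
Hypotheses combine `=`, `<`, `>` and `&`, e.g.
`"Y_with_X1 = Y_with_X2"` or `"r > -0.1 & r < 0.1"`; the complement of
the stated hypotheses is included automatically unless `--no-complement`
is passed.  Use `--report-grade` (100,000 iterations) for
publication-quality numerical accuracy, and report the `--seed`.

The same pipeline is available as a library: `load_table` /
`make_fixture` → `run_mcmc` → `fit_posterior_normal_approx` +
`fit_prior_normal_approx` → `standard_test` / `manual_test` →
`summarize`.

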