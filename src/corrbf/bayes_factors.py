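"""Bayes factors for constrained hypotheses on correlations.

Each hypothesis is compared against the unconstrained (encompassing) model
under the jointly uniform prior.  Equality constraints are evaluated with
the Savage-Dickey density ratio on the Fisher scale: the posterior density
of the constrained combinations at the null point, divided by the prior
density there.  The posterior density comes from the multivariate normal
approximation fitted to the Fisher-transformed MCMC draws; the prior
density uses the exact stretched-beta marginal where the constraint pins a
single correlation, and a kernel density estimate over prior Monte Carlo
draws for combinations of correlations.  Order constraints use the
encompassing probability ratio: posterior over prior probability of the
constrained region (conditioned on the equality part when both are
present).  Bayes factors between hypotheses follow by transitivity,
BF(Hi, Hj) = BF(iu) / BF(ju), and posterior hypothesis probabilities by
weighting with the prior probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .fisher_normal import NormalApprox
from .hypotheses import Complement, ConstraintSet, HypothesisSet
from .prior_sampler import marginal_prior_density_fisher

DEFAULT_MC_DRAWS = 100_000

#: Standard three-hypothesis test: zero / negative / positive correlation.
STANDARD_LABELS = ("H0 (rho = 0)", "H- (rho < 0)", "H+ (rho > 0)")
STANDARD_WEIGHTS = (2.0, 1.0, 1.0)


class DegenerateHypothesisError(ValueError):
    """A hypothesis whose prior mass vanishes cannot be tested."""


@dataclass
class TestResult:
    """Evidence matrix, Bayes factors and posterior hypothesis probabilities."""

    __test__ = False  # keep pytest from collecting this as a test class

    labels: list
    bf_iu: np.ndarray
    prior_probs: np.ndarray
    posterior_probs: np.ndarray = field(init=False)
    evidence: np.ndarray = field(init=False)
    legend: dict = field(default_factory=dict)

    def __post_init__(self):
        self.bf_iu = np.asarray(self.bf_iu, dtype=float)
        self.prior_probs = np.asarray(self.prior_probs, dtype=float)
        self.posterior_probs = posterior_hypothesis_probs(self.bf_iu, self.prior_probs)
        self.evidence = evidence_matrix(self.bf_iu)

    @property
    def best(self) -> int:
        """Index of the best-supported hypothesis (ties toward the first)."""
        p = self.posterior_probs
        return int(np.flatnonzero(np.isclose(p, p.max()))[0])


def _draws_or_sample(approx: NormalApprox, mc_draws: int, seed) -> np.ndarray:
    """Stored draws when present, otherwise Monte Carlo from the normal fit."""
    if approx.draws is not None:
        return approx.draws
    rng = np.random.default_rng(seed)
    return rng.multivariate_normal(approx.mean, approx.cov, size=mc_draws)


def _equality_point(constraints: ConstraintSet) -> np.ndarray:
    """Null point of the equality system on the Fisher scale.

    Equality of two correlations is equivalent to equality of their Fisher
    transforms, and a correlation pinned to the literal r corresponds to
    zeta = atanh(r); literals are therefore atanh-transformed.
    """
    if np.any(np.abs(constraints.r_E) >= 1):
        raise DegenerateHypothesisError("equality literal outside (-1, 1)")
    return np.arctanh(constraints.r_E)


def _normal_logpdf(point, mean, cov) -> float:
    cov = np.atleast_2d(cov)
    return float(stats.multivariate_normal.logpdf(point, mean=mean, cov=cov))


def _prior_equality_logdensity(
    constraints: ConstraintSet, prior: NormalApprox, z_E: np.ndarray,
    mc_draws: int, seed,
) -> float:
    """log prior density of R_E zeta at z_E on the Fisher scale.

    Single-correlation rows use the exact stretched-beta marginal; anything
    else falls back to a Gaussian KDE over prior draws (or, without stored
    draws, the prior normal approximation).
    """
    R_E = constraints.R_E
    if R_E.shape[0] == 1 and np.count_nonzero(R_E[0]) == 1 and prior.P is not None:
        k = int(np.flatnonzero(R_E[0])[0])
        c = R_E[0, k]
        # density of c * zeta_k at z_E
        return float(
            np.log(marginal_prior_density_fisher(z_E[0] / c, prior.P)) - np.log(abs(c))
        )
    if prior.draws is not None:
        proj = prior.draws @ R_E.T
        kde = stats.gaussian_kde(proj.T)
        dens = float(kde(np.atleast_2d(z_E).T)[0])
        if dens <= 0:
            raise DegenerateHypothesisError("prior density vanishes at the null point")
        return np.log(dens)
    return _normal_logpdf(z_E, R_E @ prior.mean, R_E @ prior.cov @ R_E.T)


def _conditional_normal(approx: NormalApprox, R_E, z_E):
    """Mean/cov of zeta given R_E zeta = z_E under the normal approximation."""
    mu, S = approx.mean, approx.cov
    A = R_E @ S @ R_E.T
    gain = S @ R_E.T @ np.linalg.inv(A)
    mean = mu + gain @ (z_E - R_E @ mu)
    cov = S - gain @ R_E @ S
    cov = 0.5 * (cov + cov.T)
    return mean, cov


def _order_probability(
    constraints: ConstraintSet, approx: NormalApprox, mc_draws: int, seed
) -> float:
    """Probability of the order region under prior or posterior."""
    if constraints.n_orders == 0:
        return 1.0
    if constraints.n_equalities == 0:
        if constraints.n_orders == 1:
            # exact 1-D normal orthant under the fitted approximation for the
            # posterior; empirical fraction of draws where available
            draws = _draws_or_sample(approx, mc_draws, seed)
            return float(constraints.order_satisfied(draws).mean())
        draws = _draws_or_sample(approx, mc_draws, seed)
        return float(constraints.order_satisfied(draws).mean())
    # conditional on the equality part: sample the conditioned normal fit
    z_E = _equality_point(constraints)
    mean, cov = _conditional_normal(approx, constraints.R_E, z_E)
    rng = np.random.default_rng(seed)
    jitter = 1e-12 * np.eye(len(mean))
    draws = rng.multivariate_normal(mean, cov + jitter, size=mc_draws)
    return float(constraints.order_satisfied(draws).mean())


def bf_vs_unconstrained(
    constraints,
    prior: NormalApprox,
    posterior: NormalApprox,
    mc_draws: int = DEFAULT_MC_DRAWS,
    seed=0,
) -> float:
    """Bayes factor of one hypothesis against the unconstrained model.

    ``constraints`` is a :class:`ConstraintSet` or a :class:`Complement`
    marker.  BF_iu = (posterior/prior density of the equality part at the
    null point) x (posterior/prior probability of the order region,
    conditional on the equality part when both are present).  The
    unconstrained hypothesis (no rows) has BF_iu = 1 by definition.
    """
    if isinstance(constraints, Complement):
        return _complement_bf(constraints, prior, posterior, mc_draws, seed)
    if constraints.is_unconstrained:
        return 1.0
    log_bf = 0.0
    if constraints.n_equalities:
        z_E = _equality_point(constraints)
        R_E = constraints.R_E
        log_post = _normal_logpdf(z_E, R_E @ posterior.mean, R_E @ posterior.cov @ R_E.T)
        log_prior = _prior_equality_logdensity(constraints, prior, z_E, mc_draws, seed)
        log_bf += log_post - log_prior
    if constraints.n_orders:
        p_prior = _order_probability(constraints, prior, mc_draws, seed)
        if p_prior <= 0:
            raise DegenerateHypothesisError(
                f"order region of {constraints.text!r} has zero prior probability"
            )
        p_post = _order_probability(constraints, posterior, mc_draws, seed)
        if p_post <= 0:
            return 0.0
        log_bf += np.log(p_post) - np.log(p_prior)
    return float(np.exp(log_bf))


def _complement_bf(
    complement: Complement, prior: NormalApprox, posterior: NormalApprox,
    mc_draws: int, seed,
) -> float:
    """BF of the complement region: mass outside the union of stated orders."""
    ordered = [c for c in complement.components if c.n_orders > 0]
    if not ordered:
        # only equality hypotheses stated: complement == unconstrained model
        return 1.0
    prior_draws = _draws_or_sample(prior, mc_draws, seed)
    post_draws = _draws_or_sample(posterior, mc_draws, seed + 1)

    def union_mass(draws):
        hit = np.zeros(draws.shape[0], dtype=bool)
        for c in ordered:
            hit |= c.order_satisfied(draws)
        return float(hit.mean())

    p_prior = 1.0 - union_mass(prior_draws)
    if p_prior <= 1e-12:
        raise DegenerateHypothesisError(
            "stated order hypotheses exhaust the parameter space; "
            "the complement has zero prior mass"
        )
    p_post = 1.0 - union_mass(post_draws)
    return p_post / p_prior


def posterior_hypothesis_probs(bf_iu, prior_probs) -> np.ndarray:
    """P(Hi | Y) = BF_iu P(Hi) / sum_j BF_ju P(Hj)."""
    bf = np.asarray(bf_iu, dtype=float)
    pr = np.asarray(prior_probs, dtype=float)
    if bf.shape != pr.shape:
        raise ValueError("bf_iu and prior_probs must have equal length")
    if not np.isclose(pr.sum(), 1.0):
        raise ValueError("prior probabilities must sum to 1")
    num = bf * pr
    if num.sum() <= 0:
        raise FloatingPointError("all Bayes factors vanish; cannot normalize")
    return num / num.sum()


def evidence_matrix(bf_iu) -> np.ndarray:
    """Pairwise Bayes factors BF(Hi, Hj) = BF_iu / BF_ju (unit diagonal)."""
    bf = np.asarray(bf_iu, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        mat = np.outer(bf, 1.0 / bf)
    np.fill_diagonal(mat, 1.0)
    return mat


def manual_test(
    hypothesis_set: HypothesisSet,
    prior: NormalApprox,
    posterior: NormalApprox,
    mc_draws: int = DEFAULT_MC_DRAWS,
    seed=0,
) -> TestResult:
    """Run a manual hypothesis test: BF_iu per hypothesis and the summary."""
    bfs = [
        bf_vs_unconstrained(h, prior, posterior, mc_draws, seed)
        for _, h in hypothesis_set.hypotheses
    ]
    legend = {
        lab: (h.text if isinstance(h, ConstraintSet) else "complement")
        for lab, h in hypothesis_set.hypotheses
    }
    return TestResult(
        labels=hypothesis_set.labels,
        bf_iu=np.array(bfs),
        prior_probs=hypothesis_set.prior_probs,
        legend=legend,
    )


def standard_test(
    prior: NormalApprox,
    posterior: NormalApprox,
    weights=STANDARD_WEIGHTS,
    seed=0,
) -> dict:
    """The default zero/negative/positive test for every correlation.

    For each correlation: H0: rho = 0 via the Savage-Dickey ratio of the
    posterior normal fit against the exact stretched-beta prior marginal on
    the Fisher scale; H-: rho < 0 and H+: rho > 0 via one-sided posterior
    masses against the prior one-sided masses, which are exactly 1/2 by the
    symmetry of the jointly uniform prior.  Prior weights (default 2, 1, 1)
    set the prior hypothesis probabilities.  Returns a mapping parameter
    name -> :class:`TestResult`.
    """
    w = np.asarray(weights, dtype=float)
    if w.shape != (3,) or np.any(w <= 0):
        raise ValueError("standard test needs 3 positive weights")
    prior_probs = w / w.sum()
    if prior.P is None:
        raise ValueError("prior approximation must carry the dimension P")
    prior0 = float(marginal_prior_density_fisher(0.0, prior.P))
    results = {}
    for k, name in enumerate(posterior.names):
        m, s = posterior.mean[k], np.sqrt(posterior.cov[k, k])
        bf0 = stats.norm.pdf(0.0, m, s) / prior0
        bfneg = stats.norm.cdf(0.0, m, s) / 0.5
        bfpos = stats.norm.sf(0.0, m, s) / 0.5
        results[name] = TestResult(
            labels=list(STANDARD_LABELS),
            bf_iu=np.array([bf0, bfneg, bfpos]),
            prior_probs=prior_probs,
            legend=dict(zip(STANDARD_LABELS, (f"{name} = 0", f"{name} < 0", f"{name} > 0"))),
        )
    return results
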