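"""The jointly uniform prior over correlation matrices.

The default prior is flat over the set of positive-definite P x P
correlation matrices.  Its marginal for any single correlation is a
stretched beta(P/2, P/2) distribution on (-1, 1) (Joe, 2006), so adding
variables concentrates each marginal around zero.  Draws are produced by
the onion construction (the LKJ sampler with shape eta = 1, whose density
is exactly flat over the positive-definite set).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .fisher_normal import NormalApprox, fisher_z


@dataclass(frozen=True)
class PriorSpec:
    """Jointly uniform prior for G independent groups of P variables each.

    The marginal stretched-beta shape parameter is alpha = P/2.
    """

    P: int
    G: int = 1

    def __post_init__(self):
        if self.P < 2:
            raise ValueError("need at least 2 variables")
        if self.G < 1:
            raise ValueError("need at least 1 group")

    @property
    def alpha(self) -> float:
        return self.P / 2.0


def sample_uniform_corr(P: int, m: int, seed) -> np.ndarray:
    """Draw ``m`` i.i.d. correlation matrices uniform over the PD set.

    Onion method: grow the matrix one variable at a time, drawing the new
    column as a point in the ellipsoid induced by the current leading block,
    with the radial part beta-distributed so the joint density is constant.
    Returns an array of shape (m, P, P); every draw is symmetric with unit
    diagonal and strictly positive definite.
    """
    if P < 2 or m < 1:
        raise ValueError("need P >= 2 and m >= 1")
    rng = np.random.default_rng(seed)
    R = np.zeros((m, P, P))
    R[:, 0, 0] = R[:, 1, 1] = 1.0
    beta = 1.0 + (P - 2) / 2.0
    r12 = 2.0 * rng.beta(beta, beta, size=m) - 1.0
    R[:, 0, 1] = R[:, 1, 0] = r12
    for k in range(2, P):
        beta -= 0.5
        y = rng.beta(k / 2.0, beta, size=m)  # squared radius
        u = rng.standard_normal((m, k))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        w = np.sqrt(y)[:, None] * u
        L = np.linalg.cholesky(R[:, :k, :k])
        z = np.einsum("mij,mj->mi", L, w)
        R[:, k, :k] = z
        R[:, :k, k] = z
        R[:, k, k] = 1.0
    return R


def marginal_prior_density(rho, P: int):
    """Stretched beta(P/2, P/2) density on (-1, 1) of a single correlation."""
    rho = np.asarray(rho, dtype=float)
    if np.any(np.abs(rho) >= 1):
        raise ValueError("rho must lie strictly inside (-1, 1)")
    return stats.beta.pdf((rho + 1.0) / 2.0, P / 2.0, P / 2.0) / 2.0


def marginal_prior_density_fisher(z, P: int):
    """Prior density of the Fisher-transformed correlation zeta = atanh(rho).

    Change of variables from the stretched beta: d rho / d zeta = 1 - rho^2.
    """
    z = np.asarray(z, dtype=float)
    rho = np.tanh(z)
    return marginal_prior_density(rho, P) * (1.0 - rho**2)


def fit_prior_normal_approx(
    P: int, parameters, m: int = 100_000, seed=1234
) -> NormalApprox:
    """Moment-matched normal approximation of the prior on the Fisher scale.

    Samples ``m`` uniform correlation matrices per group, Fisher-transforms
    every off-diagonal element, and fits a multivariate normal to the draws.
    Groups are independent, so cross-group covariance blocks are exactly
    zero.  The draws themselves are kept on the returned object: downstream
    Bayes-factor code uses them for kernel density estimates of equality
    combinations and for empirical order-region probabilities.

    ``parameters`` is the :class:`~corrbf.data_model.ParameterIndex` whose
    order fixes the draw columns.
    """
    if m < 10_000:
        raise ValueError("need at least 10,000 prior draws for a stable fit")
    G = parameters.n_groups
    K = len(parameters)
    draws = np.empty((m, K))
    rng_seed = np.random.default_rng(seed)
    group_mats = {}
    for g in range(G):
        group_mats[g] = sample_uniform_corr(P, m, rng_seed.integers(2**31))
    for k, (g, i, j) in enumerate(parameters.entries):
        draws[:, k] = fisher_z(group_mats[g][:, i, j])
    mean = draws.mean(axis=0)
    cov = np.atleast_2d(np.cov(draws, rowvar=False))
    # groups are independent by construction: zero the cross-group blocks
    group_of = np.array([e[0] for e in parameters.entries])
    cov[group_of[:, None] != group_of[None, :]] = 0.0
    approx = NormalApprox(
        names=parameters.names, mean=mean, cov=cov, source="prior", draws=draws, P=P
    )
    return approx
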