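"""Fisher transformation and normal approximations on the transformed scale.

Bayes factors are computed from multivariate normal approximations of the
prior and posterior of the Fisher-transformed correlations
zeta = atanh(rho).  The transformation maps (-1, 1) onto the real line and
approximately symmetrizes and variance-stabilizes correlation posteriors,
which makes the normal fit accurate already at moderate sample sizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


def fisher_z(rho):
    """z = atanh(rho), the Fisher transformation; domain (-1, 1)."""
    rho = np.asarray(rho, dtype=float)
    if np.any(np.abs(rho) >= 1):
        raise ValueError("correlation must lie strictly inside (-1, 1)")
    return np.arctanh(rho)


def inverse_fisher_z(z):
    """tanh(z), mapping the Fisher scale back to a correlation."""
    return np.tanh(np.asarray(z, dtype=float))


@dataclass(frozen=True)
class NormalApprox:
    """Multivariate normal fit on the Fisher scale.

    Parameters are ordered as in the originating
    :class:`~corrbf.data_model.ParameterIndex`.  ``draws`` optionally keeps
    the transformed draws the moments were fitted to (prior Monte Carlo
    samples or pooled posterior MCMC draws); Bayes-factor code uses them for
    kernel density estimates and empirical region probabilities.  ``P`` is
    the number of variables per group (sets the stretched-beta marginal of
    the prior).
    """

    names: tuple
    mean: np.ndarray
    cov: np.ndarray
    source: str  # "prior" | "posterior"
    draws: np.ndarray | None = None
    P: int | None = None

    def __post_init__(self):
        mean = np.atleast_1d(np.asarray(self.mean, dtype=float))
        cov = np.atleast_2d(np.asarray(self.cov, dtype=float))
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "cov", cov)
        k = len(self.names)
        if mean.shape != (k,) or cov.shape != (k, k):
            raise ValueError("mean/cov dimensions inconsistent with parameter names")
        if not np.allclose(cov, cov.T):
            raise ValueError("covariance must be symmetric")
        if np.any(np.diag(cov) < 0):
            raise ValueError("negative variance in normal approximation")

    def __len__(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"unknown parameter {name!r}") from None


def fit_posterior_normal_approx(draws) -> NormalApprox:
    """Fit the posterior normal approximation to Fisher-transformed draws.

    ``draws`` is a :class:`~corrbf.posterior_sampler.CorrelationDraws`; all
    chains are pooled after burn-in (convergence should be checked with
    R-hat before trusting the pooled fit).  Raises if any draw is outside
    (-1, 1) or if a parameter's draws are degenerate (zero variance), which
    signals a stuck sampler.
    """
    pooled = draws.pooled()  # (chains*iterations, K) on the correlation scale
    if pooled.shape[0] < 1_000:
        raise ValueError("need at least 1,000 post-burn-in draws")
    if np.any(np.abs(pooled) >= 1):
        raise FloatingPointError("correlation draw outside (-1, 1)")
    z = np.arctanh(pooled)
    spread = np.ptp(z, axis=0)
    if np.any(spread == 0):
        bad = [draws.parameters.names[k] for k in np.flatnonzero(spread == 0)]
        raise FloatingPointError(
            f"degenerate (constant) posterior draws for {bad}; sampler stuck -- "
            "rerun with a smaller nugget"
        )
    mean = z.mean(axis=0)
    cov = np.atleast_2d(np.cov(z, rowvar=False))
    return NormalApprox(
        names=draws.parameters.names,
        mean=mean,
        cov=cov,
        source="posterior",
        draws=z,
        P=draws.parameters.n_variables,
    )
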