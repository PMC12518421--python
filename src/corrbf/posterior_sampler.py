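"""Gibbs sampler for mixed-scale correlation matrices.

Model: each row of the data is a realization of a latent multivariate
normal vector.  Continuous variables are observed directly with free mean
and scale (Jeffreys prior p(mu, sigma) proportional to 1/sigma); ordinal
and binary variables are observed as the category into which a latent
standard-normal score falls relative to a strictly increasing vector of
free thresholds (latent mean 0 and variance 1 for identification; binary
variables have a single threshold).  The latent correlation matrix R per
group carries the jointly uniform prior; with covariates present, each
variable's (latent) mean is a linear function of the covariates with flat
priors on the coefficients, so R collects partial correlations given the
covariates.  Groups are sampled independently.

The sampler cycles latent scores -> thresholds -> nuisance (means, scales,
covariate coefficients) -> correlations.  Each correlation is updated from
its full conditional by discretized inverse-CDF sampling ("griddy Gibbs")
on its support: the interval keeping R positive definite given the other
entries, intersected with (-nugget, nugget).  Because the jointly uniform
prior is flat exactly on that interval, the conditional density is the
latent-data likelihood restricted to the support, which makes the update
testable: with the likelihood switched off the chain must reproduce the
stretched beta(P/2, P/2) marginals of the prior.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .data_model import Dataset, ParameterIndex, name_parameters

DEFAULT_ITERATIONS = 10_000
DEFAULT_CHAINS = 2
DEFAULT_NUGGET = 0.999
DEFAULT_GRID = 200
RHAT_THRESHOLD = 1.05

_TINY = 1e-12


class SamplerError(RuntimeError):
    """Numerical failure inside the Gibbs sampler."""


class ConvergenceWarning(UserWarning):
    """Emitted when R-hat exceeds the convergence threshold."""


@dataclass
class LatentState:
    """Current state of one group's sampler.

    ``W`` holds data-scale values: observed values for continuous variables,
    latent normals for ordinal/binary ones.  ``Z`` caches the standardized
    residuals (W minus the covariate-implied mean, divided by the scale),
    whose rows are modelled as N(0, R).  ``thresholds`` maps the column
    index of each discrete variable to its ordered cutpoint vector.
    """

    W: np.ndarray
    Z: np.ndarray
    R: np.ndarray
    sigma: np.ndarray
    beta: list
    thresholds: dict = field(default_factory=dict)


@dataclass
class CorrelationDraws:
    """Post-burn-in MCMC draws of the correlation parameters.

    ``draws`` has shape (chains, iterations, K) on the correlation scale
    with columns in ``parameters`` order.  ``threshold_draws`` optionally
    stores cutpoint draws as (chains, iterations, T) with ``threshold_names``
    labelling the columns.
    """

    draws: np.ndarray
    parameters: ParameterIndex
    seed: object
    nugget: float
    burnin: int
    threshold_draws: np.ndarray | None = None
    threshold_names: tuple = ()

    def __post_init__(self):
        if self.draws.ndim != 3:
            raise ValueError("draws must be chains x iterations x parameters")
        if np.any(np.abs(self.draws) > self.nugget + _TINY):
            raise ValueError("draw magnitude exceeds the nugget bound")

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def n_iterations(self) -> int:
        return self.draws.shape[1]

    def pooled(self) -> np.ndarray:
        """All chains pooled: (chains*iterations, K) on the correlation scale."""
        return self.draws.reshape(-1, self.draws.shape[2])


def pd_interval(R: np.ndarray, i: int, j: int) -> tuple:
    """Support of correlation (i, j) keeping R positive definite.

    With every other entry fixed, det R is a quadratic in rho_ij with
    negative leading coefficient, and (given the remaining principal minors
    are positive) R is positive definite exactly between the two real
    roots.  The quadratic is recovered from three determinant evaluations.
    """
    def det_at(x):
        M = R.copy()
        M[i, j] = M[j, i] = x
        return np.linalg.det(M)

    d0, dp, dm = det_at(0.0), det_at(0.5), det_at(-0.5)
    a = 2.0 * (dp + dm - 2.0 * d0)
    b = dp - dm
    c = d0
    if a >= -_TINY:  # numerically flat quadratic: should not happen for PD rest
        raise SamplerError("degenerate PD quadratic; corrupted sampler state")
    disc = b * b - 4.0 * a * c
    if disc <= 0:
        raise SamplerError("empty positive-definite support; corrupted state")
    sq = np.sqrt(disc)
    lo, hi = (-b + sq) / (2.0 * a), (-b - sq) / (2.0 * a)
    return max(lo, -1.0), min(hi, 1.0)


def _grid_inverse_cdf(logdens: np.ndarray, grid: np.ndarray, u: float) -> float:
    """Draw from a 1-D density tabulated on a grid (trapezoid CDF)."""
    w = np.exp(logdens - logdens.max())
    cdf = np.concatenate([[0.0], np.cumsum(0.5 * (w[1:] + w[:-1]) * np.diff(grid))])
    total = cdf[-1]
    if not np.isfinite(total) or total <= 0:
        raise SamplerError("degenerate conditional density on grid")
    return float(np.interp(u * total, cdf, grid))


def _truncnorm_draw(mean, sd, lower, upper, rng):
    """Vectorized truncated-normal draws via inverse-CDF, tail-safe."""
    a = stats.norm.cdf((lower - mean) / sd)
    b = stats.norm.cdf((upper - mean) / sd)
    lo = np.minimum(a, b - 1e-12)
    u = rng.uniform(np.clip(lo, 1e-15, None), np.clip(b, None, 1.0 - 1e-15))
    return mean + sd * stats.norm.ppf(u)


class _GroupSampler:
    """All Gibbs updates for one group's rows."""

    def __init__(self, dataset: Dataset, rows: np.ndarray, grid_size: int, nugget: float):
        self.vars = dataset.variables
        self.P = len(self.vars)
        self.Y = dataset.values[rows]
        self.n = len(rows)
        self.nugget = nugget
        self.grid_size = grid_size
        self.pairs = [(e[1], e[2]) for e in name_parameters(dataset).entries if e[0] == 0]
        cov = dataset.covariates[rows] if dataset.covariates is not None else None
        # per-variable design matrix: intercept (continuous only) + covariates
        self.X = []
        for v in self.vars:
            cols = []
            if v.scale == "continuous":
                cols.append(np.ones(self.n))
            if cov is not None:
                cols.append(cov - cov.mean(axis=0))
            self.X.append(np.column_stack(cols) if cols else None)
        self.XtXinv = [
            np.linalg.inv(X.T @ X) if X is not None else None for X in self.X
        ]
        for j, v in enumerate(self.vars):
            if v.scale != "continuous":
                observed = np.unique(self.Y[:, j])
                if len(observed) < 2:
                    raise SamplerError(
                        f"variable {v.name!r} has all observations in one category"
                    )

    # -- initialization ----------------------------------------------------
    def init_state(self, rng) -> LatentState:
        P, n = self.P, self.n
        W = self.Y.astype(float).copy()
        sigma = np.ones(P)
        beta = []
        thresholds = {}
        for j, v in enumerate(self.vars):
            if v.scale == "continuous":
                sigma[j] = self.Y[:, j].std(ddof=1)
                X = self.X[j]
                beta.append(self.XtXinv[j] @ X.T @ self.Y[:, j])
            else:
                K = v.n_categories
                freq = np.array([(self.Y[:, j] == k).mean() for k in range(1, K + 1)])
                cum = np.clip(np.cumsum(freq)[:-1], 0.01, 0.99)
                thresholds[j] = stats.norm.ppf(cum)
                beta.append(
                    np.zeros(self.X[j].shape[1]) if self.X[j] is not None else np.zeros(0)
                )
                # start latent scores at the category-midpoint normal scores
                tau = np.concatenate([[-np.inf], thresholds[j], [np.inf]])
                codes = self.Y[:, j].astype(int)
                lo = np.clip(tau[codes - 1], -4, 4)
                hi = np.clip(tau[codes], -4, 4)
                W[:, j] = 0.5 * (lo + hi) + 0.05 * rng.standard_normal(n)
        state = LatentState(
            W=W, Z=np.zeros((n, P)), R=np.eye(P), sigma=sigma, beta=beta,
            thresholds=thresholds,
        )
        self._refresh_Z(state)
        return state

    def _mean(self, state: LatentState, j: int) -> np.ndarray:
        X = self.X[j]
        if X is None or X.shape[1] == 0:
            return np.zeros(self.n)
        return X @ state.beta[j]

    def _refresh_Z(self, state: LatentState, cols=None):
        for j in cols if cols is not None else range(self.P):
            state.Z[:, j] = (state.W[:, j] - self._mean(state, j)) / state.sigma[j]

    def _conditional(self, state: LatentState, j: int):
        """Mean and variance of Z[:, j] given the other columns under R."""
        idx = [k for k in range(self.P) if k != j]
        sol = np.linalg.solve(state.R[np.ix_(idx, idx)], state.R[idx, j])
        c = state.Z[:, idx] @ sol
        v = float(1.0 - state.R[j, idx] @ sol)
        return c, max(v, _TINY), idx

    # -- Gibbs updates -----------------------------------------------------
    def update_latent_scores(self, state: LatentState, rng):
        """Redraw latent normals for discrete cells from truncated conditionals."""
        for j in state.thresholds:
            tau = np.concatenate([[-np.inf], state.thresholds[j], [np.inf]])
            codes = self.Y[:, j].astype(int)
            c, v, _ = self._conditional(state, j)
            m = self._mean(state, j)
            sd = np.sqrt(v)
            z = _truncnorm_draw(m + c, sd, tau[codes - 1], tau[codes], rng)
            state.W[:, j] = z
            state.Z[:, j] = z - m  # sigma == 1 for discrete variables

    def update_thresholds(self, state: LatentState, rng):
        """Cutpoint Gibbs step: each threshold uniform between order statistics."""
        for j, tau in state.thresholds.items():
            codes = self.Y[:, j].astype(int)
            w = state.W[:, j]
            K = len(tau) + 1
            new = tau.copy()
            for k in range(1, K):
                below = w[codes == k]
                above = w[codes == k + 1]
                lo = below.max() if below.size else (new[k - 2] if k > 1 else -8.0)
                hi = above.min() if above.size else (tau[k] if k < K - 1 else 8.0)
                lo = max(lo, new[k - 2]) if k > 1 else lo
                hi = min(hi, tau[k]) if k < K - 1 else hi
                if hi <= lo:
                    hi = lo + _TINY
                new[k - 1] = rng.uniform(lo, hi)
            state.thresholds[j] = new

    def update_nuisance(self, state: LatentState, rng):
        """Covariate coefficients, means and scales (Jeffreys p ~ 1/sigma)."""
        n = self.n
        for j, v in enumerate(self.vars):
            X = self.X[j]
            c, vv, idx = self._conditional(state, j)
            if X is not None and X.shape[1] > 0:
                # W[:, j] ~ N(X beta + sigma_j * c, sigma_j^2 * vv)
                resid = state.W[:, j] - state.sigma[j] * c
                bhat = self.XtXinv[j] @ X.T @ resid
                cov = state.sigma[j] ** 2 * vv * self.XtXinv[j]
                state.beta[j] = rng.multivariate_normal(bhat, cov)
            if v.scale == "continuous":
                Om = np.linalg.inv(state.R)
                u = state.W[:, j] - self._mean(state, j)
                a = Om[j, j] * float(u @ u)
                self._refresh_Z(state, cols=[j])
                b = float(u @ (state.Z[:, idx] @ Om[idx, j]))
                # p(phi) ~ phi^(n-1) exp(-a phi^2 / 2 - b phi), phi = 1/sigma
                phistar = (-b + np.sqrt(b * b + 4.0 * a * (n - 1))) / (2.0 * a)
                sd = 1.0 / np.sqrt((n - 1) / phistar**2 + a)
                grid = np.linspace(max(phistar - 8 * sd, _TINY), phistar + 8 * sd, 300)
                logdens = (n - 1) * np.log(grid) - 0.5 * a * grid**2 - b * grid
                state.sigma[j] = 1.0 / _grid_inverse_cdf(logdens, grid, rng.uniform())
            self._refresh_Z(state, cols=[j])

    def update_correlations(self, state: LatentState, rng, prior_only: bool = False):
        """Griddy-Gibbs step for every correlation in turn.

        The conditional support is the positive-definiteness interval
        intersected with (-nugget, nugget); on it the jointly uniform
        prior is flat, so the conditional density is the latent-data
        likelihood (constant when ``prior_only``).
        """
        S = None if prior_only else state.Z.T @ state.Z
        for (i, j) in self.pairs:
            lo, hi = pd_interval(state.R, i, j)
            lo = max(lo, -self.nugget) + 1e-9
            hi = min(hi, self.nugget) - 1e-9
            if hi <= lo:
                raise SamplerError("empty correlation support interval")
            if prior_only:
                val = rng.uniform(lo, hi)
            else:
                grid = np.linspace(lo, hi, self.grid_size)
                Rg = np.broadcast_to(state.R, (self.grid_size, self.P, self.P)).copy()
                Rg[:, i, j] = Rg[:, j, i] = grid
                sign, logdet = np.linalg.slogdet(Rg)
                ok = sign > 0
                logdens = np.full(self.grid_size, -np.inf)
                if not ok.any():
                    raise SamplerError("no positive-definite grid point")
                inv = np.linalg.inv(Rg[ok])
                logdens[ok] = -0.5 * self.n * logdet[ok] - 0.5 * np.einsum(
                    "gij,ji->g", inv, S
                )
                logdens[~ok] = logdens[ok].min() - 1e6
                val = _grid_inverse_cdf(logdens, grid, rng.uniform())
            state.R[i, j] = state.R[j, i] = val

    def sweep(self, state: LatentState, rng):
        if state.thresholds:
            self.update_latent_scores(state, rng)
            self.update_thresholds(state, rng)
        self.update_nuisance(state, rng)
        self.update_correlations(state, rng)


def run_mcmc(
    dataset: Dataset,
    iterations: int = DEFAULT_ITERATIONS,
    chains: int = DEFAULT_CHAINS,
    burnin: int | None = None,
    nugget: float = DEFAULT_NUGGET,
    seed=None,
    grid_size: int = DEFAULT_GRID,
) -> CorrelationDraws:
    """Sample the per-group correlation matrices of a dataset.

    Returns post-burn-in draws from all chains; burn-in defaults to 20% of
    ``iterations``.  ``nugget`` truncates every correlation's conditional
    support to (-nugget, nugget), which keeps the sampler out of the
    degenerate corners near |rho| = 1 at the price of a slight shrinkage
    toward zero; lower it (.995, .99, ...) only to resolve convergence
    problems.
    """
    if iterations < 1_000:
        raise ValueError("need at least 1,000 iterations")
    if not 0.9 <= nugget <= 0.999:
        raise ValueError("nugget must lie in [0.9, 0.999]")
    if burnin is None:
        burnin = iterations // 5
    params = name_parameters(dataset)
    group_rows = dataset.group_indices()
    samplers = [
        _GroupSampler(dataset, rows, grid_size, nugget) for rows in group_rows.values()
    ]
    K = len(params)
    draws = np.empty((chains, iterations, K))

    thr_names = []
    for g, sampler in enumerate(samplers):
        suffix = f"_in_g{g + 1}" if len(samplers) > 1 else ""
        for j, v in enumerate(sampler.vars):
            if v.scale != "continuous":
                thr_names += [
                    f"{v.name}{suffix}_tau{k + 1}" for k in range(v.n_categories - 1)
                ]
    thr_draws = np.empty((chains, iterations, len(thr_names))) if thr_names else None

    seed_seq = np.random.SeedSequence(seed)
    for c, child in enumerate(seed_seq.spawn(chains)):
        rng = np.random.default_rng(child)
        states = [s.init_state(rng) for s in samplers]
        for t in range(burnin + iterations):
            col = 0
            tcol = 0
            for sampler, state in zip(samplers, states):
                sampler.sweep(state, rng)
                if t >= burnin:
                    for (i, j) in sampler.pairs:
                        draws[c, t - burnin, col] = state.R[i, j]
                        col += 1
                    if thr_draws is not None:
                        for jv in sorted(state.thresholds):
                            tau = state.thresholds[jv]
                            thr_draws[c, t - burnin, tcol:tcol + len(tau)] = tau
                            tcol += len(tau)
                elif thr_draws is not None:
                    tcol += sum(len(v) for v in state.thresholds.values())
    return CorrelationDraws(
        draws=draws,
        parameters=params,
        seed=seed,
        nugget=nugget,
        burnin=burnin,
        threshold_draws=thr_draws,
        threshold_names=tuple(thr_names),
    )


def sample_prior_gibbs(
    P: int, iterations: int, chains: int = 1, nugget: float = DEFAULT_NUGGET,
    seed=None, thin: int = 1,
) -> np.ndarray:
    """Prior-only Gibbs run: the correlation update with the likelihood off.

    Returns pooled draws of shape (chains * iterations // thin, P(P-1)/2).
    The stationary distribution is the jointly uniform prior truncated to
    per-correlation magnitude < nugget, so each marginal must match the
    stretched beta(P/2, P/2) distribution (up to the nugget truncation).
    """
    pairs = [(i, j) for j in range(P) for i in range(j + 1, P)]
    out = []
    seed_seq = np.random.SeedSequence(seed)
    for child in seed_seq.spawn(chains):
        rng = np.random.default_rng(child)
        R = np.eye(P)
        for t in range(iterations):
            for (i, j) in pairs:
                lo, hi = pd_interval(R, i, j)
                lo, hi = max(lo, -nugget), min(hi, nugget)
                R[i, j] = R[j, i] = rng.uniform(lo, hi)
            if t % thin == 0:
                out.append([R[i, j] for (i, j) in pairs])
    return np.asarray(out)


def compute_rhat(draws: CorrelationDraws) -> dict:
    """Split-chain potential-scale-reduction statistic per correlation.

    Warns (:class:`ConvergenceWarning`) for any value above 1.05; requires
    at least two chains.
    """
    if draws.n_chains < 2:
        raise ValueError("R-hat needs at least 2 chains")
    import arviz as az

    result = {}
    for k, name in enumerate(draws.parameters.names):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # arviz deprecation chatter
            val = float(az.rhat(np.ascontiguousarray(draws.draws[:, :, k]), method="split"))
        result[name] = val
        if val > RHAT_THRESHOLD:
            warnings.warn(
                f"R-hat = {val:.3f} > {RHAT_THRESHOLD} for {name!r}: chains have "
                "not converged; consider a smaller nugget or more iterations",
                ConvergenceWarning,
                stacklevel=2,
            )
    return result


def export_traceplot_data(draws: CorrelationDraws, parameter: str):
    """Plot-ready trace series: DataFrame (chain, iteration, value)."""
    import pandas as pd

    if draws.n_iterations == 0:
        raise ValueError("no draws to export")
    k = draws.parameters.names.index(parameter) if parameter in draws.parameters.names else None
    if k is None:
        raise KeyError(
            f"unknown parameter {parameter!r}; valid: {', '.join(draws.parameters.names)}"
        )
    frames = []
    for c in range(draws.n_chains):
        frames.append(
            pd.DataFrame(
                {
                    "chain": c + 1,
                    "iteration": np.arange(1, draws.n_iterations + 1),
                    "value": draws.draws[c, :, k],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
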