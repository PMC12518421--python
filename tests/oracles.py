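"""Independent numerical oracles used by the tests.

These deliberately avoid the package's Savage-Dickey / MCMC machinery:
the posterior of a single product-moment correlation and the marginal
likelihoods of the zero/nonzero hypotheses are computed by direct grid
integration of the bivariate-normal likelihood (means integrated
analytically, scales on a log grid, uniform prior on rho).
"""

import numpy as np


def _log_marginal_given_rho(S, n, rho, log_scales):
    """log integral over (sigma1, sigma2) of the mean-integrated likelihood."""
    ls = np.exp(log_scales)
    s1 = ls[:, None]
    s2 = ls[None, :]
    tr = (S[0, 0] / s1**2 + S[1, 1] / s2**2 - 2 * rho * S[0, 1] / (s1 * s2)) / (
        1 - rho**2
    )
    # |Sigma|^{-(n-1)/2} exp(-tr/2) x Jeffreys 1/(s1 s2) x log-grid Jacobian s1 s2
    L = -(n - 1) * np.log(s1 * s2) - (n - 1) / 2 * np.log1p(-rho**2) - 0.5 * tr
    m = L.max()
    return m + np.log(np.exp(L - m).sum())


def _scale_grid(Y, points=200):
    sd = Y.std(axis=0, ddof=1)
    lo, hi = np.log(sd.min() * 0.25), np.log(sd.max() * 4.0)
    return np.linspace(lo, hi, points)


def grid_posterior(Y, rho_points=801):
    """Marginal posterior density of rho on a grid: (rhos, density)."""
    Yc = Y - Y.mean(axis=0)
    S = Yc.T @ Yc
    n = len(Y)
    rhos = np.linspace(-0.9995, 0.9995, rho_points)
    logs = _scale_grid(Y)
    vals = np.array([_log_marginal_given_rho(S, n, r, logs) for r in rhos])
    dens = np.exp(vals - vals.max())
    dens /= np.trapezoid(dens, rhos)
    return rhos, dens


def grid_posterior_moments(Y):
    """Posterior mean/sd of rho and of atanh(rho) by grid integration."""
    rhos, dens = grid_posterior(Y)
    mean = np.trapezoid(rhos * dens, rhos)
    sd = np.sqrt(np.trapezoid((rhos - mean) ** 2 * dens, rhos))
    z = np.arctanh(rhos)
    mz = np.trapezoid(z * dens, rhos)
    sz = np.sqrt(np.trapezoid((z - mz) ** 2 * dens, rhos))
    return mean, sd, mz, sz


def grid_bf10(Y):
    """Exact BF of 'rho free, uniform(-1,1)' against 'rho = 0'."""
    Yc = Y - Y.mean(axis=0)
    S = Yc.T @ Yc
    n = len(Y)
    logs = _scale_grid(Y)
    m0 = _log_marginal_given_rho(S, n, 0.0, logs)
    rhos = np.linspace(-0.9995, 0.9995, 801)
    vals = np.array([_log_marginal_given_rho(S, n, r, logs) for r in rhos])
    mmax = vals.max()
    m1 = mmax + np.log(np.trapezoid(np.exp(vals - mmax), rhos) * 0.5)
    return float(np.exp(m1 - m0))
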