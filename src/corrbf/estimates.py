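"""Posterior summaries, the classical reference p value, evidence labels."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

#: Kass-Raftery style cutoffs between qualitative evidence categories.
EVIDENCE_CUTOFFS = (1.0, 3.0, 20.0, 150.0)
EVIDENCE_LABELS = (
    "no preference",
    "weak evidence",
    "positive evidence",
    "strong evidence",
    "very strong evidence",
)


def summarize(draws) -> pd.DataFrame:
    """Posterior mean, median and central 95% interval per correlation.

    Pools all chains after burn-in; quantiles use linear interpolation of
    the order statistics.  Returns a DataFrame indexed by parameter name
    with columns mean / median / lower / upper (correlation scale).
    """
    pooled = draws.pooled()
    if pooled.shape[0] < 1_000:
        raise ValueError("need at least 1,000 draws to summarize")
    q = np.quantile(pooled, [0.025, 0.5, 0.975], axis=0)
    return pd.DataFrame(
        {
            "mean": pooled.mean(axis=0),
            "median": q[1],
            "lower": q[0],
            "upper": q[2],
        },
        index=list(draws.parameters.names),
    )


def classical_p_pearson(r: float, n: int) -> float:
    """Two-sided p value for a sample product-moment correlation.

    Uses the exact null distribution via t = r sqrt(n-2) / sqrt(1-r^2)
    with n - 2 degrees of freedom.  Provided as the classical reference
    for the continuous case only.
    """
    if not np.abs(r) < 1:
        raise ValueError("need |r| < 1")
    if n < 4:
        raise ValueError("need n >= 4")
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return float(2.0 * stats.t.sf(abs(t), n - 2))


def label_evidence(bf: float) -> str:
    """Qualitative label for a Bayes factor (direction-aware).

    Cutoffs 1 / 3 / 20 / 150: e.g. 8.653 is "positive evidence", 163.8 is
    "very strong evidence".  Values below 1 are labelled for the reciprocal
    hypothesis.
    """
    if not bf > 0:
        raise ValueError("Bayes factor must be positive")
    direction = ""
    if bf < 1.0:
        bf = 1.0 / bf
        direction = " (for the other hypothesis)"
    if np.isclose(bf, 1.0):
        return EVIDENCE_LABELS[0]
    for cut, lab in zip(EVIDENCE_CUTOFFS[1:], EVIDENCE_LABELS[1:-1]):
        if bf <= cut:
            return lab + direction
    return EVIDENCE_LABELS[-1] + direction
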