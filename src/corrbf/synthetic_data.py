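"""Synthetic datasets with exactly specified sample correlations.

The worked examples in the literature on default Bayesian correlation
tests are defined by their *sample* correlations (the raw data are not
public), so fixtures are generated to match those sample correlations
exactly: a standard-normal table is empirically whitened (making its
sample correlation the identity) and then recolored by the Cholesky
factor of the target matrix.  Continuous columns can afterwards be
discretized with stated thresholds to produce ordinal and binary
versions; discretization intervals are left-closed/right-open, so a value
equal to a threshold falls in the upper category.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_model import Dataset, VariableSpec

#: WHO-style BMI category thresholds: severely underweight, underweight,
#: normal, overweight, obese.
BMI_THRESHOLDS = (16.5, 18.5, 25.0, 30.0)
#: Steps/day activity categories: sedentary, low, somewhat, active, highly.
PA_THRESHOLDS = (5000.0, 7500.0, 10000.0, 12500.0)
#: Binary splits: obese-side BMI >= 25, highly-active PA >= 10000.
BMI_BINARY_THRESHOLD = (25.0,)
PA_BINARY_THRESHOLD = (10000.0,)


@dataclass
class SyntheticSpec:
    """Recipe for one exact-correlation fixture."""

    n: int
    target: np.ndarray
    seed: object = None
    names: list = field(default_factory=list)

    def __post_init__(self):
        self.target = np.atleast_2d(np.asarray(self.target, dtype=float))
        P = self.target.shape[0]
        if self.target.shape != (P, P) or not np.allclose(self.target, self.target.T):
            raise ValueError("target must be a symmetric correlation matrix")
        if not np.allclose(np.diag(self.target), 1.0):
            raise ValueError("target must have unit diagonal")
        if np.linalg.eigvalsh(self.target).min() <= 0:
            raise ValueError("target correlation matrix must be positive definite")
        if self.n <= P:
            raise ValueError("need n > P for an exact sample correlation")
        if not self.names:
            self.names = [f"V{j + 1}" for j in range(P)]


def exact_corr_values(n: int, target, seed=None) -> np.ndarray:
    """n x P array whose sample correlation equals ``target`` exactly.

    Whiten-then-recolor: draw standard normals, center, decorrelate with the
    inverse Cholesky factor of their sample covariance, then recolor with
    the Cholesky factor of the target.  Different seeds give different data
    with identical sample correlation matrices.
    """
    target = np.atleast_2d(np.asarray(target, dtype=float))
    P = target.shape[0]
    if n <= P:
        raise ValueError("need n > P")
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, P))
    X -= X.mean(axis=0)
    L = np.linalg.cholesky(np.cov(X, rowvar=False))
    X = X @ np.linalg.inv(L).T
    X = X @ np.linalg.cholesky(target).T
    # sample covariance (ddof=1) of X is now exactly `target`
    return X


def exact_corr_data(spec: SyntheticSpec) -> Dataset:
    """Continuous :class:`Dataset` realizing a :class:`SyntheticSpec`."""
    X = exact_corr_values(spec.n, spec.target, spec.seed)
    return Dataset(
        variables=[VariableSpec(name, "continuous") for name in spec.names],
        values=X,
    )


def discretize(values, thresholds) -> np.ndarray:
    """Ordinal codes 1..K from strictly increasing thresholds.

    Code k means the value lies in [tau_{k-1}, tau_k) with tau_0 = -inf and
    tau_K = +inf; a value equal to a threshold goes to the upper category.
    """
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any(np.diff(thresholds) <= 0):
        raise ValueError("thresholds must be strictly increasing")
    return np.searchsorted(thresholds, np.asarray(values, dtype=float), side="right") + 1.0


def _scaled(col, mean, sd):
    return mean + sd * col


def make_fixture(name: str, seed=None, **kwargs) -> Dataset:
    """Named example fixtures.

    ``bmi_pa``
        n = 44 continuous (bmi, pa) with exact sample r = -0.38, rescaled to
        plausible BMI (mean 24, sd 4) and step-count (mean 9000, sd 2500)
        scales, plus ordinal (K = 5) and binary versions cut at the standard
        category thresholds -> 44 x 6 dataset.
    ``meng``
        n = 15 trivariate (X1, X2, Y) with exact sample correlations
        r(X1, Y) = .63, r(X2, Y) = -.03 and r(X1, X2) = -.19 (the last is
        overridable via ``r_x1x2``).
    ``grouped``
        two independent samples with per-group target correlations
        (``n_groups`` sizes via ``sizes``, targets via ``targets``) stacked
        with a group column.
    """
    if name == "bmi_pa":
        r = kwargs.get("r", -0.38)
        n = kwargs.get("n", 44)
        X = exact_corr_values(n, np.array([[1.0, r], [r, 1.0]]), seed)
        bmi = _scaled(X[:, 0], 24.0, 4.0)
        pa = _scaled(X[:, 1], 9000.0, 2500.0)
        cols = {
            "bmi": bmi,
            "pa": pa,
            "bmi_ord": discretize(bmi, BMI_THRESHOLDS),
            "pa_ord": discretize(pa, PA_THRESHOLDS),
            "bmi_bin": discretize(bmi, BMI_BINARY_THRESHOLD),
            "pa_bin": discretize(pa, PA_BINARY_THRESHOLD),
        }
        variables = [
            VariableSpec("bmi", "continuous"),
            VariableSpec("pa", "continuous"),
            _observed_spec("bmi_ord", cols["bmi_ord"], "ordinal"),
            _observed_spec("pa_ord", cols["pa_ord"], "ordinal"),
            _observed_spec("bmi_bin", cols["bmi_bin"], "binary"),
            _observed_spec("pa_bin", cols["pa_bin"], "binary"),
        ]
        values = np.column_stack([_recode(cols[v.name], v) for v in variables])
        return Dataset(variables=variables, values=values)

    if name == "meng":
        r_x1y = kwargs.get("r_x1y", 0.63)
        r_x2y = kwargs.get("r_x2y", -0.03)
        r_x1x2 = kwargs.get("r_x1x2", -0.19)
        target = np.array(
            [[1.0, r_x1x2, r_x1y], [r_x1x2, 1.0, r_x2y], [r_x1y, r_x2y, 1.0]]
        )
        spec = SyntheticSpec(
            n=kwargs.get("n", 15), target=target, seed=seed, names=["X1", "X2", "Y"]
        )
        return exact_corr_data(spec)

    if name == "grouped":
        sizes = kwargs.get("sizes", (40, 40))
        targets = kwargs.get("targets", (0.4, 0.4))
        labels = kwargs.get("labels", ("g1", "g2"))
        seeds = np.random.SeedSequence(seed).spawn(len(sizes))
        blocks, group = [], []
        for sz, tgt, lab, child in zip(sizes, targets, labels, seeds):
            blocks.append(exact_corr_values(sz, np.array([[1.0, tgt], [tgt, 1.0]]), child))
            group += [lab] * sz
        values = np.vstack(blocks)
        return Dataset(
            variables=[VariableSpec("LBA", "continuous"), VariableSpec("Strength", "continuous")],
            values=values[:, ::-1],  # order (LBA, Strength) -> Strength_with_LBA
            group=np.array(group),
        )

    raise ValueError(f"unknown fixture {name!r}; choose bmi_pa, meng or grouped")


def _observed_spec(name, codes, scale) -> VariableSpec:
    levels = np.unique(codes)
    return VariableSpec(name, scale, tuple(int(v) for v in levels))


def _recode(codes, spec: VariableSpec):
    """Map raw category codes onto consecutive 1..K for observed categories."""
    if spec.scale == "continuous":
        return np.asarray(codes, dtype=float)
    levels = np.asarray(spec.category_labels, dtype=float)
    return np.searchsorted(levels, np.asarray(codes, dtype=float)) + 1.0


def write_fixture_csv(dataset: Dataset, path) -> None:
    """Write a dataset as a CSV readable by :func:`corrbf.data_model.load_table`."""
    import pandas as pd

    df = pd.DataFrame(dataset.values, columns=dataset.variable_names)
    for v in dataset.variables:
        if v.scale != "continuous":
            df[v.name] = df[v.name].astype(int)
    if dataset.group is not None:
        df["group"] = dataset.group
    if dataset.covariates is not None:
        for k, nm in enumerate(dataset.covariate_names):
            df[nm] = dataset.covariates[:, k]
    df.to_csv(path, index=False)
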