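"""Typed tabular data for correlation analysis.

Variables are measured on one of three scales -- continuous, ordinal
(polytomous, 3+ ordered categories), or binary -- and the scale of a pair
determines which latent-normal correlation relates them (product-moment,
polyserial, biserial, polychoric, tetrachoric).  An optional categorical
grouping column splits the rows into independent groups, each with its own
correlation matrix; optional continuous covariates are regressed out so the
analysed correlations are partial correlations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SCALES = ("continuous", "ordinal", "binary")

#: Columns with at most this many distinct integer codes are auto-typed ordinal.
ORDINAL_MAX_LEVELS = 10


class DataError(ValueError):
    """Invalid or degenerate input data."""


@dataclass(frozen=True)
class VariableSpec:
    """One analysis variable: its name, measurement scale and category labels.

    ``category_labels`` is the ordered list of original codes for ordinal and
    binary variables (empty for continuous ones); internally categories are
    re-coded 1..K preserving order.
    """

    name: str
    scale: str
    category_labels: tuple = ()

    def __post_init__(self):
        if self.scale not in SCALES:
            raise DataError(f"unknown scale {self.scale!r} for variable {self.name!r}")
        k = len(self.category_labels)
        if self.scale == "binary" and k != 2:
            raise DataError(f"binary variable {self.name!r} needs exactly 2 categories, got {k}")
        if self.scale == "ordinal" and k < 3:
            raise DataError(f"ordinal variable {self.name!r} needs >=3 categories, got {k}")

    @property
    def n_categories(self) -> int:
        return len(self.category_labels)


@dataclass
class Dataset:
    """Observed data: an n x P value table plus typing, grouping and covariates.

    ``values`` holds continuous reals and ordinal/binary integer codes 1..K.
    ``group`` is a per-row label (``None`` for a single group); ``covariates``
    is an n x C real array (``None`` when absent).
    """

    variables: list
    values: np.ndarray
    group: np.ndarray | None = None
    covariates: np.ndarray | None = None
    covariate_names: list = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise DataError("variable names must be unique")
        if self.values.ndim != 2 or self.values.shape[1] != len(self.variables):
            raise DataError("values must be n x P with one column per variable")
        if not np.isfinite(self.values).all():
            raise DataError("values contain missing/non-finite entries after loading")
        for g, idx in self.group_indices().items():
            if len(idx) < 5:
                raise DataError(f"group {g!r} has fewer than 5 rows")
        for j, v in enumerate(self.variables):
            col = self.values[:, j]
            if v.scale == "continuous":
                if np.ptp(col) == 0:
                    raise DataError(f"variable {v.name!r} is constant")
            else:
                k = v.n_categories
                if not np.isin(col, np.arange(1, k + 1)).all():
                    raise DataError(f"variable {v.name!r} has codes outside 1..{k}")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def n_variables(self) -> int:
        return len(self.variables)

    @property
    def variable_names(self) -> list:
        return [v.name for v in self.variables]

    def group_labels(self) -> list:
        """Distinct group labels ordered by first appearance."""
        if self.group is None:
            return [None]
        seen: dict = {}
        for g in self.group:
            seen.setdefault(g, None)
        return list(seen)

    def group_indices(self) -> dict:
        """Map group label -> row index array (single entry when ungrouped)."""
        if self.group is None:
            return {None: np.arange(self.n)}
        return {g: np.flatnonzero(self.group == g) for g in self.group_labels()}

    @property
    def n_groups(self) -> int:
        return len(self.group_labels())


@dataclass(frozen=True)
class ParameterIndex:
    """Bijective map between correlation-parameter names and (group, pair).

    Parameter names follow ``"<later>_with_<earlier>"`` for the variable pair
    (earlier, later) in the analysis order, i.e. row-with-column of the lower
    triangle.  With G >= 2 groups each name gets a suffix ``"_in_g1"`` ...
    ``"_in_gG"``, groups ordered by first appearance in the data.

    .. note::
       Within a single analysis the later-listed variable always comes first
       in the name: variables (bmi, pa) yield the parameter ``pa_with_bmi``.
    """

    names: tuple
    entries: tuple  # parallel tuple of (group_index, i, j) with i > j

    def __post_init__(self):
        if len(self.names) != len(set(self.names)):
            raise DataError("parameter names must be unique")
        if len(self.names) != len(self.entries):
            raise DataError("names and entries must be parallel")

    def __len__(self) -> int:
        return len(self.names)

    def lookup(self, name: str):
        """Return (group_index, i, j) for a parameter name."""
        try:
            return self.entries[self.names.index(name)]
        except ValueError:
            raise KeyError(
                f"unknown parameter {name!r}; valid names: {', '.join(self.names)}"
            ) from None

    @property
    def n_groups(self) -> int:
        return 1 + max(e[0] for e in self.entries)

    @property
    def n_variables(self) -> int:
        return 1 + max(e[1] for e in self.entries)


def _infer_scale(col: pd.Series) -> str:
    vals = col.dropna().unique()
    if len(vals) <= 2:
        return "binary"
    as_int = np.asarray(vals, dtype=float)
    if np.all(as_int == np.round(as_int)) and len(vals) <= ORDINAL_MAX_LEVELS:
        return "ordinal"
    return "continuous"


def load_table(
    path,
    scales: dict | None = None,
    variables: list | None = None,
    group: str | None = None,
    covariates: list | None = None,
) -> Dataset:
    """Read a delimited table (header row) into a typed :class:`Dataset`.

    Column scales are taken from ``scales`` overrides where given and inferred
    otherwise: <=2 distinct values -> binary, integer codes with <=10 distinct
    values -> ordinal, anything else -> continuous.  Rows with missing values
    are dropped with a logged count; ordinal/binary codes are re-mapped to
    consecutive integers 1..K preserving order.
    """
    df = pd.read_csv(path)
    scales = dict(scales or {})
    if variables is None:
        variables = [c for c in df.columns if c != group and c not in (covariates or [])]
    for req in list(variables) + ([group] if group else []) + list(covariates or []):
        if req not in df.columns:
            raise DataError(f"column {req!r} not found in {path}")

    keep_cols = list(variables) + ([group] if group else []) + list(covariates or [])
    sub = df[keep_cols]
    n_before = len(sub)
    sub = sub.dropna()
    dropped = n_before - len(sub)
    if dropped:
        logger.warning("dropped %d of %d rows with missing values", dropped, n_before)

    specs, columns = [], []
    for name in variables:
        col = sub[name]
        scale = scales.get(name) or _infer_scale(col)
        if scale not in SCALES:
            raise DataError(f"unknown scale override {scale!r} for column {name!r}")
        if scale == "continuous":
            try:
                vals = col.astype(float).to_numpy()
            except (TypeError, ValueError):
                raise DataError(f"non-numeric value in continuous column {name!r}") from None
            if np.ptp(vals) == 0:
                raise DataError(f"column {name!r} is constant")
            specs.append(VariableSpec(name, "continuous"))
            columns.append(vals)
        else:
            levels = np.sort(pd.unique(col))
            codes = np.searchsorted(levels, col.to_numpy()) + 1.0
            specs.append(VariableSpec(name, scale, tuple(levels.tolist())))
            columns.append(codes)
        if name not in scales:
            logger.info("inferred scale %r for column %r", scale, name)

    grp = sub[group].to_numpy() if group else None
    cov = sub[list(covariates)].astype(float).to_numpy() if covariates else None
    return Dataset(
        variables=specs,
        values=np.column_stack(columns),
        group=grp,
        covariates=cov,
        covariate_names=list(covariates or []),
    )


def name_parameters(dataset: Dataset, variable_order: list | None = None) -> ParameterIndex:
    """Build the :class:`ParameterIndex` for a dataset.

    For each unordered variable pair (vA earlier, vB later in
    ``variable_order``) the parameter is named ``"vB_with_vA"``; with G >= 2
    groups names get ``"_in_g{g}"`` suffixes.  Parameters are ordered by
    column-major lower triangle within group, groups outermost.
    """
    if variable_order is None:
        variable_order = dataset.variable_names
    if len(variable_order) != len(set(variable_order)):
        raise DataError("duplicate variable in order")
    if len(variable_order) < 2:
        raise DataError("need at least 2 variables to form a correlation")
    unknown = set(variable_order) - set(dataset.variable_names)
    if unknown:
        raise DataError(f"unknown variables in order: {sorted(unknown)}")

    n_groups = dataset.n_groups
    names, entries = [], []
    for g in range(n_groups):
        suffix = f"_in_g{g + 1}" if n_groups > 1 else ""
        for j, earlier in enumerate(variable_order):
            for i in range(j + 1, len(variable_order)):
                later = variable_order[i]
                names.append(f"{later}_with_{earlier}{suffix}")
                entries.append((g, i, j))
    return ParameterIndex(names=tuple(names), entries=tuple(entries))
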