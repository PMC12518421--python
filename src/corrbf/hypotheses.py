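"""Constrained hypotheses on named correlation parameters.

A hypothesis is a conjunction of equality and order constraints over the
correlation parameters, written as text, e.g. ``"pa_with_bmi = 0"``,
``"Y_with_X1 > Y_with_X2"`` or ``"r > -0.1 & r < 0.1"``.  Chains such as
``"a > b > 0"`` expand pairwise.  Each parsed hypothesis becomes a pair of
linear systems: R_E theta = r_E (equalities) and R_O theta > r_O (orders),
where theta is the parameter vector.  A set of hypotheses can be closed
with the complement hypothesis, covering the parameter region not claimed
by any stated order constraint; prior weights are normalized into prior
hypothesis probabilities.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .data_model import ParameterIndex


class HypothesisError(ValueError):
    """Malformed or infeasible hypothesis specification."""


@dataclass
class ConstraintSet:
    """Linear equality/order constraint systems over the parameter vector."""

    names: tuple
    R_E: np.ndarray  # (mE, K)
    r_E: np.ndarray  # (mE,)
    R_O: np.ndarray  # (mO, K)
    r_O: np.ndarray  # (mO,)
    text: str = ""

    def __post_init__(self):
        K = len(self.names)
        self.R_E = np.atleast_2d(np.asarray(self.R_E, dtype=float)).reshape(-1, K)
        self.R_O = np.atleast_2d(np.asarray(self.R_O, dtype=float)).reshape(-1, K)
        self.r_E = np.asarray(self.r_E, dtype=float).reshape(-1)
        self.r_O = np.asarray(self.r_O, dtype=float).reshape(-1)
        if len(self.r_E) != self.R_E.shape[0] or len(self.r_O) != self.R_O.shape[0]:
            raise HypothesisError("constraint matrix/vector shapes disagree")
        if self.n_equalities:
            if np.linalg.matrix_rank(self.R_E) < self.n_equalities:
                # rank-deficient: either redundant or contradictory rows
                sol, *_ = np.linalg.lstsq(self.R_E, self.r_E, rcond=None)
                if not np.allclose(self.R_E @ sol, self.r_E, atol=1e-10):
                    raise HypothesisError(f"contradictory equalities in {self.text!r}")
                raise HypothesisError(f"redundant equality rows in {self.text!r}")

    @property
    def n_equalities(self) -> int:
        return self.R_E.shape[0]

    @property
    def n_orders(self) -> int:
        return self.R_O.shape[0]

    @property
    def is_unconstrained(self) -> bool:
        return self.n_equalities == 0 and self.n_orders == 0

    def order_satisfied(self, theta: np.ndarray) -> np.ndarray:
        """Boolean mask of sample points satisfying every order constraint."""
        theta = np.atleast_2d(theta)
        if self.n_orders == 0:
            return np.ones(theta.shape[0], dtype=bool)
        return np.all(theta @ self.R_O.T > self.r_O, axis=1)


#: Marker object standing for the complement hypothesis.
@dataclass(frozen=True)
class Complement:
    """The parameter region not claimed by any stated order hypothesis.

    Its prior/posterior mass is one minus the mass of the union of the
    stated order-constrained regions (equality hypotheses are null sets).
    When the only stated hypothesis is a single equality, the complement is
    the ordinary two-sided alternative.
    """

    components: tuple  # the stated ConstraintSets it complements


@dataclass
class HypothesisSet:
    """Labelled hypotheses with prior weights and probabilities."""

    hypotheses: list  # of (label, ConstraintSet | Complement)
    prior_weights: np.ndarray
    prior_probs: np.ndarray = field(init=False)

    def __post_init__(self):
        self.prior_weights = np.asarray(self.prior_weights, dtype=float)
        if len(self.prior_weights) != len(self.hypotheses):
            raise HypothesisError("one prior weight per hypothesis required")
        self.prior_probs = prior_probs_from_weights(self.prior_weights)

    @property
    def labels(self) -> list:
        return [lab for lab, _ in self.hypotheses]


_COMPARE = re.compile(r"(=|<|>)")
_NUMBER = re.compile(r"^[+-]?(\d+\.?\d*|\.\d+)$")


def _term(token: str, parameters: ParameterIndex):
    """A parsed side of a comparison: (coefficient row, constant)."""
    token = token.strip()
    K = len(parameters)
    if _NUMBER.match(token):
        return np.zeros(K), float(token)
    if token in parameters.names:
        row = np.zeros(K)
        row[parameters.names.index(token)] = 1.0
        return row, 0.0
    raise HypothesisError(
        f"unknown parameter {token!r}; valid names: {', '.join(parameters.names)}"
    )


def parse(text: str, parameters: ParameterIndex) -> ConstraintSet:
    """Parse one hypothesis string into a :class:`ConstraintSet`.

    Grammar: comparisons of parameter names and numeric literals with
    ``=``, ``<``, ``>``; chained comparisons expand pairwise; ``&`` joins
    constraints conjunctively.  ``a < b`` rows are stored as ``b - a > 0``.
    """
    if not text or not text.strip():
        raise HypothesisError("empty hypothesis string")
    RE, rE, RO, rO = [], [], [], []
    for clause in text.split("&"):
        parts = [p for p in _COMPARE.split(clause) if p.strip()]
        if len(parts) < 3 or len(parts) % 2 == 0:
            raise HypothesisError(f"cannot parse clause {clause.strip()!r}")
        for k in range(0, len(parts) - 2, 2):
            left, op, right = parts[k], parts[k + 1], parts[k + 2]
            lrow, lconst = _term(left, parameters)
            rrow, rconst = _term(right, parameters)
            row = lrow - rrow
            const = rconst - lconst
            if not row.any():
                raise HypothesisError(
                    f"clause {clause.strip()!r} involves no parameters"
                )
            if op == "=":
                RE.append(row), rE.append(const)
            elif op == ">":
                RO.append(row), rO.append(const)
            else:  # '<' : negate into '>'
                RO.append(-row), rO.append(-const)
    K = len(parameters)
    return ConstraintSet(
        names=parameters.names,
        R_E=np.array(RE).reshape(-1, K),
        r_E=np.array(rE),
        R_O=np.array(RO).reshape(-1, K),
        r_O=np.array(rO),
        text=" & ".join(c.strip() for c in text.split("&")),
    )


def render(constraints: ConstraintSet) -> str:
    """Canonical text form of a constraint set (round-trips through parse)."""
    return constraints.text


def build_complement(hypotheses) -> Complement:
    """Complement marker for a list of stated :class:`ConstraintSet`.

    The complement region excludes the union of the stated order regions;
    purely equality-constrained hypotheses contribute measure zero.  Its
    mass is evaluated by the Bayes-factor code from prior/posterior draws;
    if the stated order regions already exhaust the space the complement
    has (near) zero prior mass and testing it raises there.
    """
    hypotheses = tuple(hypotheses)
    if not hypotheses:
        raise HypothesisError("complement requires at least one stated hypothesis")
    for h in hypotheses:
        if not isinstance(h, ConstraintSet):
            raise HypothesisError("complement components must be ConstraintSets")
    return Complement(components=hypotheses)


def prior_probs_from_weights(weights) -> np.ndarray:
    """Normalize positive weights into prior hypothesis probabilities."""
    w = np.asarray(weights, dtype=float)
    if w.ndim != 1 or len(w) == 0:
        raise HypothesisError("weights must be a nonempty vector")
    if np.any(w <= 0):
        raise HypothesisError("prior weights must be strictly positive")
    return w / w.sum()
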