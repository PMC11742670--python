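"""Fuzzy-rough-set feature selection for potency (IC50) decision tables.

A feature subset induces a graded similarity relation between compounds;
decision classes (potency bands) are approximated from below and above by
that relation.  The fraction of compounds confidently assignable to a band
— the dependency degree γ — scores the subset, and a greedy forward search
(QuickReduct) selects a reduct: a small subset whose γ matches the full
descriptor set's.

Construction used throughout:

* per-feature similarity  r_a(x, y) = 1 − |a(x) − a(y)| / range(a)
* aggregation across a subset by the minimum t-norm
* lower approximation with the Łukasiewicz implicator
  I(r, s) = min(1, 1 − r + s); upper approximation with the min t-norm.

With 0/1 similarities and crisp decision classes these operators reduce
exactly to the classical rough-set approximations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np

from .chem_io import DescriptorTable

__all__ = [
    "FuzzyRelation",
    "FuzzySet",
    "ReductResult",
    "attribute_similarity",
    "subset_relation",
    "lower_approx",
    "upper_approx",
    "fuzzify_decision",
    "dependency_degree",
    "quickreduct",
    "brute_force_reduct",
]


@dataclass(frozen=True)
class FuzzyRelation:
    """Reflexive symmetric matrix of pairwise similarity degrees in [0, 1]."""

    matrix: np.ndarray
    subset: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("relation matrix must be square")
        if not np.all(np.diag(m) == 1.0):
            raise ValueError("relation must be reflexive (unit diagonal)")
        if not np.array_equal(m, m.T):
            raise ValueError("relation must be symmetric")
        if m.size and (m.min() < 0 or m.max() > 1):
            raise ValueError("relation entries must lie in [0, 1]")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


@dataclass(frozen=True)
class FuzzySet:
    """Membership vector over the compound universe."""

    membership: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        m = np.asarray(self.membership, dtype=float)
        object.__setattr__(self, "membership", m)
        if m.ndim != 1:
            raise ValueError("membership must be a vector")
        if m.size and (m.min() < 0 or m.max() > 1):
            raise ValueError("memberships must lie in [0, 1]")

    @property
    def n(self) -> int:
        return self.membership.shape[0]


@dataclass
class ReductResult:
    """Outcome of a reduct search: selected features plus the γ trace."""

    selected: list[str]
    gamma_trace: list[float]
    gamma_full: float
    tolerance: float
    universe: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.selected)) != len(self.selected):
            raise ValueError("selected features must be unique")
        if any(b < a - 1e-12 for a, b in zip(self.gamma_trace, self.gamma_trace[1:])):
            raise ValueError("gamma_trace must be non-decreasing")

    @property
    def gamma(self) -> float:
        return self.gamma_trace[-1] if self.gamma_trace else 0.0

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "selected": self.selected,
                "gamma_trace": self.gamma_trace,
                "gamma_full": self.gamma_full,
                "tolerance": self.tolerance,
                "universe": self.universe,
            },
            indent=2,
            sort_keys=True,
        )
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload

    @classmethod
    def from_json(cls, text: str) -> "ReductResult":
        d = json.loads(text)
        return cls(d["selected"], d["gamma_trace"], d["gamma_full"], d["tolerance"],
                   d.get("universe", []))


# ---------------------------------------------------------------------------
# Similarity relations
# ---------------------------------------------------------------------------

def attribute_similarity(
    values: np.ndarray, i: int, j: int, value_range: float | None = None
) -> float:
    """Similarity of objects i and j under one attribute: 1 − |Δ| / range.

    ``value_range`` defaults to the observed column range; a zero range
    (constant attribute) yields similarity 1 for every pair.
    """
    values = np.asarray(values, dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("attribute values must be finite")
    rng = float(values.max() - values.min()) if value_range is None else float(value_range)
    if rng == 0.0:
        return 1.0
    return float(1.0 - abs(values[i] - values[j]) / rng)


def _similarity_matrix(column: np.ndarray) -> np.ndarray:
    rng = float(column.max() - column.min())
    if rng == 0.0:
        return np.ones((column.size, column.size))
    d = np.abs(column[:, None] - column[None, :]) / rng
    return 1.0 - d


def subset_relation(table: DescriptorTable, subset: Sequence[str]) -> FuzzyRelation:
    """Min-t-norm aggregation of per-feature similarities over ``subset``.

    The empty subset induces the all-ones relation (every pair fully
    indiscernible) by convention.
    """
    unknown = [s for s in subset if s not in table.feature_names]
    if unknown:
        raise KeyError(f"unknown feature name(s): {', '.join(unknown)}")
    n = table.n_compounds
    m = np.ones((n, n))
    for name in subset:
        m = np.minimum(m, _similarity_matrix(table.column(name)))
    np.fill_diagonal(m, 1.0)
    return FuzzyRelation(m, tuple(subset))


# ---------------------------------------------------------------------------
# Approximation operators
# ---------------------------------------------------------------------------

def lower_approx(relation: FuzzyRelation, a: FuzzySet) -> FuzzySet:
    """Fuzzy-rough lower approximation, Łukasiewicz implicator.

    membership(x) = inf_y I(R(x, y), A(y)) with I(r, s) = min(1, 1 − r + s).
    In the crisp case this is exactly "x belongs iff its whole class lies
    inside A".
    """
    if relation.n != a.n:
        raise ValueError(f"dimension mismatch: relation n={relation.n}, set n={a.n}")
    imp = np.minimum(1.0, 1.0 - relation.matrix + a.membership[None, :])
    return FuzzySet(imp.min(axis=1), label=a.label)


def upper_approx(relation: FuzzyRelation, a: FuzzySet) -> FuzzySet:
    """Fuzzy-rough upper approximation, min t-norm.

    membership(x) = sup_y T(R(x, y), A(y)) with T = min.  In the crisp case:
    "x belongs iff its class meets A".
    """
    if relation.n != a.n:
        raise ValueError(f"dimension mismatch: relation n={relation.n}, set n={a.n}")
    t = np.minimum(relation.matrix, a.membership[None, :])
    return FuzzySet(t.max(axis=1), label=a.label)


# ---------------------------------------------------------------------------
# Decision fuzzification
# ---------------------------------------------------------------------------

_BIN_LABELS_3 = ("potent", "moderate", "weak")  # ascending IC50


def fuzzify_decision(
    targets: np.ndarray, bins: int = 3, method: str = "crisp"
) -> list[FuzzySet]:
    """Turn continuous IC50 values into decision classes.

    ``method="crisp"`` (default) cuts the targets at quantile edges into
    ``bins`` ordered potency bands, returned as 0/1 sets that partition the
    universe.  ``method="fuzzy"`` instead returns one fuzzy similarity class
    per compound (membership of y in x's class = 1 − |y_x − y| / range),
    which needs no binning and tolerates ties.
    """
    y = np.asarray(targets, dtype=float)
    if y.ndim != 1 or y.size < 3:
        raise ValueError("targets must be a vector of length >= 3")
    if not np.isfinite(y).all():
        raise ValueError("targets must be finite")

    if method == "fuzzy":
        sim = _similarity_matrix(y)
        return [FuzzySet(sim[i], label=f"~{i}") for i in range(y.size)]
    if method != "crisp":
        raise ValueError(f"unknown fuzzification method {method!r}")

    if np.unique(y).size < bins:
        raise ValueError(
            f"only {np.unique(y).size} distinct target value(s) for {bins} bins; "
            "use method='fuzzy' instead"
        )
    edges = np.quantile(y, [k / bins for k in range(1, bins)])
    assignment = np.searchsorted(edges, y, side="left")  # value == edge -> lower bin
    labels = (
        _BIN_LABELS_3 if bins == 3 else tuple(f"band{k}" for k in range(bins))
    )
    sets = []
    for k in range(bins):
        sets.append(FuzzySet((assignment == k).astype(float), label=labels[k]))
    return sets


# ---------------------------------------------------------------------------
# Dependency degree and reduct search
# ---------------------------------------------------------------------------

def _gamma_from_matrix(matrix: np.ndarray, decision: Sequence[FuzzySet]) -> float:
    pos = np.zeros(matrix.shape[0])
    for d in decision:
        imp = np.minimum(1.0, 1.0 - matrix + d.membership[None, :])
        pos = np.maximum(pos, imp.min(axis=1))
    return float(pos.mean())


def dependency_degree(
    table: DescriptorTable, subset: Sequence[str], decision: Sequence[FuzzySet]
) -> float:
    """γ(subset): mean over compounds of the fuzzy positive-region membership.

    positive region(x) = max over decision classes of the lower-approximation
    membership of x; γ = Σ_x pos(x) / n ∈ [0, 1].
    """
    if not decision:
        raise ValueError("decision list must be non-empty")
    if any(d.n != table.n_compounds for d in decision):
        raise ValueError("decision sets must share n with the table")
    rel = subset_relation(table, subset)
    return _gamma_from_matrix(rel.matrix, decision)


def quickreduct(
    table: DescriptorTable,
    decision: Sequence[FuzzySet],
    tolerance: float = 1e-6,
) -> ReductResult:
    """Greedy forward selection of a feature reduct by dependency degree.

    Starting empty, repeatedly add the feature with the largest γ gain
    (ties broken by lexicographically smallest name) until γ reaches the
    full set's γ minus ``tolerance``, or no feature yields a positive gain.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    if not np.isfinite(table.values).all():
        raise ValueError("table values must be finite")
    if not decision:
        raise ValueError("decision list must be non-empty")
    names = sorted(table.feature_names)
    sim = {n: _similarity_matrix(table.column(n)) for n in names}
    n = table.n_compounds

    gamma_full = _gamma_from_matrix(subset_relation(table, table.feature_names).matrix, decision)
    current = np.ones((n, n))
    gamma_now = _gamma_from_matrix(current, decision)
    selected: list[str] = []
    trace: list[float] = []

    while gamma_now < gamma_full - tolerance:
        best_name, best_gamma = None, gamma_now
        for name in names:
            if name in selected:
                continue
            g = _gamma_from_matrix(np.minimum(current, sim[name]), decision)
            if g > best_gamma + 1e-15:
                best_name, best_gamma = name, g
        if best_name is None:
            break
        selected.append(best_name)
        current = np.minimum(current, sim[best_name])
        gamma_now = best_gamma
        trace.append(gamma_now)

    return ReductResult(selected, trace, gamma_full, tolerance,
                        universe=list(table.feature_names))


def brute_force_reduct(
    table: DescriptorTable, decision: Sequence[FuzzySet]
) -> list[tuple[str, ...]]:
    """Enumerate every minimal feature subset matching the full set's γ.

    Exhaustive test oracle: subsets are visited in increasing size; a subset
    qualifies when its γ is within 1e−12 of the full set's, and is minimal
    when no qualifying proper subset exists.  Refuses tables with more than
    12 features.
    """
    nf = table.n_features
    if nf > 12:
        raise ValueError(f"brute_force_reduct limited to 12 features, got {nf}")
    if not decision:
        raise ValueError("decision list must be non-empty")
    names = sorted(table.feature_names)
    sim = {n: _similarity_matrix(table.column(n)) for n in names}
    gamma_full = _gamma_from_matrix(
        subset_relation(table, table.feature_names).matrix, decision
    )

    def gamma_of(subset: tuple[str, ...]) -> float:
        m = np.ones((table.n_compounds,) * 2)
        for s in subset:
            m = np.minimum(m, sim[s])
        return _gamma_from_matrix(m, decision)

    minimal: list[tuple[str, ...]] = []
    for size in range(0, nf + 1):
        for combo in combinations(names, size):
            if any(set(q) < set(combo) for q in minimal):
                continue
            if gamma_of(combo) >= gamma_full - 1e-12:
                minimal.append(combo)
    return minimal
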