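"""Exact inference on the fitted network by variable elimination.

Supports both reasoning directions on the same model: predictive queries
P(outcome | causes) and diagnostic queries P(cause | outcome).  Factors are
dense tables over binary scopes (axis index 0 = TRUE); elimination order is
chosen by the min-fill heuristic with a deterministic lexicographic
tie-break, and results are exact up to floating-point rounding.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .errors import ImpossibleEvidenceError, LookupError_
from .parameter_estimation import CPT, BayesianNetworkModel

__all__ = [
    "Evidence",
    "FactorTable",
    "PosteriorResult",
    "joint_probability",
    "posterior",
    "marginal_all",
    "diagnostic_probabilities",
]

Evidence = Mapping[str, bool]


@dataclass
class FactorTable:
    """A non-negative table over an ordered set of binary variables."""

    scope: tuple[str, ...]
    values: np.ndarray  # shape (2,) * len(scope); index 0 = TRUE

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (2,) * len(self.scope):
            raise ValueError("factor shape must be (2,)*len(scope)")
        if len(set(self.scope)) != len(self.scope):
            raise ValueError("factor scope must not repeat variables")

    def reduce(self, var: str, state: bool) -> "FactorTable":
        axis = self.scope.index(var)
        sliced = np.take(self.values, 0 if state else 1, axis=axis)
        scope = self.scope[:axis] + self.scope[axis + 1 :]
        return FactorTable(scope, sliced)

    def multiply(self, other: "FactorTable") -> "FactorTable":
        scope = self.scope + tuple(v for v in other.scope if v not in self.scope)
        a = self.values.reshape(self.values.shape + (1,) * (len(scope) - len(self.scope)))
        perm = [scope.index(v) for v in other.scope]
        b_shape = [2 if i in perm else 1 for i in range(len(scope))]
        b = np.transpose(other.values, np.argsort(perm)).reshape(b_shape)
        return FactorTable(scope, a * b)

    def sum_out(self, var: str) -> "FactorTable":
        axis = self.scope.index(var)
        return FactorTable(
            self.scope[:axis] + self.scope[axis + 1 :], self.values.sum(axis=axis)
        )


@dataclass(frozen=True)
class PosteriorResult:
    query: str
    p_true: float
    evidence: dict[str, bool]


def _cpt_factor(cpt: CPT) -> FactorTable:
    k = len(cpt.parents)
    p = cpt.p_true.reshape((2,) * k) if k else cpt.p_true.reshape(())
    values = np.stack([p, 1.0 - p], axis=-1)  # child axis last
    return FactorTable(cpt.parents + (cpt.node,), values.reshape((2,) * (k + 1)))


def joint_probability(model: BayesianNetworkModel, assignment: Evidence) -> float:
    """Product of CPT entries for one complete node assignment."""
    missing = set(model.graph.nodes) - set(assignment)
    if missing:
        raise ValueError(f"assignment must cover all nodes; missing {sorted(missing)}")
    p = 1.0
    for node, cpt in model.cpts.items():
        parent_states = [assignment[q] for q in cpt.parents]
        p_true = cpt.p(parent_states)
        p *= p_true if assignment[node] else 1.0 - p_true
    return p


def _min_fill_order(scopes: list[set[str]], to_eliminate: set[str]) -> list[str]:
    """Min-fill elimination order over the factor interaction graph."""
    adj: dict[str, set[str]] = {}
    for scope in scopes:
        for v in scope:
            adj.setdefault(v, set()).update(scope - {v})
    order = []
    remaining = set(to_eliminate)
    while remaining:
        best, best_fill = None, None
        for v in sorted(remaining):
            nbrs = [u for u in adj.get(v, ()) if u in adj]
            fill = sum(
                1
                for i, a in enumerate(nbrs)
                for b in nbrs[i + 1 :]
                if b not in adj[a]
            )
            if best_fill is None or fill < best_fill:
                best, best_fill = v, fill
        nbrs = [u for u in adj.get(best, ()) if u in adj]
        for i, a in enumerate(nbrs):
            for b in nbrs[i + 1 :]:
                adj[a].add(b)
                adj[b].add(a)
        for u in nbrs:
            adj[u].discard(best)
        adj.pop(best, None)
        remaining.discard(best)
        order.append(best)
    return order


def _eliminate(
    factors: list[FactorTable], order: Sequence[str]
) -> FactorTable:
    factors = list(factors)
    for var in order:
        involved = [f for f in factors if var in f.scope]
        if not involved:
            continue
        product = involved[0]
        for f in involved[1:]:
            product = product.multiply(f)
        factors = [f for f in factors if var not in f.scope] + [product.sum_out(var)]
    result = FactorTable((), np.array(1.0))
    for f in factors:
        result = result.multiply(f)
    return result


def posterior(
    model: BayesianNetworkModel,
    query: str,
    evidence: Evidence | None = None,
    elimination_order: Sequence[str] | None = None,
) -> PosteriorResult:
    """Exact P(query=TRUE | evidence) by variable elimination."""
    evidence = dict(evidence or {})
    if query not in model.cpts:
        raise LookupError_(f"unknown query node {query!r}")
    for node in evidence:
        if node not in model.cpts:
            raise LookupError_(f"unknown evidence node {node!r}")
    if query in evidence:
        raise ValueError("query node must not carry evidence")

    factors = []
    for cpt in model.cpts.values():
        f = _cpt_factor(cpt)
        for var, state in evidence.items():
            if var in f.scope:
                f = f.reduce(var, state)
        factors.append(f)

    hidden = set(model.graph.nodes) - set(evidence) - {query}
    if elimination_order is None:
        order = _min_fill_order([set(f.scope) for f in factors], hidden)
    else:
        order = [v for v in elimination_order if v in hidden]
        if set(order) != hidden:
            raise ValueError("elimination_order must cover all hidden variables")
    result = _eliminate(factors, order)
    if result.scope != (query,):
        result = FactorTable((query,), np.transpose(result.values))
    unnorm = result.values
    total = float(unnorm.sum())
    if total <= 0.0:
        raise ImpossibleEvidenceError(
            f"evidence {evidence} has probability zero under the model"
        )
    return PosteriorResult(query, float(unnorm[0] / total), evidence)


def marginal_all(model: BayesianNetworkModel) -> dict[str, float]:
    """Empty-evidence marginal P(node=TRUE) for every node."""
    return {
        node: posterior(model, node).p_true for node in sorted(model.graph.nodes)
    }


def diagnostic_probabilities(
    model: BayesianNetworkModel, outcome: str = "FFHA"
) -> dict[str, float]:
    """Backward reasoning: P(node=TRUE | outcome=TRUE) for every non-outcome node."""
    if outcome not in model.cpts:
        raise LookupError_(f"unknown outcome node {outcome!r}")
    evidence = {outcome: True}
    return {
        node: posterior(model, node, evidence).p_true
        for node in sorted(model.graph.nodes)
        if node != outcome
    }
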