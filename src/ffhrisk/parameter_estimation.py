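"""Laplace-smoothed estimation of priors and conditional probability tables.

Every node is binary (TRUE = factor present).  Root nodes get smoothed
priors P(A=TRUE) = (X_A + α)/(N + 2α); child nodes get one smoothed row per
parent-state combination, P(A=TRUE|C) = (X_{A|C} + α)/(N_C + 2α).  Parent
combinations never observed in the data (N_C = 0) fall back to a normalized
geometric mean of the single-parent conditionals: with
p_i = P(A=TRUE | parent_i = c_i) estimated pairwise, the row is
g_T/(g_T + g_F) where g_T, g_F are the geometric means of the p_i and
(1 − p_i).  The normalization restores a valid complementary pair, which a
bare geometric mean of marginals would not.

The corpus is accident-only, so the outcome node has no data column; by
default it is fitted as if an implicit all-TRUE outcome column existed,
which yields (N_C + α)/(N_C + 2α) for observed parent combinations.  An
explicit outcome column (e.g. synthetic controls) can be supplied instead —
without one, accident-only data cannot produce outcome rows below 1/2, a
structural limitation discussed in docs/methods.md.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from .errors import ValidationError
from .factor_model import IncidenceMatrix, parent_combination_counts

__all__ = [
    "EstimationConfig",
    "CPT",
    "BayesianNetworkModel",
    "estimate_prior",
    "estimate_cpt_row",
    "fallback_row",
    "fit_parameters",
    "row_index",
    "row_states",
]

OBSERVED = "observed"
FALLBACK = "fallback"


@dataclass(frozen=True)
class EstimationConfig:
    alpha: float = 1.0
    fallback: str = "geometric_mean"  # or "uniform"

    def __post_init__(self):
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.fallback not in ("geometric_mean", "uniform"):
            raise ValueError(f"unknown fallback {self.fallback!r}")


def row_index(states: Sequence[bool]) -> int:
    """Row number of a parent-state combination.

    TRUE-first enumeration with the leftmost parent most significant:
    all-TRUE is row 0, all-FALSE is the last row.
    """
    idx = 0
    for s in states:
        idx = (idx << 1) | (0 if s else 1)
    return idx


def row_states(index: int, n_parents: int) -> tuple[bool, ...]:
    """Inverse of :func:`row_index`."""
    return tuple(not bool((index >> (n_parents - 1 - i)) & 1) for i in range(n_parents))


@dataclass
class CPT:
    """P(node=TRUE | parent combination) with per-row provenance."""

    node: str
    parents: tuple[str, ...]
    p_true: np.ndarray  # shape (2**len(parents),)
    provenance: tuple[str, ...]

    def __post_init__(self):
        self.p_true = np.asarray(self.p_true, dtype=float)
        expected = 2 ** len(self.parents)
        if self.p_true.shape != (expected,):
            raise ValidationError(
                f"CPT for {self.node!r} needs {expected} rows, got {self.p_true.shape}"
            )
        if len(self.provenance) != expected:
            raise ValidationError("provenance must cover every CPT row")
        if np.any((self.p_true <= 0) | (self.p_true >= 1)):
            raise ValidationError(
                f"CPT for {self.node!r} has probabilities outside (0, 1)"
            )

    def p(self, parent_states: Sequence[bool]) -> float:
        return float(self.p_true[row_index(parent_states)])


@dataclass
class BayesianNetworkModel:
    """A DAG over binary nodes plus one CPT per node."""

    graph: nx.DiGraph = field(repr=False)
    cpts: dict[str, CPT]

    def __post_init__(self):
        if set(self.graph.nodes) != set(self.cpts):
            raise ValidationError("CPTs must cover exactly the graph nodes")
        for node, cpt in self.cpts.items():
            if set(cpt.parents) != set(self.graph.predecessors(node)):
                raise ValidationError(
                    f"CPT parents for {node!r} disagree with the graph"
                )

    @property
    def nodes(self) -> list[str]:
        return list(nx.lexicographical_topological_sort(self.graph))

    def parents(self, node: str) -> tuple[str, ...]:
        return self.cpts[node].parents

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "nodes": sorted(self.graph.nodes),
            "edges": sorted(self.graph.edges),
            "cpts": {
                node: {
                    "parents": list(cpt.parents),
                    "p_true": [float(p) for p in cpt.p_true],
                    "provenance": list(cpt.provenance),
                }
                for node, cpt in self.cpts.items()
            },
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "BayesianNetworkModel":
        if isinstance(source, Path) or (
            isinstance(source, str) and "\n" not in source and Path(source).exists()
        ):
            text = Path(source).read_text(encoding="utf-8")
        else:
            text = str(source)
        payload = json.loads(text)
        graph = nx.DiGraph()
        graph.add_nodes_from(payload["nodes"])
        graph.add_edges_from(payload["edges"])
        cpts = {
            node: CPT(
                node,
                tuple(spec["parents"]),
                np.array(spec["p_true"], dtype=float),
                tuple(spec["provenance"]),
            )
            for node, spec in payload["cpts"].items()
        }
        return cls(graph, cpts)


def estimate_prior(x_a: int, n: int, alpha: float = 1.0) -> float:
    """Smoothed prior (X_A + α)/(N + 2α)."""
    if not 0 <= x_a <= n:
        raise ValueError(f"need 0 <= X_A <= N, got X_A={x_a}, N={n}")
    if n == 0 and alpha == 0:
        raise ZeroDivisionError("prior undefined for N=0 with alpha=0")
    return (x_a + alpha) / (n + 2 * alpha)


def estimate_cpt_row(x_given_c: int, n_c: int, alpha: float = 1.0) -> float:
    """Smoothed conditional (X_{A|C} + α)/(N_C + 2α)."""
    if not 0 <= x_given_c <= n_c:
        raise ValueError(f"need 0 <= X_A|C <= N_C, got {x_given_c}, {n_c}")
    return (x_given_c + alpha) / (n_c + 2 * alpha)


def fallback_row(single_parent_conditionals: Sequence[float]) -> float:
    """Normalized geometric-mean estimate for an unseen parent combination."""
    p = np.asarray(single_parent_conditionals, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one single-parent conditional")
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("single-parent conditionals must lie strictly in (0, 1)")
    g_t = float(np.exp(np.mean(np.log(p))))
    g_f = float(np.exp(np.mean(np.log(1.0 - p))))
    return g_t / (g_t + g_f)


def _augmented_column(
    matrix: IncidenceMatrix,
    node: str,
    outcome_id: str | None,
    outcome_column: np.ndarray | None,
) -> np.ndarray:
    if node in matrix.factor_ids:
        return matrix.column(node)
    if node == outcome_id:
        if outcome_column is not None:
            return np.asarray(outcome_column, dtype=np.int8)
        return np.ones(matrix.n_reports, dtype=np.int8)  # accident-only corpus
    raise ValidationError(f"graph node {node!r} has no data column")


def fit_parameters(
    matrix: IncidenceMatrix,
    graph: nx.DiGraph,
    config: EstimationConfig = EstimationConfig(),
    outcome_id: str | None = "FFHA",
    outcome_column: np.ndarray | None = None,
    parent_order: Mapping[str, Sequence[str]] | None = None,
) -> BayesianNetworkModel:
    """Fit every node's prior or CPT from the incidence matrix.

    Parents default to lexicographic (catalog) order; ``parent_order`` can
    pin a different order per node.  ``outcome_column`` supplies explicit
    outcome states; without it the outcome (absent from the matrix) is
    treated as TRUE in every report.
    """
    alpha = config.alpha
    n = matrix.n_reports
    missing = [
        v
        for v in graph.nodes
        if v not in matrix.factor_ids and v != outcome_id
    ]
    if missing:
        raise ValidationError(f"graph nodes missing from the matrix: {missing}")

    columns = {
        node: _augmented_column(matrix, node, outcome_id, outcome_column)
        for node in graph.nodes
    }
    aug = IncidenceMatrix(
        matrix.data.assign(**{outcome_id: columns[outcome_id]})
        if outcome_id in graph.nodes and outcome_id not in matrix.factor_ids
        else matrix.data.copy()
    )

    cpts: dict[str, CPT] = {}
    for node in graph.nodes:
        default_parents = sorted(graph.predecessors(node))
        if parent_order and node in parent_order:
            ordered = list(parent_order[node])
            if sorted(ordered) != default_parents:
                raise ValidationError(
                    f"parent_order for {node!r} must be a permutation of its parents"
                )
            parents = tuple(ordered)
        else:
            parents = tuple(default_parents)

        if not parents:
            x_a = int(columns[node].sum())
            cpts[node] = CPT(
                node, (), np.array([estimate_prior(x_a, n, alpha)]), (OBSERVED,)
            )
            continue

        n_c, x_given_c = parent_combination_counts(aug, node, parents)
        n_rows = 2 ** len(parents)
        p = np.empty(n_rows)
        provenance = []
        pairwise: dict[tuple[str, bool], float] = {}
        for row in range(n_rows):
            if n_c[row] > 0:
                p[row] = estimate_cpt_row(int(x_given_c[row]), int(n_c[row]), alpha)
                provenance.append(OBSERVED)
            elif config.fallback == "uniform":
                p[row] = 0.5
                provenance.append(FALLBACK)
            else:
                states = row_states(row, len(parents))
                conds = []
                for parent, state in zip(parents, states):
                    key = (parent, state)
                    if key not in pairwise:
                        nc1, x1 = parent_combination_counts(aug, node, [parent])
                        idx = row_index([state])
                        pairwise[key] = estimate_cpt_row(
                            int(x1[idx]), int(nc1[idx]), alpha
                        )
                    conds.append(pairwise[key])
                p[row] = fallback_row(conds)
                provenance.append(FALLBACK)
        cpts[node] = CPT(node, parents, p, tuple(provenance))
    return BayesianNetworkModel(graph.copy(), cpts)
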