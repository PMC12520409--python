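"""Exhaustive enumeration and ranking of outcome risk scenarios.

A risk scenario is one complete TRUE/FALSE assignment of the outcome node's
parents; with 7 parents there are 2^7 = 128 scenarios.  Because the outcome
is d-separated from everything else given its parents, each scenario's
P(outcome=TRUE) is exactly the matching CPT row — the enumeration therefore
doubles as a readable rendering of the outcome CPT, ranked by risk.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .inference_engine import marginal_all, diagnostic_probabilities, posterior
from .parameter_estimation import BayesianNetworkModel, row_states

__all__ = ["Scenario", "ScenarioTable", "enumerate_scenarios", "top_scenarios",
           "rank_risk_factors", "write_scenario_csv"]


@dataclass(frozen=True)
class Scenario:
    assignment: tuple[tuple[str, bool], ...]  # (parent, state) in table order
    p_outcome: float

    def states(self) -> dict[str, bool]:
        return dict(self.assignment)


@dataclass
class ScenarioTable:
    outcome: str
    parent_order: tuple[str, ...]
    scenarios: list[Scenario]

    def __len__(self) -> int:
        return len(self.scenarios)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, s in enumerate(self.scenarios, start=1):
            row: dict[str, object] = {"number": i}
            for parent, state in s.assignment:
                row[parent] = "TRUE" if state else "FALSE"
            row[self.outcome] = f"{100 * s.p_outcome:.2f}%"
            rows.append(row)
        return pd.DataFrame(rows)


def enumerate_scenarios(
    model: BayesianNetworkModel,
    outcome: str = "FFHA",
    parent_order: Sequence[str] | None = None,
) -> ScenarioTable:
    """One row per parent-state combination, in canonical enumeration order.

    Rows enumerate TRUE-first with the leftmost parent most significant
    (all-TRUE first, all-FALSE last).  ``parent_order`` reorders the columns
    and hence the enumeration; it must be a permutation of the outcome's
    parents.  The default is the fitted CPT's parent order.
    """
    cpt = model.cpts[outcome]
    if not cpt.parents:
        raise ValueError(f"outcome {outcome!r} is a root node; no scenarios to enumerate")
    order = tuple(parent_order) if parent_order is not None else cpt.parents
    if sorted(order) != sorted(cpt.parents):
        raise ValueError("parent_order must be a permutation of the outcome's parents")
    k = len(order)
    scenarios = []
    for row in range(2**k):
        states = row_states(row, k)
        assignment = dict(zip(order, states))
        p = cpt.p([assignment[q] for q in cpt.parents])
        scenarios.append(Scenario(tuple(zip(order, states)), p))
    return ScenarioTable(outcome, order, scenarios)


def top_scenarios(table: ScenarioTable, n: int) -> list[Scenario]:
    """The n riskiest scenarios; ties break by canonical enumeration order."""
    if not 1 <= n <= len(table):
        raise ValueError(f"n must be in [1, {len(table)}], got {n}")
    indexed = sorted(
        enumerate(table.scenarios), key=lambda iv: (-iv[1].p_outcome, iv[0])
    )
    return [s for _, s in indexed[:n]]


def rank_risk_factors(
    model: BayesianNetworkModel, outcome: str = "FFHA"
) -> pd.DataFrame:
    """Non-outcome nodes ranked by marginal P(TRUE), with diagnostic posteriors.

    The diagnostic column is P(node=TRUE | outcome=TRUE) — backward
    reasoning from an observed accident to its likely contributing factors.
    """
    marginals = marginal_all(model)
    diagnostics = diagnostic_probabilities(model, outcome)
    rows = [
        {"node": node, "marginal": marginals[node], "diagnostic": diagnostics[node]}
        for node in sorted(model.graph.nodes)
        if node != outcome
    ]
    df = pd.DataFrame(rows).sort_values(
        by=["marginal", "node"], ascending=[False, True], kind="mergesort"
    )
    return df.reset_index(drop=True)


def write_scenario_csv(table: ScenarioTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, index=False)
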