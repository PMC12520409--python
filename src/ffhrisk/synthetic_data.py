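"""Synthetic generators for every input the pipeline consumes.

Two generators mirror the two real data sources: (1) binary incidence
matrices drawn by ancestral sampling from a known ground-truth network,
optionally rejection-conditioned on the outcome being TRUE — emulating a
corpus in which every collected report is an accident — and (2) 0–10
questionnaire scores for candidate edges, drawn around a high true-edge
support (8.5/10) or a low non-edge support (2.0/10) with controllable noise.
Having a known ground truth makes end-to-end recovery of both structure and
parameters testable without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import SamplingBudgetError
from .evidence_fusion import Edge, ResponseSet
from .factor_model import IncidenceMatrix
from .network_structure import assemble_graph
from .parameter_estimation import CPT, BayesianNetworkModel

__all__ = [
    "FFH21_EDGES",
    "FFH21_OUTCOME_PARENT_ORDER",
    "GroundTruthSpec",
    "SimulationReport",
    "make_ground_truth",
    "sample_reports",
    "simulate_questionnaires",
    "simulation_report",
]

# The refined 21-node fall-from-height network: the 25 panel-screened edges
# plus the data-retained B3→A2 link, minus the two CMI-pruned shortcuts
# B2→C3 and B7→C3.  24 edges; FFHA has exactly 7 parents.
FFH21_EDGES: tuple[Edge, ...] = (
    ("B4", "B2"),
    ("B2", "B1"),
    ("B2", "B7"),
    ("B1", "D1"),
    ("B1", "C3"),
    ("B7", "D3"),
    ("B7", "D2"),
    ("D3", "C3"),
    ("D2", "E2"),
    ("B6", "C1"),
    ("B3", "A1"),
    ("B3", "A2"),
    ("A1", "A3"),
    ("B8", "B5"),
    ("B5", "E1"),
    ("A3", "E1"),
    ("C2", "E1"),
    ("D1", "FFHA"),
    ("C1", "FFHA"),
    ("C3", "FFHA"),
    ("E2", "FFHA"),
    ("E1", "FFHA"),
    ("E3", "FFHA"),
    ("A2", "FFHA"),
)

# Scenario-table column order for the outcome's seven parents.
FFH21_OUTCOME_PARENT_ORDER: tuple[str, ...] = ("A2", "D1", "C3", "E1", "E2", "E3", "C1")


@dataclass(frozen=True)
class GroundTruthSpec:
    """Recipe for a ground-truth model: a topology plus a CPT source."""

    topology: str | tuple[Edge, ...] = "ffh21"
    cpt_source: str | dict[str, Sequence[float]] = "random"
    seed: int = 0
    outcome_id: str = "FFHA"
    nodes: tuple[str, ...] = ()  # isolated nodes beyond the edge endpoints


@dataclass
class SimulationReport:
    matrix: IncidenceMatrix = field(repr=False)
    model: BayesianNetworkModel = field(repr=False)
    marginals: pd.DataFrame = field(repr=False)  # node, true, empirical
    conditioned: bool = False
    acceptance_rate: float | None = None


def _resolve_edges(spec: GroundTruthSpec) -> tuple[Edge, ...]:
    if isinstance(spec.topology, str):
        if spec.topology != "ffh21":
            raise ValueError(f"unknown topology preset {spec.topology!r}")
        return FFH21_EDGES
    return tuple(spec.topology)


def make_ground_truth(spec: GroundTruthSpec) -> BayesianNetworkModel:
    """Deterministic ground-truth model from a spec.

    Random CPT entries are drawn uniformly in (0.05, 0.95) so no row is
    degenerate.  For the ffh21 preset the outcome's parent order is pinned
    to the scenario-table column order; other nodes use lexicographic order.
    """
    graph = assemble_graph(_resolve_edges(spec))  # raises StructureError on cycles
    graph.add_nodes_from(spec.nodes)
    rng = np.random.default_rng(spec.seed)
    cpts: dict[str, CPT] = {}
    for node in sorted(graph.nodes):
        parents = tuple(sorted(graph.predecessors(node)))
        if (
            isinstance(spec.topology, str)
            and spec.topology == "ffh21"
            and node == spec.outcome_id
        ):
            parents = FFH21_OUTCOME_PARENT_ORDER
        n_rows = 2 ** len(parents)
        if isinstance(spec.cpt_source, dict):
            p = np.asarray(spec.cpt_source[node], dtype=float)
        else:
            p = rng.uniform(0.05, 0.95, size=n_rows)
        cpts[node] = CPT(node, parents, p, ("observed",) * n_rows)
    return BayesianNetworkModel(graph, cpts)


def _ancestral_sample(
    model: BayesianNetworkModel, n: int, rng: np.random.Generator
) -> pd.DataFrame:
    order = list(nx.lexicographical_topological_sort(model.graph))
    draws: dict[str, np.ndarray] = {}
    for node in order:
        cpt = model.cpts[node]
        if cpt.parents:
            idx = np.zeros(n, dtype=np.int64)
            for parent in cpt.parents:
                idx = (idx << 1) | (1 - draws[parent])
            p = cpt.p_true[idx]
        else:
            p = np.full(n, cpt.p_true[0])
        draws[node] = (rng.random(n) < p).astype(np.int8)
    return pd.DataFrame({node: draws[node] for node in sorted(order)})


def _report_ids(n: int) -> list[str]:
    width = max(3, len(str(n)))
    return [str(i).zfill(width) for i in range(1, n + 1)]


def sample_reports(
    model: BayesianNetworkModel,
    n: int,
    seed: int = 0,
    condition_outcome_true: bool = False,
    outcome_id: str = "FFHA",
    keep_outcome: bool = False,
    max_batches: int = 1000,
) -> IncidenceMatrix:
    """Ancestral sampling of ``n`` synthetic reports.

    With ``condition_outcome_true`` the sampler rejects rows until it has
    ``n`` with outcome TRUE, then (unless ``keep_outcome``) drops the
    outcome column, matching the accident-only corpus layout.
    """
    rng = np.random.default_rng(seed)
    if n == 0:
        cols = sorted(model.graph.nodes)
        if not keep_outcome and outcome_id in cols:
            cols.remove(outcome_id)
        empty = pd.DataFrame({c: pd.Series(dtype=np.int8) for c in cols})
        empty.index = pd.Index([], dtype=str)
        return IncidenceMatrix(empty)
    if not condition_outcome_true:
        frame = _ancestral_sample(model, n, rng)
    else:
        kept: list[pd.DataFrame] = []
        batch = max(4 * n, 256)
        for _ in range(max_batches):
            draw = _ancestral_sample(model, batch, rng)
            kept.append(draw[draw[outcome_id] == 1])
            if sum(len(k) for k in kept) >= n:
                break
        frame = pd.concat(kept, ignore_index=True)
        if len(frame) < n:
            raise SamplingBudgetError(
                f"outcome={outcome_id} TRUE too rare: kept {len(frame)} of "
                f"{max_batches * batch} draws, needed {n}"
            )
        frame = frame.iloc[:n].reset_index(drop=True)
    if not keep_outcome and outcome_id in frame.columns:
        frame = frame.drop(columns=[outcome_id])
    frame.index = pd.Index(_report_ids(n))
    return IncidenceMatrix(frame)


def simulate_questionnaires(
    true_graph: nx.DiGraph,
    candidate_edges: Sequence[Edge],
    n_expert: int = 11,
    n_frontline: int = 41,
    noise_sd: float = 1.5,
    seed: int = 0,
    true_center: float = 8.5,
    false_center: float = 2.0,
) -> list[ResponseSet]:
    """Per-respondent 0–10 scores for each candidate edge.

    Scores are normal draws around the true-edge or non-edge center,
    clipped to [0, 10] and rounded half-even to integers.  noise_sd = 0
    degenerates to the rounded center itself.
    """
    if n_expert < 1 or n_frontline < 1:
        raise ValueError("panel sizes must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    for edge in candidate_edges:
        center = true_center if true_graph.has_edge(*edge) else false_center
        scores = []
        for n_panel in (n_expert, n_frontline):
            raw = rng.normal(center, noise_sd, size=n_panel) if noise_sd > 0 else np.full(n_panel, center)
            clipped = np.clip(raw, 0.0, 10.0)
            scores.append(tuple(int(s) for s in np.round(clipped)))
        out.append(ResponseSet(tuple(edge), scores[0], scores[1]))
    return out


def simulation_report(
    model: BayesianNetworkModel,
    matrix: IncidenceMatrix,
    true_marginals: dict[str, float] | None = None,
) -> SimulationReport:
    """Per-node empirical frequency vs model marginal for a generated matrix."""
    from .inference_engine import marginal_all

    truth = true_marginals if true_marginals is not None else marginal_all(model)
    rows = []
    for node in matrix.factor_ids:
        rows.append(
            {
                "node": node,
                "true": truth.get(node, np.nan),
                "empirical": float(matrix.column(node).mean())
                if matrix.n_reports
                else np.nan,
            }
        )
    return SimulationReport(matrix, model, pd.DataFrame(rows))
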