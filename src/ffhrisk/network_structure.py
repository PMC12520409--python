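"""DAG assembly and data-driven structure refinement.

The screened expert edges form a preliminary directed acyclic graph.
d-separation then suggests edges that may be redundant (a direct edge X→Y
shadowed by a mediated path X→Z→Y); each suspect edge is tested with the
plug-in conditional mutual information I(X;Y|Z) estimated from the binary
incidence matrix, and removed when the estimate falls below an independence
threshold (default 0.02, in bits).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .errors import LookupError_, StructureError
from .factor_model import IncidenceMatrix

__all__ = [
    "Edge",
    "CMITest",
    "assemble_graph",
    "d_separated",
    "candidate_cmi_tests",
    "conditional_mutual_information",
    "prune_edges",
    "write_edge_list",
    "read_edge_list",
    "to_dot",
]

Edge = tuple[str, str]

DEFAULT_CMI_THRESHOLD = 0.02


@dataclass(frozen=True)
class CMITest:
    """One conditional-independence test of a candidate-redundant edge."""

    edge: Edge
    conditioner: str
    value: float
    threshold: float = DEFAULT_CMI_THRESHOLD

    @property
    def independent(self) -> bool:
        return self.value < self.threshold


def assemble_graph(edges: Iterable[Edge]) -> nx.DiGraph:
    """Directed graph over exactly the given edges; rejects self-loops and cycles."""
    g = nx.DiGraph()
    for u, v in edges:
        if u == v:
            raise StructureError(f"self-loop on node {u!r}")
        g.add_edge(u, v)
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        raise StructureError(f"graph contains a cycle: {cycle}")
    return g


def d_separated(graph: nx.DiGraph, x: str, y: str, z: Iterable[str] = ()) -> bool:
    """Standard d-separation of x and y given the set z."""
    z = set(z)
    for node in {x, y} | z:
        if node not in graph:
            raise LookupError_(f"unknown node {node!r}")
    if x in z or y in z:
        raise ValueError("query nodes must not appear in the conditioning set")
    return nx.is_d_separator(graph, {x}, {y}, z)


def candidate_cmi_tests(
    graph: nx.DiGraph,
    extra: Sequence[tuple[Edge, str]] | None = None,
) -> list[tuple[Edge, str]]:
    """Edges worth a conditional-independence test, with their conditioners.

    For every edge X→Y whose removal still leaves a single-mediator directed
    path X→Z→Y, emit (X→Y, Z) for each such mediator Z.  User-supplied
    triples are appended verbatim (deduplicated); a triple naming an edge
    absent from the graph draws a warning, not an error, since the tested
    relationship may deliberately probe a rejected candidate.
    """
    tests: list[tuple[Edge, str]] = []
    seen: set[tuple[Edge, str]] = set()
    for x, y in graph.edges:
        for z in graph.successors(x):
            if z != y and graph.has_edge(z, y):
                item = ((x, y), z)
                if item not in seen:
                    seen.add(item)
                    tests.append(item)
    for edge, z in extra or ():
        if not graph.has_edge(*edge):
            warnings.warn(
                f"user-supplied CMI triple references absent edge {edge[0]}→{edge[1]}",
                stacklevel=2,
            )
        item = (tuple(edge), z)
        if item not in seen:
            seen.add(item)
            tests.append(item)  # type: ignore[arg-type]
    return tests


def conditional_mutual_information(
    matrix: IncidenceMatrix,
    x: str,
    y: str,
    z: str,
    log_base: float = 2.0,
) -> float:
    """Plug-in estimate of I(X;Y|Z) from empirical cell frequencies.

    I(X;Y|Z) = Σ_{x,y,z} P(x,y,z) log [ P(x,y|z) / (P(x|z) P(y|z)) ],
    with the usual convention that empty cells contribute zero.  Frequencies
    are joint occurrence counts N(x,y,z)/N over the incidence matrix.
    """
    if len({x, y, z}) != 3:
        raise ValueError("x, y, z must be distinct")
    n = matrix.n_reports
    if n == 0:
        raise ValueError("cannot estimate CMI from an empty matrix")
    cx, cy, cz = matrix.column(x), matrix.column(y), matrix.column(z)
    for name, col in ((x, cx), (y, cy), (z, cz)):
        if col.min() == col.max():
            warnings.warn(
                f"variable {name!r} is constant in the data; CMI degenerates to 0",
                stacklevel=2,
            )
            return 0.0
    idx = cx * 4 + cy * 2 + cz
    counts = np.bincount(idx, minlength=8).reshape(2, 2, 2).astype(float)
    p_xyz = counts / n
    p_z = p_xyz.sum(axis=(0, 1), keepdims=True)
    p_xz = p_xyz.sum(axis=1, keepdims=True)
    p_yz = p_xyz.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = p_xyz * p_z / (p_xz * p_yz)
        terms = np.where(p_xyz > 0, p_xyz * np.log(ratio), 0.0)
    return float(terms.sum() / np.log(log_base))


def prune_edges(
    graph: nx.DiGraph,
    matrix: IncidenceMatrix,
    threshold: float = DEFAULT_CMI_THRESHOLD,
    extra: Sequence[tuple[Edge, str]] | None = None,
    log_base: float = 2.0,
) -> tuple[nx.DiGraph, list[CMITest]]:
    """Drop every tested edge whose CMI falls below ``threshold`` for any conditioner.

    Returns the pruned graph together with the full test report (retained
    edges included).  Edge removal cannot create cycles, so the result stays
    a DAG.
    """
    tests: list[CMITest] = []
    to_remove: set[Edge] = set()
    for edge, z in candidate_cmi_tests(graph, extra):
        x, y = edge
        value = conditional_mutual_information(matrix, x, y, z, log_base=log_base)
        test = CMITest(edge, z, value, threshold)
        tests.append(test)
        if test.independent and graph.has_edge(x, y):
            to_remove.add(edge)
    pruned = graph.copy()
    pruned.remove_edges_from(to_remove)
    return pruned, tests


def write_edge_list(graph: nx.DiGraph, path: str | Path) -> None:
    lines = ["from,to"] + [f"{u},{v}" for u, v in graph.edges]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_edge_list(path: str | Path) -> list[Edge]:
    lines = Path(path).read_text(encoding="utf-8").strip().splitlines()
    if lines and lines[0].strip().lower() == "from,to":
        lines = lines[1:]
    return [tuple(line.strip().split(",")) for line in lines if line.strip()]  # type: ignore[misc]


def to_dot(graph: nx.DiGraph, path: str | Path) -> None:
    """Minimal GraphViz DOT export (nodes and directed edges only)."""
    body = "\n".join(f'  "{u}" -> "{v}";' for u, v in graph.edges)
    Path(path).write_text("digraph risk {\n" + body + "\n}\n", encoding="utf-8")
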