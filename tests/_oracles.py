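"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written by a different route than the
package: joint enumeration instead of variable elimination, explicit path
enumeration instead of graph separation algorithms, and a literal
triple-loop instead of vectorized counting.
"""

from __future__ import annotations

import itertools
import math

import networkx as nx
import numpy as np

from ffhrisk.parameter_estimation import BayesianNetworkModel, CPT


def enumerate_joint(model: BayesianNetworkModel) -> tuple[list[str], np.ndarray]:
    """Full joint distribution by enumeration; bit 1 = TRUE, node j uses bit (n-1-j)."""
    nodes = sorted(model.graph.nodes)
    n = len(nodes)
    idx = np.arange(2**n, dtype=np.int64)
    states = {
        node: ((idx >> (n - 1 - j)) & 1).astype(bool) for j, node in enumerate(nodes)
    }
    probs = np.ones(2**n)
    for node in nodes:
        cpt = model.cpts[node]
        row = np.zeros(2**n, dtype=np.int64)
        for parent in cpt.parents:
            row = (row << 1) | (~states[parent]).astype(np.int64)
        p_true = cpt.p_true[row]
        probs *= np.where(states[node], p_true, 1.0 - p_true)
    return nodes, probs


def brute_posterior(
    model: BayesianNetworkModel, query: str, evidence: dict[str, bool]
) -> float:
    nodes, probs = enumerate_joint(model)
    n = len(nodes)
    idx = np.arange(2**n, dtype=np.int64)
    mask = np.ones(2**n, dtype=bool)
    for node, state in evidence.items():
        bit = ((idx >> (n - 1 - nodes.index(node))) & 1).astype(bool)
        mask &= bit == state
    q_bit = ((idx >> (n - 1 - nodes.index(query))) & 1).astype(bool)
    denom = probs[mask].sum()
    if denom == 0:
        raise ZeroDivisionError("evidence has probability zero")
    return float(probs[mask & q_bit].sum() / denom)


def brute_marginal(model: BayesianNetworkModel, node: str) -> float:
    return brute_posterior(model, node, {})


def dsep_by_path_enumeration(
    graph: nx.DiGraph, x: str, y: str, z: set[str]
) -> bool:
    """d-separation decided by enumerating every undirected simple path."""
    z = set(z)
    descendants = {v: nx.descendants(graph, v) | {v} for v in graph.nodes}
    skeleton = graph.to_undirected()
    for path in nx.all_simple_paths(skeleton, x, y):
        active = True
        for i in range(1, len(path) - 1):
            prev, v, nxt = path[i - 1], path[i], path[i + 1]
            collider = graph.has_edge(prev, v) and graph.has_edge(nxt, v)
            if collider:
                if not (descendants[v] & z):
                    active = False
                    break
            elif v in z:
                active = False
                break
        if active:
            return False
    return True


def cmi_triple_loop(matrix, x: str, y: str, z: str, log_base: float = 2.0) -> float:
    """Literal triple-loop plug-in CMI over the 8 joint cells."""
    cx, cy, cz = matrix.column(x), matrix.column(y), matrix.column(z)
    n = matrix.n_reports
    total = 0.0
    for a in (0, 1):
        for b in (0, 1):
            for c in (0, 1):
                n_xyz = int(((cx == a) & (cy == b) & (cz == c)).sum())
                if n_xyz == 0:
                    continue
                n_z = int((cz == c).sum())
                n_xz = int(((cx == a) & (cz == c)).sum())
                n_yz = int(((cy == b) & (cz == c)).sum())
                p_xyz = n_xyz / n
                ratio = (n_xyz / n_z) / ((n_xz / n_z) * (n_yz / n_z))
                total += p_xyz * math.log(ratio, log_base)
    return total


def random_model(
    rng: np.random.Generator, n_nodes: int, p_edge: float = 0.35
) -> BayesianNetworkModel:
    """A random DAG with CPT entries in (0.05, 0.95)."""
    names = [f"N{j}" for j in range(n_nodes)]
    g = nx.DiGraph()
    g.add_nodes_from(names)
    for i, j in itertools.combinations(range(n_nodes), 2):
        if rng.random() < p_edge:
            g.add_edge(names[i], names[j])
    cpts = {}
    for node in names:
        parents = tuple(sorted(g.predecessors(node)))
        p = rng.uniform(0.05, 0.95, size=2 ** len(parents))
        cpts[node] = CPT(node, parents, p, ("observed",) * len(p))
    return BayesianNetworkModel(g, cpts)
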