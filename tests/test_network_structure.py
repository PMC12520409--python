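"""DAG assembly, d-separation, CMI estimation, and edge pruning."""

import numpy as np
import pandas as pd
import pytest

from _oracles import cmi_triple_loop, dsep_by_path_enumeration, random_model
from ffhrisk import (
    assemble_graph,
    candidate_cmi_tests,
    conditional_mutual_information,
    d_separated,
    make_ground_truth,
    prune_edges,
    sample_reports,
)
from ffhrisk.errors import LookupError_, StructureError
from ffhrisk.factor_model import IncidenceMatrix
from ffhrisk.synthetic_data import FFH21_EDGES, GroundTruthSpec


def _matrix(frame: pd.DataFrame) -> IncidenceMatrix:
    frame = frame.copy()
    frame.index = [str(i).zfill(3) for i in range(1, len(frame) + 1)]
    return IncidenceMatrix(frame)


# ---------------------------------------------------------------- assembly


def test_assemble_full_elicited_graph(elicited):
    edges = list(zip(elicited["from"], elicited["to"])) + [("B3", "A2")]
    g = assemble_graph(edges)
    assert g.number_of_nodes() == 21
    assert g.number_of_edges() == 26


def test_assemble_rejects_two_cycle():
    with pytest.raises(StructureError):
        assemble_graph([("A", "B"), ("B", "A")])


def test_assemble_rejects_self_loop():
    with pytest.raises(StructureError):
        assemble_graph([("A", "A")])


def test_assemble_empty():
    assert assemble_graph([]).number_of_nodes() == 0


# ------------------------------------------------------------ d-separation


def test_chain_blocked_by_middle():
    g = assemble_graph([("A", "B"), ("B", "C")])
    assert d_separated(g, "A", "C", {"B"})
    assert not d_separated(g, "A", "C", set())


def test_collider_semantics():
    g = assemble_graph([("A", "C"), ("B", "C")])
    assert d_separated(g, "A", "B", set())
    assert not d_separated(g, "A", "B", {"C"})


def test_refined_network_separates_pruned_shortcut():
    """After dropping B2→C3 the pair is separated given {B1, D3}."""
    g = assemble_graph(FFH21_EDGES)
    assert d_separated(g, "B2", "C3", {"B1", "D3"})
    assert not d_separated(g, "B2", "C3", set())


def test_unknown_node_raises(ffh21_model):
    with pytest.raises(LookupError_):
        d_separated(ffh21_model.graph, "Z9", "A1", set())


def test_dsep_matches_path_enumeration_oracle():
    rng = np.random.default_rng(11)
    for _ in range(15):
        model = random_model(rng, 8, p_edge=0.3)
        g = model.graph
        nodes = sorted(g.nodes)
        for _ in range(30):
            x, y = rng.choice(nodes, size=2, replace=False)
            others = [v for v in nodes if v not in (x, y)]
            z = set(rng.choice(others, size=rng.integers(0, 4), replace=False))
            assert d_separated(g, x, y, z) == dsep_by_path_enumeration(g, x, y, z)


# ------------------------------------------------------- candidate tests


def test_candidate_triangle_b2_c3():
    g = assemble_graph([("B2", "B1"), ("B1", "C3"), ("B2", "C3")])
    assert (("B2", "C3"), "B1") in candidate_cmi_tests(g)


def test_candidate_triangle_b7_c3():
    g = assemble_graph([("B7", "D3"), ("D3", "C3"), ("B7", "C3")])
    assert (("B7", "C3"), "D3") in candidate_cmi_tests(g)


def test_pure_chain_yields_no_candidates():
    g = assemble_graph([("A", "B"), ("B", "C")])
    assert candidate_cmi_tests(g) == []


def test_user_triple_appended_and_absent_edge_warns():
    g = assemble_graph([("A", "B"), ("B", "C")])
    with pytest.warns(UserWarning, match="absent edge"):
        tests = candidate_cmi_tests(g, extra=[(("B3", "A2"), "A1")])
    assert tests == [(("B3", "A2"), "A1")]


# ------------------------------------------------------------------- CMI


def test_cmi_matches_triple_loop_oracle(excerpt):
    for x, y, z in [("B3", "A2", "A1"), ("B2", "C3", "B1"), ("B7", "C3", "D3")]:
        mine = conditional_mutual_information(excerpt, x, y, z)
        oracle = cmi_triple_loop(excerpt, x, y, z)
        assert mine == pytest.approx(oracle, abs=1e-12)
        assert mine >= -1e-12


def test_cmi_symmetric_in_x_and_y(excerpt):
    a = conditional_mutual_information(excerpt, "B2", "D1", "E1")
    b = conditional_mutual_information(excerpt, "D1", "B2", "E1")
    assert a == pytest.approx(b, abs=1e-12)


def test_cmi_zero_on_exactly_factorized_counts():
    # product design: every (x,y,z) cell appears equally often -> exact independence
    rows = []
    for x in (0, 1):
        for y in (0, 1):
            for z in (0, 1):
                rows.extend([{"X": x, "Y": y, "Z": z}] * 4)
    matrix = _matrix(pd.DataFrame(rows))
    assert conditional_mutual_information(matrix, "X", "Y", "Z") == pytest.approx(
        0.0, abs=1e-12
    )


def test_cmi_one_bit_on_copied_variable():
    # X == Y balanced, Z an independent fair indicator: I(X;Y|Z) = H(X) = 1 bit
    rows = []
    for x in (0, 1):
        for z in (0, 1):
            rows.extend([{"X": x, "Y": x, "Z": z}] * 5)
    matrix = _matrix(pd.DataFrame(rows))
    assert conditional_mutual_information(matrix, "X", "Y", "Z") == pytest.approx(1.0)


def test_cmi_natural_log_base_rescales():
    rows = []
    rng = np.random.default_rng(5)
    frame = pd.DataFrame(
        rng.integers(0, 2, size=(200, 3)), columns=["X", "Y", "Z"]
    )
    matrix = _matrix(frame)
    bits = conditional_mutual_information(matrix, "X", "Y", "Z", log_base=2)
    nats = conditional_mutual_information(matrix, "X", "Y", "Z", log_base=np.e)
    assert nats == pytest.approx(bits * np.log(2), abs=1e-12)


def test_cmi_constant_column_degenerates_to_zero():
    frame = pd.DataFrame({"X": [1, 1, 1, 1], "Y": [0, 1, 0, 1], "Z": [0, 0, 1, 1]})
    with pytest.warns(UserWarning, match="constant"):
        assert conditional_mutual_information(_matrix(frame), "X", "Y", "Z") == 0.0


def test_cmi_empty_matrix_rejected():
    frame = pd.DataFrame({"X": [], "Y": [], "Z": []})
    with pytest.raises(ValueError):
        conditional_mutual_information(_matrix(frame), "X", "Y", "Z")


# ----------------------------------------------------------------- pruning


def _chain_with_shortcut_model():
    cpts = {
        "X": [0.5],
        "Z": [0.85, 0.15],
        "Y": [0.8, 0.25],
    }
    return make_ground_truth(
        GroundTruthSpec(topology=(("X", "Z"), ("Z", "Y")), cpt_source=cpts)
    )


def test_prune_removes_spurious_shortcut_and_keeps_true_edge():
    """A mediated-only dependency X→Z→Y loses a spuriously added X→Y edge."""
    truth = _chain_with_shortcut_model()
    removed = 0
    for seed in range(20):
        matrix = sample_reports(truth, 368, seed=seed, keep_outcome=True)
        spurious = assemble_graph([("X", "Z"), ("Z", "Y"), ("X", "Y")])
        pruned, tests = prune_edges(spurious, matrix)
        assert pruned.has_edge("Z", "Y")  # the real edge is never touched
        if not pruned.has_edge("X", "Y"):
            removed += 1
    assert removed >= 18  # >= 90% of seeds


def test_prune_reports_retained_edges(excerpt):
    g = assemble_graph([("B2", "B1"), ("B1", "C3"), ("B2", "C3")])
    pruned, tests = prune_edges(g, excerpt, threshold=1e-9)
    assert len(tests) == 1
    assert not tests[0].independent  # tiny threshold retains the edge
    assert pruned.number_of_edges() == 3


def test_prune_any_conditioner_rule(excerpt):
    # two conditioners; removal happens when at least one falls below threshold
    g = assemble_graph(
        [("B2", "B1"), ("B1", "C3"), ("B2", "B7"), ("B7", "C3"), ("B2", "C3")]
    )
    values = {
        z: conditional_mutual_information(excerpt, "B2", "C3", z) for z in ("B1", "B7")
    }
    threshold = (min(values.values()) + max(values.values())) / 2
    pruned, _ = prune_edges(g, excerpt, threshold=threshold)
    assert not pruned.has_edge("B2", "C3")


def test_prune_idempotent(excerpt):
    g = assemble_graph(
        [("B2", "B1"), ("B1", "C3"), ("B2", "C3"), ("B7", "D3"), ("D3", "C3")]
    )
    once, _ = prune_edges(g, excerpt)
    twice, _ = prune_edges(once, excerpt)
    assert set(once.edges) == set(twice.edges)


def test_prune_without_candidates_is_identity(excerpt):
    g = assemble_graph([("A1", "A3"), ("A3", "E1")])
    pruned, tests = prune_edges(g, excerpt)
    assert tests == []
    assert set(pruned.edges) == set(g.edges)


def test_sensitivity_grid_runs_on_excerpt(excerpt):
    """The log-base sensitivity sweep for the published test triples executes cleanly."""
    triples = [("B3", "A2", "A1"), ("B2", "C3", "B1"), ("B2", "C3", "B7"), ("B7", "C3", "D3")]
    for base in (2.0, np.e):
        for x, y, z in triples:
            value = conditional_mutual_information(excerpt, x, y, z, log_base=base)
            assert np.isfinite(value) and value >= -1e-12
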