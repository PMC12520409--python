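"""Laplace-smoothed priors, CPT rows, geometric-mean fallback, and model fitting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ffhrisk import (
    BayesianNetworkModel,
    EstimationConfig,
    assemble_graph,
    estimate_cpt_row,
    estimate_prior,
    fallback_row,
    fit_parameters,
    make_ground_truth,
    sample_reports,
)
from ffhrisk.errors import ValidationError
from ffhrisk.parameter_estimation import FALLBACK, OBSERVED, row_index, row_states
from ffhrisk.synthetic_data import GroundTruthSpec


# ------------------------------------------------------------- point values


@pytest.mark.parametrize(
    "x,n,alpha,expected",
    [
        (0, 368, 1.0, 1 / 370),  # never-observed factor stays strictly positive
        (184, 368, 1.0, 0.5),
        (368, 368, 1.0, 369 / 370),
    ],
)
def test_prior_values(x, n, alpha, expected):
    assert estimate_prior(x, n, alpha) == pytest.approx(expected)


@pytest.mark.parametrize(
    "x,n_c,alpha,expected",
    [
        (0, 0, 1.0, 0.5),  # no data: maximal uncertainty
        (15, 15, 1.0, 16 / 17),
        (3, 10, 1.0, 4 / 12),
    ],
)
def test_cpt_row_values(x, n_c, alpha, expected):
    assert estimate_cpt_row(x, n_c, alpha) == pytest.approx(expected)


@settings(derandomize=True, max_examples=100)
@given(st.integers(min_value=0, max_value=367))
def test_prior_monotone_in_count(x):
    assert estimate_prior(x + 1, 368) > estimate_prior(x, 368)


def test_prior_input_validation():
    with pytest.raises(ValueError):
        estimate_prior(5, 4)
    with pytest.raises(ZeroDivisionError):
        estimate_prior(0, 0, alpha=0)


# ----------------------------------------------------------------- fallback


def test_fallback_single_parent_passthrough():
    assert fallback_row([0.7]) == pytest.approx(0.7)


def test_fallback_hand_computed_pair():
    # g_T = g_F = sqrt(0.8*0.2) -> normalized to 0.5
    assert fallback_row([0.8, 0.2]) == pytest.approx(0.5)


@settings(derandomize=True, max_examples=50)
@given(st.floats(min_value=0.01, max_value=0.99), st.integers(min_value=1, max_value=5))
def test_fallback_equal_conditionals_passthrough(p, k):
    assert fallback_row([p] * k) == pytest.approx(p)


def test_fallback_rejects_degenerate_inputs():
    with pytest.raises(ValueError):
        fallback_row([0.0, 0.5])
    with pytest.raises(ValueError):
        fallback_row([])


# ----------------------------------------------------------- row indexing


def test_row_enumeration_true_first():
    # two parents: TT, TF, FT, FF
    assert [row_states(i, 2) for i in range(4)] == [
        (True, True),
        (True, False),
        (False, True),
        (False, False),
    ]
    assert row_index((True, True)) == 0
    assert row_index((False, False)) == 3


# -------------------------------------------------------------- fit_parameters


def test_edgeless_graph_gives_pure_priors(excerpt):
    g = assemble_graph([])
    g.add_nodes_from(["A1", "B2"])
    model = fit_parameters(excerpt, g, outcome_id=None)
    assert model.cpts["A1"].p_true[0] == pytest.approx((7 + 1) / (16 + 2))


def test_chain_fit_recovers_truth_within_sampling_error():
    truth = make_ground_truth(
        GroundTruthSpec(
            topology=(("X", "Y"), ("Y", "Z")),
            cpt_source={"X": [0.6], "Y": [0.8, 0.3], "Z": [0.7, 0.2]},
        )
    )
    matrix = sample_reports(truth, 1000, seed=42, keep_outcome=True)
    model = fit_parameters(matrix, truth.graph, outcome_id=None)
    for node in ("X", "Y", "Z"):
        fitted, true = model.cpts[node].p_true, truth.cpts[node].p_true
        assert np.all(np.abs(fitted - true) < 0.05)
        assert all(p == OBSERVED for p in model.cpts[node].provenance)


def test_unseen_parent_combo_flagged_fallback():
    truth = make_ground_truth(
        GroundTruthSpec(
            topology=(("A", "C"), ("B", "C")),
            cpt_source={"A": [0.95], "B": [0.95], "C": [0.9, 0.6, 0.5, 0.1]},
        )
    )
    rng_matrix = sample_reports(truth, 60, seed=1, keep_outcome=True)
    # force the all-FALSE parent combo to be absent
    data = rng_matrix.data[(rng_matrix.data["A"] == 1) | (rng_matrix.data["B"] == 1)]
    from ffhrisk.factor_model import IncidenceMatrix

    matrix = IncidenceMatrix(data)
    model = fit_parameters(matrix, truth.graph, outcome_id=None)
    provenance = model.cpts["C"].provenance
    assert provenance[row_index((False, False))] == FALLBACK
    assert OBSERVED in provenance


def test_missing_node_is_validation_error(excerpt):
    g = assemble_graph([("A1", "Z9")])
    with pytest.raises(ValidationError, match="Z9"):
        fit_parameters(excerpt, g, outcome_id=None)


def test_outcome_without_column_treated_all_true(excerpt):
    g = assemble_graph([("D1", "FFHA"), ("E1", "FFHA")])
    model = fit_parameters(excerpt, g)
    cpt = model.cpts["FFHA"]
    # observed combos follow (N_C + a)/(N_C + 2a) and exceed 1/2
    for row, prov in enumerate(cpt.provenance):
        if prov == OBSERVED:
            assert cpt.p_true[row] > 0.5


def test_explicit_outcome_column(excerpt):
    g = assemble_graph([("D1", "FFHA")])
    outcome = np.zeros(excerpt.n_reports, dtype=np.int8)  # all controls
    model = fit_parameters(excerpt, g, outcome_column=outcome)
    assert np.all(model.cpts["FFHA"].p_true < 0.5)


def test_fit_deterministic(excerpt):
    g = assemble_graph([("B2", "B1"), ("B1", "D1")])
    a = fit_parameters(excerpt, g, outcome_id=None)
    b = fit_parameters(excerpt, g, outcome_id=None)
    for node in a.cpts:
        assert np.array_equal(a.cpts[node].p_true, b.cpts[node].p_true)


def test_parent_order_override(excerpt):
    g = assemble_graph([("B2", "D1"), ("E1", "D1")])
    default = fit_parameters(excerpt, g, outcome_id=None)
    flipped = fit_parameters(
        excerpt, g, outcome_id=None, parent_order={"D1": ["E1", "B2"]}
    )
    assert default.cpts["D1"].parents == ("B2", "E1")
    assert flipped.cpts["D1"].parents == ("E1", "B2")
    # same distribution, permuted rows
    assert flipped.cpts["D1"].p([True, False]) == default.cpts["D1"].p([False, True])
    with pytest.raises(ValidationError):
        fit_parameters(excerpt, g, outcome_id=None, parent_order={"D1": ["E1", "E1"]})


def test_model_json_round_trip(tmp_path, excerpt):
    g = assemble_graph([("B2", "B1"), ("B1", "D1"), ("D1", "FFHA")])
    model = fit_parameters(excerpt, g)
    path = tmp_path / "model.json"
    model.to_json(path)
    back = BayesianNetworkModel.from_json(path)
    assert set(back.graph.edges) == set(model.graph.edges)
    for node in model.cpts:
        assert np.array_equal(back.cpts[node].p_true, model.cpts[node].p_true)
        assert back.cpts[node].parents == model.cpts[node].parents
        assert back.cpts[node].provenance == model.cpts[node].provenance


def test_smoothing_keeps_probabilities_interior(excerpt):
    g = assemble_graph([("B2", "B1"), ("B6", "C1"), ("C1", "FFHA")])
    model = fit_parameters(excerpt, g, EstimationConfig(alpha=0.5))
    for cpt in model.cpts.values():
        assert np.all((cpt.p_true > 0) & (cpt.p_true < 1))
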