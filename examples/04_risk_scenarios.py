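"""Enumerate and rank all 128 risk scenarios of the accident outcome.

A scenario is one TRUE/FALSE assignment of the outcome's seven parent
factors (A2, D1, C3, E1, E2, E3, C1); its probability is the fitted
P(FFHA=TRUE | scenario).
"""

from ffhrisk import (
    FFH21_OUTCOME_PARENT_ORDER,
    GroundTruthSpec,
    enumerate_scenarios,
    fit_parameters,
    make_ground_truth,
    sample_reports,
    top_scenarios,
)

truth = make_ground_truth(GroundTruthSpec(topology="ffh21", seed=7))
matrix = sample_reports(truth, 368, seed=11, condition_outcome_true=True)
model = fit_parameters(
    matrix, truth.graph, parent_order={"FFHA": list(FFH21_OUTCOME_PARENT_ORDER)}
)

table = enumerate_scenarios(model, "FFHA")
print(f"scenario table: {len(table)} rows over parents {table.parent_order}")
print("\nFive highest-risk scenarios:")
for rank, s in enumerate(top_scenarios(table, 5), start=1):
    present = [p for p, v in s.assignment if v]
    absent = [p for p, v in s.assignment if not v]
    print(
        f"  {rank}. {100 * s.p_outcome:.2f}%  present: {', '.join(present) or '-'};"
        f"  absent: {', '.join(absent) or '-'}"
    )
print(
    "\nEach percentage is the conditional accident probability for that exact"
    " combination of present/absent risk factors (rows do not sum to 1)."
)
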