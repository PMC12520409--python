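"""Fit CPTs from accident reports and run predictive/diagnostic queries.

Samples a synthetic accident-only corpus (368 reports) from the bundled
21-node ground-truth network, fits Laplace-smoothed parameters, and shows
both reasoning directions: forward (accident probability given observed
factors) and backward (factor probability given that an accident happened).
"""

from ffhrisk import (
    FFH21_OUTCOME_PARENT_ORDER,
    GroundTruthSpec,
    diagnostic_probabilities,
    fit_parameters,
    make_ground_truth,
    posterior,
    sample_reports,
)

truth = make_ground_truth(GroundTruthSpec(topology="ffh21", seed=7))
matrix = sample_reports(truth, 368, seed=11, condition_outcome_true=True)
model = fit_parameters(
    matrix, truth.graph, parent_order={"FFHA": list(FFH21_OUTCOME_PARENT_ORDER)}
)

evidence = {"D1": True, "B2": True, "B7": True, "B1": True}
pred = posterior(model, "FFHA", evidence)
print(f"P(FFHA=TRUE | {', '.join(evidence)}) = {100 * pred.p_true:.1f}%")

diag = diagnostic_probabilities(model, "FFHA")
top5 = sorted(diag.items(), key=lambda kv: -kv[1])[:5]
print("\nTop five factors given an observed accident:")
for node, p in top5:
    print(f"  {node}: {100 * p:.1f}%")
print(
    "\nForward inference predicts accident risk from observed deficiencies;"
    " diagnostic inference ranks which deficiencies most likely accompanied"
    " an accident that did occur."
)
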