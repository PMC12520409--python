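"""End-to-end recovery benchmark on fully synthetic inputs.

Generates questionnaires and an accident-only report corpus from a known
ground-truth network, runs the whole fuse -> screen -> prune pipeline, and
checks whether the recovered structure equals the ground truth.
"""

from ffhrisk import (
    GroundTruthSpec,
    aggregate_responses,
    assemble_graph,
    make_ground_truth,
    prune_edges,
    sample_reports,
    screen_edges,
    simulate_questionnaires,
)
from ffhrisk.evidence_fusion import combine_supports
from ffhrisk.synthetic_data import FFH21_EDGES

truth = make_ground_truth(GroundTruthSpec(topology="ffh21", seed=7))
decoys = [("B4", "E3"), ("C2", "D2"), ("A2", "B6"), ("E3", "C2"), ("B8", "D3")]
candidates = list(FFH21_EDGES) + decoys

successes = 0
n_seeds = 5
for seed in range(1, n_seeds + 1):
    responses = simulate_questionnaires(
        truth.graph, candidates, n_expert=11, n_frontline=41, noise_sd=1.5, seed=seed
    )
    kept = screen_edges(combine_supports([aggregate_responses(r) for r in responses]))
    matrix = sample_reports(truth, 368, seed=100 + seed, condition_outcome_true=True)
    pruned, _ = prune_edges(assemble_graph(kept), matrix)
    recovered = set(pruned.edges) == set(FFH21_EDGES)
    successes += recovered
    print(f"seed {seed}: kept {len(kept)}/{len(candidates)} candidates, "
          f"structure recovered exactly: {recovered}")

print(f"\n{successes}/{n_seeds} seeds recover the ground-truth structure exactly")
print(
    "Recovery means the panel screen rejected every decoy edge, kept every"
    " true edge, and the CMI prune removed nothing real — at the realistic"
    " panel sizes (11 experts, 41 frontline) and corpus size (368 reports)."
)
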