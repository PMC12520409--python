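"""Refine an expert-elicited DAG with conditional-mutual-information tests.

Builds the screened 26-edge candidate graph (25 panel-screened edges plus
the administrative-supervision -> unauthorized-construction link), finds the
mediated shortcut edges d-separation marks as possibly redundant, and tests
them against the bundled 16-report incidence excerpt.
"""

from ffhrisk import (
    assemble_graph,
    load_elicited_supports,
    load_incidence_excerpt,
    prune_edges,
)

supports = load_elicited_supports()
edges = list(zip(supports["from"], supports["to"])) + [("B3", "A2")]
graph = assemble_graph(edges)
matrix = load_incidence_excerpt()

pruned, tests = prune_edges(
    graph, matrix, threshold=0.02, extra=[(("B3", "A2"), "A1")]
)

print(f"candidate graph: {graph.number_of_nodes()} nodes, {graph.number_of_edges()} edges")
print(f"{'edge':<12}{'given':>7}{'I(X;Y|Z) bits':>15}  verdict")
for t in tests:
    verdict = "independent -> remove" if t.independent else "dependent -> keep"
    print(f"{t.edge[0]+' -> '+t.edge[1]:<12}{t.conditioner:>7}{t.value:>15.4f}  {verdict}")
print(f"refined graph: {pruned.number_of_edges()} edges")
print(
    "\nAn edge is dropped when, conditioned on a mediator, the two factors"
    " share less than 0.02 bits of information in the report data — the"
    " direct link is then explained by the mediated path."
    "\n(Values here use the 16-report excerpt; the full 368-report corpus"
    " gives the decisive estimates.)"
)
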