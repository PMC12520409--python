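"""Fuse the two elicitation panels' edge supports with Dempster's rule.

Loads the bundled panel-level support summary for 25 candidate causal edges
between fall-from-height risk factors, fuses each edge's expert and
frontline support masses, and screens with Bel/Pl >= 0.8 and k < 0.5.
"""

from ffhrisk import ScreeningRule, dempster_combine, load_elicited_supports, screen_edges

supports = load_elicited_supports()
fused = [
    dempster_combine(r.expert_support, r.frontline_support, (r["from"], r.to)).rounded()
    for _, r in supports.iterrows()
]

print(f"{'edge':<12}{'m1':>6}{'m2':>8}{'Bel=Pl':>9}{'k':>9}")
for row, f in zip(supports.itertuples(), fused):
    print(
        f"{f.edge[0]+' -> '+f.edge[1]:<12}{row.expert_support:>6.2f}"
        f"{row.frontline_support:>8.3f}{f.bel:>9.4f}{f.k:>9.4f}"
    )

kept = screen_edges(fused, ScreeningRule(bel_min=0.8, k_max=0.5))
print(f"\n{len(kept)}/{len(fused)} edges pass the screen.")
print(
    "Bel is the fused confidence that the causal link exists; k measures how"
    " much the two panels contradict each other (k < 0.5 = acceptable agreement)."
)
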