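"""Rank candidate functional-differentiation sites between two ortholog groups.

Builds a synthetic pooled alignment of 27 group-A and 24 group-B
orthologs with one planted specificity-determining column (group A
prefers Ala at 82%, group B prefers His at 99%), then scores every
column with the symmetric Kullback-Leibler divergence and prints the top
five sites with their reference coordinates and per-group conservation.
"""

from etrace import (
    MSASimConfig,
    PlantedSite,
    conservation_pct,
    score_all_sites,
    simulate_grouped_msa,
    top_sites,
)

cfg = MSASimConfig(
    planted_sites=[PlantedSite(column=42, modal_a="A", modal_b="H",
                               freq_a=0.82, freq_b=0.99)],
    seed=7,
)
ga, truth = simulate_grouped_msa(cfg)
report = score_all_sites(ga, pseudocount=0.5, min_occupancy=0.5)

print(f"planted ground truth: column {truth[0][0]} "
      f"({truth[0][1]} in group A vs {truth[0][2]} in group B)\n")
print("rank  column  refA        refB        KL")
for i, s in enumerate(top_sites(report, 5), start=1):
    ref_a = f"{s.modal_a}{s.ref_a_pos} {conservation_pct(s.conservation_a)}%"
    ref_b = f"{s.modal_b}{s.ref_b_pos} {conservation_pct(s.conservation_b)}%"
    print(f"{i:>4}  {s.column:>6}  {ref_a:<10}  {ref_b:<10}  {s.kl:.4f}")

print(
    "\nThe rank-1 column is the planted site: its KL separates cleanly from"
    "\nthe background because the two groups prefer different residues there,"
    "\nwhile every other column is either conserved across both groups or"
    "\nnear-uniformly variable in both."
)
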