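"""The whole screen at study scale, ending in the candidate-gene table.

Generates the study-shaped lineage (parent with 126 SNPs + 22 indels, one
sibling adding 97 + 11, the focal strain inheriting 107 + 10 and adding
77 + 30 of its own), then runs filter -> annotate -> effects -> subtract
-> select and prints the tables the knockout screen would start from.
"""

from mutscreen import (
    Pedigree,
    SimConfig,
    candidate_table,
    crosstab_table,
    run_screen,
    simulate_genome,
    simulate_pedigree_variants,
)

config = SimConfig.study(seed=1)
genome, models = simulate_genome(config)
strains, _ = simulate_pedigree_variants(config, genome, models)
report = run_screen(genome, models, strains,
                    Pedigree(config.focal, config.comparison_strains))

print("element cross-tabulation (all focal variants | unique subset):")
print(crosstab_table(report).to_string(index=False))

cand = candidate_table(report)
print(f"\ncandidate genes: {len(cand)}")
print(cand.head(5).to_string(index=False))
print("\nEach candidate carries at least one focal-unique variant in its")
print("promoter, exon, intron or terminator; these are the genes one would")
print("knock out to test for a causal role in the focal phenotype.")
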