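"""Gene association and overlap (Venn) analysis.

Associates called DMRs with genes within 10 kb (gene body anchor, flanks
included), tallies gene functional categories from a static map, and
computes interval overlaps between two feature sets.
"""

import medipdmr as m
from medipdmr.config import SimulationConfig
from medipdmr.simulate import simulate_gene_category_map, simulate_gene_models

config = SimulationConfig(seed=4, chrom_length_bp=500_000, n_planted_dmrs=8)
_, chrom_sizes = m.simulate_genome(config)
_, _, truth = m.simulate_medip_experiment(config, chrom_sizes, emit_fragments=False)

# use the planted regions as a stand-in DMR table for this annotation demo
dmrs = truth.planted_dmrs.copy()
dmrs["dmr_id"] = [f"DMR{i + 1:03d}" for i in range(len(dmrs))]

genes = simulate_gene_models(config, chrom_sizes, n_genes=40)
mapping = simulate_gene_category_map(config, genes)

assoc = m.associate_genes(dmrs, genes, max_dist_bp=10_000)
n_with_genes = sum(1 for lst in assoc if lst)
print(f"{n_with_genes} of {len(dmrs)} DMRs lie within 10 kb of a gene")

gene_list = sorted({g for lst in assoc for g in lst})
print("category counts for DMR-associated genes:")
print(m.map_counts(gene_list, mapping).to_string(index=False))

v = m.venn_intervals(dmrs, genes)
print(f"interval Venn: |A|={v.a_size} |B|={v.b_size}, "
      f"A overlapping B: {v.a_common}, B overlapping A: {v.b_common}")
vid = m.venn_ids(["g1", "g2", "g3"], ["g2", "g3", "g4"])
print(f"id Venn: common={vid.common}, A-only={vid.a_only}, B-only={vid.b_only}")
# interval overlap needs >= 1 bp; gene association allows a 10 kb gap so
# promoter/flank contacts count.
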