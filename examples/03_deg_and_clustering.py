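"""Expression filtering, DEG counting and genotype clustering.

On a simulated population: count expressed genes per genotype (RPKM > 0.5),
tally >2-fold differentially expressed genes between a progeny and each
parent, and cluster the genotypes by expression-profile correlation.
"""

import tcna
from tcna import FilterConfig, PopulationSimConfig

matrix, truth = tcna.simulate_population(
    PopulationSimConfig(n_background=300, dropout_fraction=0.2, seed=7))

_, counts = tcna.filter_expressed(matrix, FilterConfig(rpkm_min=0.5))
print("expressed genes per genotype (RPKM > 0.5):")
for s in list(counts)[:4]:
    print(f"  {s}: {counts[s]} of {matrix.n_genes}")

for parent in ("parent_A", "parent_B"):
    deg = tcna.count_deg(matrix, "progeny_01", parent)
    print(f"progeny_01 vs {parent}: {deg.n_up} up / {deg.n_down} down "
          f"(> {deg.fold_threshold:g}-fold, {deg.n_genes_considered} genes)")

dend = tcna.cluster_genotypes(matrix, metric="correlation",
                              linkage_method="average")
print(f"dendrogram over {len(dend.leaves)} genotypes "
      f"({dend.metric} distance, {dend.linkage_method} linkage)")
print("newick:", dend.to_newick()[:70], "...")
# Up/down counts are antisymmetric between the two directions of the same
# comparison; dropout genes fall below the expressed filter in every sample.
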