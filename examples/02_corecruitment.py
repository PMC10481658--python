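"""Core co-recruitment nodes of one promoter cluster.

Mines regulator combinations present at >= 50% of a cluster's promoters
(frequent itemsets), summarizes how often each TF occurs across those
core nodes, and embeds the TF-TF Tanimoto distances with classical MDS.
"""

from protfnet import binding, corecruit
from protfnet.synthetic import (SyntheticConfig, generate_cistromes,
                                generate_tss_annotation)

cfg = SyntheticConfig(n_tfs=12, n_promoters=120, n_binding_clusters=3,
                      binding_noise=0.05, rng_seed=1)
cistromes, truth = generate_cistromes(cfg)
tss, truth = generate_tss_annotation(cfg, truth)
crms = binding.merge_peaks_to_crms(cistromes)
records = binding.map_crms_to_promoters(crms, tss,
                                        gene_filter=set(cfg.gene_ids))
matrix = binding.build_binding_matrix(records, tf_universe=cfg.tf_names)

members = [g for g in matrix.index if truth.promoter_cluster[g] == 0]
itemsets = corecruit.mine_frequent_itemsets(matrix.loc[members],
                                            min_support=0.5, size_min=2,
                                            size_max=None)
print(f"cluster 0: {len(members)} promoters, "
      f"{len(itemsets)} core co-recruitment nodes")
top = itemsets.head(3).copy()
top["itemset"] = top["itemset"].map(lambda s: "+".join(sorted(s)))
print(top.to_string(index=False))

occurrence = corecruit.core_node_occurrence(itemsets, list(matrix.columns))
print("TFs in >= 50% of core nodes:",
      ", ".join(occurrence.index[occurrence >= 50]))

tanimoto = corecruit.tanimoto_distance_matrix(matrix)
embedding = corecruit.mds_embedding(tanimoto, dims=2)
print("MDS spread (dim1, dim2 std):",
      embedding.std().round(3).tolist())
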