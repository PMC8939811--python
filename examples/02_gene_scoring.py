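"""Score genes with the LD-aware SNP-wise mean statistic.

Maps SNVs to genes under the baseline model and under the baseline augmented
with regulatory interactions, scores every gene (mean of per-SNV 1-df
chi-squares against a weighted-chi-square null), adjusts for technical
covariates, and prints the genes that respond to augmentation.
"""

import rigsa
from rigsa.simulate import default_fixture

panel, arch, sumstats = default_fixture(seed=1)

features = rigsa.build_flanked_features(arch.genes, 10, 10)
base_anns = rigsa.annotate_features_with_snvs(features, panel.variants)
elements = rigsa.process_ri_dataset(arch.regulatory_interactions, arch.genes)
elem_anns = rigsa.annotate_features_with_snvs(elements, panel.variants)

baseline_map = rigsa.aggregate_snv_gene_map(base_anns, None, "U10D10")
augmented_map = rigsa.aggregate_snv_gene_map(base_anns, elem_anns, "U10D10+RI")

res_base, _ = rigsa.score_genes(baseline_map, sumstats, panel, compute_correlations=False)
res_aug, _ = rigsa.score_genes(augmented_map, sumstats, panel, compute_correlations=False)

print(f"genes scored: baseline {len(res_base)}, augmented {len(res_aug)}")
print(f"FDR-significant genes: baseline {(res_base.p_fdr < 0.05).sum()}, "
      f"augmented {(res_aug.p_fdr < 0.05).sum()}")

gains = rigsa.compute_gains(res_base, res_aug, level="gene")
top = gains.sort_values("gain", ascending=False).head(5)
print("\ntop-gaining genes (adjusted Z, augmented - baseline):")
print(top.to_string(index=False))
print("\n-> genes whose distal elements carry planted causal SNVs gain several")
print("   Z units; a positive gain means augmentation strengthened the gene's")
print("   phenotype association.")
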