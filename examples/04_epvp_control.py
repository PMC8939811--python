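"""EPVP: validate augmentation gains against matched random augmentation.

Circularly shifts SNV-level p-values and sample sizes within each chromosome,
assigns the shifted values only to extragenic SNVs (those mapped to a gene
solely through augmentation), rescores everything, and classifies each gaining
set by how far its genuine score sits above the permutation distribution.
"""

import numpy as np

import rigsa
from rigsa.epvp import classify_validation, run_epvp, ttest_genuine_vs_permuted
from rigsa.simulate import default_fixture

panel, arch, sumstats = default_fixture(seed=1)
gene_sets = {gs.set_id: tuple(gs.gene_ids) for gs in arch.gene_sets}

features = rigsa.build_flanked_features(arch.genes, 10, 10)
base_anns = rigsa.annotate_features_with_snvs(features, panel.variants)
elem_anns = rigsa.annotate_features_with_snvs(
    rigsa.process_ri_dataset(arch.regulatory_interactions, arch.genes), panel.variants
)
snv_map = rigsa.aggregate_snv_gene_map(base_anns, elem_anns, "U10D10+RI")
gene_res, ctx = rigsa.score_genes(snv_map, sumstats, panel)
set_res = rigsa.run_gsa(gene_res, gene_sets, ctx.correlations, set_size_range=(10, 200))

runs = run_epvp(ctx, gene_sets, n_perm=20, seed=1, set_size_range=(10, 200))

genuine_count = int((gene_res["p_fdr"] < 0.05).sum())
perm_counts = [int((r.gene_results["p_fdr"] < 0.05).sum()) for r in runs]
print(f"significant genes: genuine {genuine_count}, permutations "
      f"mean {np.mean(perm_counts):.1f} (max {max(perm_counts)})")
print(f"one-sided t-test genuine > permuted: p = {ttest_genuine_vs_permuted(genuine_count, perm_counts):.2e}")

planted = arch.enriched_set_ids[0]
z_genuine = float(set_res.set_index("set_id").loc[planted, "z_set"])
perm_scores = [float(r.set_results.set_index("set_id").loc[planted, "z_set"]) for r in runs]
v = classify_validation(z_genuine, perm_scores, planted)
print(f"\nplanted set {planted}: genuine score {v.z_genuine:.2f}, permutation "
      f"{v.perm_mean:.2f} +/- {v.perm_sd:.2f} -> {v.category}")
print("-> a gain at least two SDs above the matched-random mean is specific to")
print("   the genuine element-to-gene assignment, not to added mapping size.")
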