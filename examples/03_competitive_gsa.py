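"""Competitive gene-set analysis and set-level gains from augmentation.

Tests every gene set for enrichment of phenotype association (GLS on adjusted
gene scores with LD-induced gene-gene correlations), then compares set scores
(probit of 1 - FDR-adjusted p) between the baseline and augmented mappings.
"""

import rigsa
from rigsa.simulate import default_fixture

panel, arch, sumstats = default_fixture(seed=1)
gene_sets = {gs.set_id: tuple(gs.gene_ids) for gs in arch.gene_sets}

features = rigsa.build_flanked_features(arch.genes, 10, 10)
base_anns = rigsa.annotate_features_with_snvs(features, panel.variants)
elem_anns = rigsa.annotate_features_with_snvs(
    rigsa.process_ri_dataset(arch.regulatory_interactions, arch.genes), panel.variants
)

results = {}
for label, aug in [("baseline", None), ("augmented", elem_anns)]:
    snv_map = rigsa.aggregate_snv_gene_map(base_anns, aug, label)
    gene_res, ctx = rigsa.score_genes(snv_map, sumstats, panel)
    results[label] = rigsa.run_gsa(gene_res, gene_sets, ctx.correlations, set_size_range=(10, 200))

for label, df in results.items():
    sig = df[df["p_fdr"] < 0.05]
    print(f"{label}: {len(sig)} significant gene sets "
          f"{sorted(sig['set_id'].tolist())}")

gains = rigsa.compute_gains(results["baseline"], results["augmented"], level="set")
planted = arch.enriched_set_ids[0]
row = gains.set_index("entity_id").loc[planted]
print(f"\nplanted set {planted}: score {row.score_baseline:.2f} -> {row.score_augmented:.2f} "
      f"(gain {row.gain:+.2f}, gaining={bool(row.gaining)})")
print("-> the set carrying planted distal signal becomes significant only with")
print("   augmentation, and its probit-scale score gain quantifies the benefit.")
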