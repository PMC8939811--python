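"""IRED: how many genes carry a gene set's gain from augmentation?

Ranks the planted set's genes by their score gain, removes them cumulatively
(top-gaining first), re-runs the competitive gene-set analysis for both
mappings after each removal, and reports the number of removals needed to
erase the set-level gain.  Four or more removals mark the gain as robust.
"""

import rigsa
from rigsa.ired import ired_run
from rigsa.simulate import default_fixture

panel, arch, sumstats = default_fixture(seed=1)
gene_sets = {gs.set_id: tuple(gs.gene_ids) for gs in arch.gene_sets}

features = rigsa.build_flanked_features(arch.genes, 10, 10)
base_anns = rigsa.annotate_features_with_snvs(features, panel.variants)
elem_anns = rigsa.annotate_features_with_snvs(
    rigsa.process_ri_dataset(arch.regulatory_interactions, arch.genes), panel.variants
)
res = {}
for label, aug in [("baseline", None), ("augmented", elem_anns)]:
    m = rigsa.aggregate_snv_gene_map(base_anns, aug, label)
    res[label] = rigsa.score_genes(m, sumstats, panel)

planted = arch.enriched_set_ids[0]
trace = ired_run(
    planted,
    res["baseline"][0], res["augmented"][0],
    res["baseline"][1].correlations, res["augmented"][1].correlations,
    gene_sets, set_size_range=(10, 200),
)
print(f"IRED trace for {planted} (set gain on the probit scale):")
print(trace.to_frame().to_string(index=False))
print(f"\niterations to loss: {trace.iterations_to_loss}   robust: {trace.robust}")
print("-> the gain survives removal of the top-gaining genes one by one; losing")
print("   it only after >= 4 removals means many genes, not one outlier, carry it.")
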