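"""Generate the synthetic study conditions and inspect signal placement.

Builds a block-LD reference panel, a regulatory architecture with one
planted-enriched gene set, and matching GWAS summary statistics, then shows
that every planted causal SNV lies outside the proximity-based baseline
mapping (gene body +/- 10 kb) — only regulatory augmentation can recover it.
"""

import numpy as np

import rigsa
from rigsa.simulate import default_fixture

panel, arch, sumstats = default_fixture(seed=1)

print(f"reference panel : {panel.sample_count} samples x {panel.n_variants} SNVs")
print(f"genes           : {len(arch.genes)}   gene sets: {len(arch.gene_sets)}")
print(f"regulatory elems: {len(arch.regulatory_interactions)}")
print(f"causal SNVs     : {len(arch.causal_plan)} (lambda = {arch.causal_plan[0][1]})")
print(f"enriched set    : {arch.enriched_set_ids[0]}")

features = rigsa.build_flanked_features(arch.genes, 10, 10)
anns = rigsa.annotate_features_with_snvs(features, panel.variants)
baseline = rigsa.aggregate_snv_gene_map(anns, None, "baseline")
mapped = set().union(*(set(e.snv_ids) for e in baseline.genes.values()))
causal = {rsid for rsid, _ in arch.causal_plan}
print(f"causal SNVs captured by the baseline mapping: {len(causal & mapped)} (expected 0)")

strong = (sumstats["pval"] < 5e-8).sum()
print(f"genome-wide significant SNVs in the simulated GWAS: {strong}")
print("-> the association signal exists but sits in distal elements, invisible")
print("   to proximity-based SNV-to-gene mapping.")
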