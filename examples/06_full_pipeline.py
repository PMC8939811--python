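"""One-call controlled analysis: mapping ladder, gains, EPVP, IRED, trends.

Runs the whole controlled comparison on the default synthetic conditions: a
flank ladder plus a regulatory-interaction augmentation of the baseline,
summary-statistics QC, gene and gene-set scoring, redundancy reduction, gains,
the EPVP permutation control, and IRED on validated gaining sets.
"""

from rigsa.pipeline import PipelineConfig, run_controlled_analysis
from rigsa.simulate import default_fixture

panel, arch, sumstats = default_fixture(seed=1)
config = PipelineConfig(
    panel=panel,
    genes=arch.genes,
    sumstats=sumstats,
    gene_sets=arch.gene_sets,
    ri_datasets={"RI": arch.regulatory_interactions},
    flank_ladder=[(0, 0), (2, 2), (10, 10), (20, 20), (50, 50), (100, 100)],
    set_size_range=(10, 200),
    n_perm=20,
    seed=1,
)
report = run_controlled_analysis(config)

print(report.per_mapping.to_string(index=False))
e = report.epvp["RI"]
print(f"\nEPVP (RI augmentation): genuine significant genes "
      f"{e['genuine_sig_gene_count']} vs permutation max {max(e['perm_sig_gene_counts'])} "
      f"(t-test p = {e['p_ttest']:.2e})")
for v in e["validations"]:
    print(f"  {v.set_id}: genuine {v.z_genuine:.2f} vs permuted {v.perm_mean:.2f} "
          f"+/- {v.perm_sd:.2f} -> {v.category}")
for set_id, trace in report.ired.get("RI", {}).items():
    print(f"  IRED {set_id}: iterations to loss {trace.iterations_to_loss} "
          f"(robust={trace.robust})")
print(f"\ntrends: coverage vs significant genes rho = "
      f"{report.trends['rho_coverage_genes']:.3f} "
      f"(p = {report.trends['p_coverage_genes']:.4f})")
print("-> coverage drives significant-gene counts; only the planted set's gain")
print("   survives the permutation control and the robustness check.")
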