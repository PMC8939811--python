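"""End-to-end controlled analysis across a ladder of SNV-to-gene mappings.

The orchestrator processes the summary statistics once, builds a ladder of
flank-based mappings plus regulatory-interaction augmentations of the baseline
model, scores genes and gene sets for every mapping, restricts evaluations to
the common scored universe, computes gains against the baseline, runs the
permutation control (EPVP) on the augmentations, runs the iterative-reduction
robustness check (IRED) on validated gaining sets, and reports comparison
counts and trend statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import child_rng
from .epvp import ValidationResult, classify_validation, run_epvp, ttest_genuine_vs_permuted
from .gsa import compute_gains, reduce_redundant_sets, run_gsa
from .ired import IredTrace, ired_run
from .mapping import (
    FeatureAnnotation,
    GeneModel,
    RegulatoryElement,
    SnvGeneMap,
    aggregate_snv_gene_map,
    annotate_features_with_snvs,
    build_flanked_features,
    compute_coverage,
    process_ri_dataset,
)
from .scoring import ScoringContext, score_genes
from .simulate import GeneSetDef, ReferencePanel
from .sumstats import VariantDictionary, process_sumstats

__all__ = [
    "PipelineConfig",
    "ComparisonReport",
    "classify_model_changes",
    "trend_statistics",
    "run_controlled_analysis",
    "relabel_origin",
]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    panel: ReferencePanel
    genes: list[GeneModel]
    sumstats: pd.DataFrame  # raw records; processed internally
    gene_sets: list[GeneSetDef]
    ri_datasets: dict[str, list[RegulatoryElement]] = field(default_factory=dict)
    flank_ladder: list[tuple[float, float]] = field(
        default_factory=lambda: [(0, 0), (2, 2), (10, 10), (20, 20), (50, 50), (100, 100)]
    )
    baseline_flanks: tuple[float, float] = (10, 10)
    alpha: float = 0.05
    set_size_range: tuple[int, int] = (25, 200)
    n_perm: int = 20
    seed: int = 0
    exclusion_region: tuple[int, int, int] | None = None
    window_bp: int = 1_000_000
    epvp_mappings: list[str] | None = None  # defaults to all RI augmentations
    run_ired: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if self.baseline_flanks not in self.flank_ladder:
            self.flank_ladder = [*self.flank_ladder, self.baseline_flanks]


@dataclass
class ComparisonReport:
    baseline_label: str
    per_mapping: pd.DataFrame
    gene_results: dict[str, pd.DataFrame]
    set_results: dict[str, pd.DataFrame]
    contexts: dict[str, ScoringContext]
    sig_genes: dict[str, set[str]]
    sig_sets: dict[str, set[str]]
    reduced_sig_sets: dict[str, list[str]]
    changes: dict[str, dict] = field(default_factory=dict)
    gains: dict[str, dict] = field(default_factory=dict)
    epvp: dict[str, dict] = field(default_factory=dict)
    ired: dict[str, dict[str, IredTrace]] = field(default_factory=dict)
    trends: dict[str, float] = field(default_factory=dict)
    seeds: dict[str, int] = field(default_factory=dict)


def relabel_origin(snv_map: SnvGeneMap, baseline_map: SnvGeneMap) -> SnvGeneMap:
    """Set origin labels of a mapping relative to the baseline model: a SNV is
    intragenic for a gene iff the baseline model maps it to that gene."""
    for gene_id, entry in snv_map.genes.items():
        base = baseline_map.genes.get(gene_id)
        base_ids = set(base.snv_ids.tolist()) if base is not None else set()
        entry.intragenic = np.array([s in base_ids for s in entry.snv_ids], dtype=bool)
    return snv_map


def classify_model_changes(
    sig_baseline: set[str],
    sig_augmented: set[str],
) -> tuple[set[str], set[str], set[str]]:
    """(novel, known, lost) entity ids between two mappings' significant sets."""
    return (
        sig_augmented - sig_baseline,
        sig_augmented & sig_baseline,
        sig_baseline - sig_augmented,
    )


def trend_statistics(
    x: np.ndarray | list[float],
    y: np.ndarray | list[float],
    alternative: str = "greater",
) -> tuple[float, float]:
    """Spearman rank correlation with a one-sided p-value.

    Raises for fewer than 4 pairs or constant input (undefined ranks)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 4:
        raise ValueError("need at least 4 mappings for a rank trend")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("trend undefined for constant input; add more mappings")
    res = stats.spearmanr(x, y, alternative=alternative)
    return float(res.statistic), float(res.pvalue)


def wilcoxon_attenuation(score_baseline: np.ndarray, score_augmented: np.ndarray) -> float:
    """One-sided paired Wilcoxon: do augmented scores tend to fall below the
    baseline scores?  All-tied input returns 1 with a warning."""
    diff = np.asarray(score_augmented, dtype=float) - np.asarray(score_baseline, dtype=float)
    if np.all(diff == 0):
        logger.warning("wilcoxon_attenuation: all paired scores tied")
        return 1.0
    return float(stats.wilcoxon(diff, alternative="less").pvalue)


def _flank_label(up: float, down: float) -> str:
    return f"U{up:g}D{down:g}"


def run_controlled_analysis(config: PipelineConfig) -> ComparisonReport:
    """Execute the full controlled comparison described in the module docstring."""
    panel, genes = config.panel, config.genes
    dictionary = VariantDictionary.from_panel(panel)
    ss = process_sumstats(config.sumstats, dictionary, exclusion_region=config.exclusion_region)
    ss_ids = set(ss["rsid"])
    gene_sets = {gs.set_id: tuple(gs.gene_ids) for gs in config.gene_sets}

    baseline_label = _flank_label(*config.baseline_flanks)
    base_features = build_flanked_features(genes, *config.baseline_flanks)
    base_anns = annotate_features_with_snvs(base_features, panel.variants, config.exclusion_region)
    baseline_map = aggregate_snv_gene_map(base_anns, None, baseline_label)

    mappings: dict[str, SnvGeneMap] = {}
    annotations: dict[str, list[FeatureAnnotation]] = {}
    for up, down in config.flank_ladder:
        label = _flank_label(up, down)
        if label == baseline_label:
            mappings[label] = baseline_map
            annotations[label] = base_anns
            continue
        feats = build_flanked_features(genes, up, down)
        anns = annotate_features_with_snvs(feats, panel.variants, config.exclusion_region)
        mappings[label] = relabel_origin(aggregate_snv_gene_map(anns, None, label), baseline_map)
        annotations[label] = anns
    for label, raw in config.ri_datasets.items():
        elems = process_ri_dataset(raw, genes)
        e_anns = annotate_features_with_snvs(elems, panel.variants, config.exclusion_region)
        mappings[label] = aggregate_snv_gene_map(base_anns, e_anns, label)
        annotations[label] = [*base_anns, *e_anns]

    gene_results: dict[str, pd.DataFrame] = {}
    contexts: dict[str, ScoringContext] = {}
    coverage: dict[str, int] = {}
    for label, m in mappings.items():
        logger.info("scoring mapping %s", label)
        res, ctx = score_genes(m, ss, panel, window_bp=config.window_bp)
        if res.empty:
            raise RuntimeError(f"stage gene-scoring failed for mapping {label}: no scored genes")
        gene_results[label] = res
        contexts[label] = ctx
        coverage[label] = compute_coverage(annotations[label], ss_ids, label).coverage_bp

    common_genes = set.intersection(*(set(df["gene_id"]) for df in gene_results.values()))
    sig_genes = {
        label: set(df.loc[(df["p_fdr"] < config.alpha) & df["gene_id"].isin(common_genes), "gene_id"])
        for label, df in gene_results.items()
    }

    set_results: dict[str, pd.DataFrame] = {}
    for label in mappings:
        set_results[label] = run_gsa(
            gene_results[label], gene_sets, contexts[label].correlations, config.set_size_range
        )
    tested = [set(df["set_id"]) for df in set_results.values() if len(df)]
    common_sets = set.intersection(*tested) if tested else set()
    sig_sets = {
        label: set(df.loc[(df["p_fdr"] < config.alpha) & df["set_id"].isin(common_sets), "set_id"])
        for label, df in set_results.items()
    }
    reduced_sig_sets = {
        label: reduce_redundant_sets(df[df["set_id"].isin(sig_sets[label])], gene_sets)
        for label, df in set_results.items()
    }

    report = ComparisonReport(
        baseline_label=baseline_label,
        per_mapping=pd.DataFrame(
            {
                "mapping": list(mappings),
                "coverage_bp": [coverage[m] for m in mappings],
                "n_scored_genes": [len(gene_results[m]) for m in mappings],
                "n_sig_genes": [len(sig_genes[m]) for m in mappings],
                "n_sig_sets_reduced": [len(reduced_sig_sets[m]) for m in mappings],
            }
        ),
        gene_results=gene_results,
        set_results=set_results,
        contexts=contexts,
        sig_genes=sig_genes,
        sig_sets=sig_sets,
        reduced_sig_sets=reduced_sig_sets,
        seeds={"master": config.seed},
    )

    for label in mappings:
        if label == baseline_label:
            continue
        novel_g, known_g, lost_g = classify_model_changes(sig_genes[baseline_label], sig_genes[label])
        # union-restore rule for sets: a set pruned as redundant in one mapping
        # but significant in both still counts as known
        union_reduced = set(reduced_sig_sets[baseline_label]) | set(reduced_sig_sets[label])
        in_base = union_reduced & sig_sets[baseline_label]
        in_aug = union_reduced & sig_sets[label]
        novel_s, known_s, lost_s = classify_model_changes(in_base, in_aug)
        report.changes[label] = {
            "genes": {"novel": novel_g, "known": known_g, "lost": lost_g},
            "sets": {"novel": novel_s, "known": known_s, "lost": lost_s},
        }
        report.gains[label] = {
            "genes": compute_gains(gene_results[baseline_label], gene_results[label], "gene"),
            "sets": compute_gains(set_results[baseline_label], set_results[label], "set")
            if len(set_results[baseline_label]) and len(set_results[label])
            else pd.DataFrame(),
        }

    epvp_labels = config.epvp_mappings if config.epvp_mappings is not None else list(config.ri_datasets)
    for label in epvp_labels:
        epvp_seed = int(child_rng(config.seed, f"epvp-seed:{label}").integers(2**31))
        report.seeds[f"epvp:{label}"] = epvp_seed
        runs = run_epvp(
            contexts[label], gene_sets, n_perm=config.n_perm, seed=epvp_seed,
            set_size_range=config.set_size_range,
        )
        perm_gene_counts = []
        for r in runs:
            df = r.gene_results
            perm_gene_counts.append(
                int(((df["p_fdr"] < config.alpha) & df["gene_id"].isin(common_genes)).sum())
            )
        genuine_count = len(sig_genes[label])
        validations: list[ValidationResult] = []
        set_gains = report.gains[label]["sets"]
        gaining_sig = [
            s for s in sorted(sig_sets[label])
            if s in set(set_gains.loc[set_gains["gaining"], "entity_id"])
        ]
        genuine_sets = set_results[label].set_index("set_id")
        for set_id in gaining_sig:
            perm_scores = [
                float(r.set_results.set_index("set_id").loc[set_id, "z_set"])
                for r in runs
                if set_id in set(r.set_results["set_id"])
            ]
            if len(perm_scores) >= 2:
                validations.append(
                    classify_validation(float(genuine_sets.loc[set_id, "z_set"]), perm_scores, set_id)
                )
        report.epvp[label] = {
            "genuine_sig_gene_count": genuine_count,
            "perm_sig_gene_counts": perm_gene_counts,
            "p_ttest": ttest_genuine_vs_permuted(genuine_count, perm_gene_counts),
            "validations": validations,
            "runs": runs,
        }

        if config.run_ired:
            traces: dict[str, IredTrace] = {}
            for v in report.epvp[label]["validations"]:
                if v.category == "invalidated":
                    continue
                traces[v.set_id] = ired_run(
                    v.set_id,
                    gene_results[baseline_label],
                    gene_results[label],
                    contexts[baseline_label].correlations,
                    contexts[label].correlations,
                    gene_sets,
                    set_size_range=config.set_size_range,
                )
            report.ired[label] = traces

    labels = list(mappings)
    cov = np.array([coverage[m] for m in labels], dtype=float)
    nsg = np.array([len(sig_genes[m]) for m in labels], dtype=float)
    nss = np.array([len(reduced_sig_sets[m]) for m in labels], dtype=float)
    try:
        rho, p_rho = trend_statistics(cov, nsg, alternative="greater")
        report.trends.update({"rho_coverage_genes": rho, "p_coverage_genes": p_rho})
    except ValueError as exc:
        logger.warning("coverage/genes trend skipped: %s", exc)
    try:
        rho2, p2 = trend_statistics(nsg, nss, alternative="less")
        report.trends.update({"rho_genes_sets": rho2, "p_genes_sets": p2})
    except ValueError as exc:
        logger.warning("genes/sets trend skipped: %s", exc)
    return report
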