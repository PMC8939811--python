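"""Synthetic reference panels, regulatory architectures and GWAS summary statistics.

The generator produces every input the analysis pipeline consumes: a block-LD
reference panel of genotype dosages, non-overlapping gene models with distal
regulatory elements, gene-set collections with a configurable number of
"enriched" sets, and marginal GWAS summary statistics with planted causal
signal inside distal regulatory elements (outside the proximity-based baseline
mapping, so that only regulatory augmentation can recover it).

Marginal association z-scores are simulated directly on the summary-statistics
scale: within each LD block, ``z ~ MVN(R @ lam, R)`` where ``R`` is the block's
(empirical, PSD-regularized) genotype correlation matrix and ``lam`` the vector
of planted per-SNV noncentralities. Two-sided p-values follow as
``2 * (1 - Phi(|z|))``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import child_rng
from .mapping import GeneModel, RegulatoryElement

__all__ = [
    "ReferencePanel",
    "VariantRecord",
    "GeneSetDef",
    "SyntheticArchitecture",
    "simulate_reference_panel",
    "simulate_architecture",
    "simulate_sumstats",
    "reassign_elements_randomly",
]

NUCLEOTIDES = np.array(list("ACGT"))


@dataclass(frozen=True)
class VariantRecord:
    """One reference-panel SNV (positions are 1-based, as in .bim files)."""

    rsid: str
    chromosome: int
    position: int
    allele_a1: str
    allele_a2: str
    maf: float


@dataclass(frozen=True)
class GeneSetDef:
    set_id: str
    gene_ids: tuple[str, ...]


@dataclass
class ReferencePanel:
    """Genotype dosages (samples x variants) plus an ordered variant table.

    ``variants`` columns: rsid, chrom, pos (1-based), a1, a2, maf (empirical),
    block.  Variants are strictly ordered by (chrom, pos).
    """

    sample_count: int
    variants: pd.DataFrame
    genotype_matrix: np.ndarray

    def __post_init__(self) -> None:
        v = self.variants
        order = np.lexsort((v["pos"].to_numpy(), v["chrom"].to_numpy()))
        if not np.array_equal(order, np.arange(len(v))):
            raise ValueError("variants must be ordered by (chromosome, position)")
        if v["rsid"].duplicated().any():
            raise ValueError("duplicated variant identifiers in panel")

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def block_slices(self) -> list[np.ndarray]:
        """Column indices of each LD block, in genomic order."""
        blocks = self.variants["block"].to_numpy()
        return [np.flatnonzero(blocks == b) for b in pd.unique(blocks)]

    def variant_records(self) -> list[VariantRecord]:
        return [
            VariantRecord(r.rsid, int(r.chrom), int(r.pos), r.a1, r.a2, float(r.maf))
            for r in self.variants.itertuples(index=False)
        ]


@dataclass
class SyntheticArchitecture:
    """Gene models, regulatory elements, gene sets and the planted causal plan."""

    genes: list[GeneModel]
    regulatory_interactions: list[RegulatoryElement]
    gene_sets: list[GeneSetDef]
    causal_plan: list[tuple[str, float]] = field(default_factory=list)
    enriched_set_ids: tuple[str, ...] = ()

    def lambda_vector(self, panel: ReferencePanel) -> np.ndarray:
        """Per-panel-SNV noncentrality vector (zero for non-causal SNVs)."""
        lam = np.zeros(panel.n_variants)
        if self.causal_plan:
            idx = pd.Index(panel.variants["rsid"])
            for rsid, value in self.causal_plan:
                pos = idx.get_indexer([rsid])[0]
                if pos < 0:
                    raise ValueError(f"causal SNV {rsid!r} not present in panel")
                lam[pos] = value
        return lam


def _draw_unique_positions(rng: np.random.Generator, n: int, length: int) -> np.ndarray:
    pos: np.ndarray = np.empty(0, dtype=np.int64)
    while len(pos) < n:
        extra = rng.integers(1, length + 1, size=2 * (n - len(pos)) + 8)
        pos = np.unique(np.concatenate([pos, extra]))
        if len(pos) > n:
            pos = np.sort(rng.choice(pos, size=n, replace=False))
    return np.sort(pos)


def simulate_reference_panel(
    n_samples: int,
    block_spec: list[tuple[int, float]],
    chrom_layout: list[int],
    maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int = 0,
    maf_floor: float = 0.01,
) -> ReferencePanel:
    """Simulate a block-LD reference panel of Hardy-Weinberg dosages.

    Each block draws two latent Gaussian haplotype vectors per sample with
    equicorrelation ``rho`` across its SNVs; thresholding each at the quantile
    of a per-SNV target allele frequency yields alleles, whose sum is the
    dosage in {0, 1, 2}.  SNVs in different blocks are independent.
    """
    if n_samples < 50:
        raise ValueError("n_samples must be >= 50")
    lo, hi = maf_range
    if not (0.01 < lo <= hi <= 0.5):
        raise ValueError("maf_range must lie within (0.01, 0.5]")
    for size, rho in block_spec:
        if size <= 0:
            raise ValueError(f"block_spec: non-positive block size {size}")
        if not (0.0 <= rho < 1.0):
            raise ValueError(f"block_spec: within-block correlation {rho} outside [0, 1)")
    rng = child_rng(seed, "panel")

    n_blocks = len(block_spec)
    n_chroms = len(chrom_layout)
    # blocks assigned to chromosomes in contiguous runs, proportional to count
    chrom_of_block = [i * n_chroms // n_blocks for i in range(n_blocks)]

    geno_cols: list[np.ndarray] = []
    rows: list[dict] = []
    block_id = 0
    for chrom0 in range(n_chroms):
        sizes = [block_spec[b][0] for b in range(n_blocks) if chrom_of_block[b] == chrom0]
        if not sizes:
            continue
        positions = _draw_unique_positions(rng, sum(sizes), chrom_layout[chrom0])
        offset = 0
        for b in range(n_blocks):
            if chrom_of_block[b] != chrom0:
                continue
            size, rho = block_spec[b]
            block_pos = positions[offset : offset + size]
            offset += size
            for _attempt in range(200):
                target_maf = rng.uniform(lo, hi, size=size)
                thresh = stats.norm.ppf(target_maf)
                dosage = np.zeros((n_samples, size), dtype=np.int8)
                for _hap in range(2):
                    shared = rng.standard_normal((n_samples, 1))
                    noise = rng.standard_normal((n_samples, size))
                    latent = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * noise
                    dosage += (latent < thresh).astype(np.int8)
                freq = dosage.mean(axis=0) / 2.0
                emp_maf = np.minimum(freq, 1.0 - freq)
                if np.all(emp_maf >= maf_floor):
                    break
            else:  # pragma: no cover - vanishing probability at n >= 50
                raise RuntimeError("could not satisfy the MAF floor; widen maf_range")
            geno_cols.append(dosage)
            for j in range(size):
                a1, a2 = rng.choice(NUCLEOTIDES, size=2, replace=False)
                rows.append(
                    {
                        "rsid": "",
                        "chrom": chrom0 + 1,
                        "pos": int(block_pos[j]),
                        "a1": a1,
                        "a2": a2,
                        "maf": float(emp_maf[j]),
                        "block": block_id,
                    }
                )
            block_id += 1

    variants = pd.DataFrame(rows)
    variants["rsid"] = [f"rs{i + 1}" for i in range(len(variants))]
    genotypes = np.concatenate(geno_cols, axis=1)
    return ReferencePanel(n_samples, variants, genotypes)


def _place_genes(
    rng: np.random.Generator,
    n_genes: int,
    chrom_layout: list[int],
    gene_length_range: tuple[int, int],
    min_gap: int,
) -> list[GeneModel]:
    total_len = sum(chrom_layout)
    genes: list[GeneModel] = []
    gid = 0
    for chrom0, length in enumerate(chrom_layout):
        n_here = round(n_genes * length / total_len)
        if chrom0 == len(chrom_layout) - 1:
            n_here = n_genes - gid
        if n_here == 0:
            continue
        bodies = rng.integers(gene_length_range[0], gene_length_range[1] + 1, size=n_here)
        needed = int(bodies.sum() + (n_here + 1) * min_gap)
        if needed > length:
            raise ValueError(
                f"genome too small to place {n_here} genes on chromosome {chrom0 + 1}; "
                "use a larger chrom_layout"
            )
        slack = length - needed
        gaps = rng.multinomial(slack, np.full(n_here + 1, 1.0 / (n_here + 1)))
        cursor = 0
        for i in range(n_here):
            cursor += min_gap + int(gaps[i])
            start = cursor
            end = start + int(bodies[i])
            cursor = end
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(GeneModel(f"G{gid + 1:04d}", chrom0 + 1, start, end, strand))
            gid += 1
    return genes


def _baseline_footprints(genes: list[GeneModel], flank_bp: int) -> dict[int, np.ndarray]:
    """Per chromosome, (n, 2) array of body +/- flank intervals (half-open)."""
    out: dict[int, list[tuple[int, int]]] = {}
    for g in genes:
        out.setdefault(g.chromosome, []).append((max(0, g.body_start - flank_bp), g.body_end + flank_bp))
    return {c: np.array(sorted(iv)) for c, iv in out.items()}


def _outside_footprints(pos0: np.ndarray, intervals: np.ndarray) -> np.ndarray:
    """Boolean mask of 0-based positions falling outside every interval."""
    if len(intervals) == 0:
        return np.ones(len(pos0), dtype=bool)
    inside = np.zeros(len(pos0), dtype=bool)
    for s, e in intervals:
        inside |= (pos0 >= s) & (pos0 < e)
    return ~inside


def simulate_architecture(
    panel: ReferencePanel,
    n_genes: int = 300,
    n_sets: int = 20,
    set_size_range: tuple[int, int] = (25, 40),
    n_enriched_sets: int = 1,
    ri_distance_range: tuple[int, int] = (50_000, 1_000_000),
    seed: int = 0,
    chrom_layout: list[int] | None = None,
    gene_length_range: tuple[int, int] = (20_000, 60_000),
    baseline_flank_bp: int = 10_000,
    max_elements_per_gene: int = 2,
    element_halfwidth: int = 1_500,
    n_causal_genes_per_set: int = 10,
    n_causal_snvs_per_element: int = 3,
    causal_lambda: float = 5.5,
    signal_placement: str = "distal_elements",
) -> SyntheticArchitecture:
    """Lay out genes, distal regulatory elements, gene sets, and a causal plan.

    Enriched sets receive causal SNVs placed strictly outside every gene's
    baseline footprint (body +/- ``baseline_flank_bp``): inside distal
    regulatory elements by default, or — with
    ``signal_placement="dispersed_flanks"`` — at assorted distances up to
    100 kb from the TSS of member genes, so that progressively larger flank
    mappings capture progressively more of the signal.
    """
    if signal_placement not in ("distal_elements", "dispersed_flanks"):
        raise ValueError(f"unknown signal_placement {signal_placement!r}")
    rng = child_rng(seed, "architecture")
    if chrom_layout is None:
        n_chroms = int(panel.variants["chrom"].max())
        chrom_layout = [int(panel.variants.loc[panel.variants["chrom"] == c + 1, "pos"].max()) + 50_000
                        for c in range(n_chroms)]
    genes = _place_genes(rng, n_genes, chrom_layout, gene_length_range, min_gap=2 * baseline_flank_bp + 5_000)
    footprints = _baseline_footprints(genes, baseline_flank_bp)

    variants = panel.variants
    pos0_by_chrom = {c: variants.loc[variants["chrom"] == c, "pos"].to_numpy() - 1 for c in variants["chrom"].unique()}
    rsid_by_chrom = {c: variants.loc[variants["chrom"] == c, "rsid"].to_numpy() for c in variants["chrom"].unique()}
    block_by_chrom = {c: variants.loc[variants["chrom"] == c, "block"].to_numpy() for c in variants["chrom"].unique()}
    eligible = {c: _outside_footprints(pos0_by_chrom[c], footprints.get(c, np.empty((0, 2)))) for c in pos0_by_chrom}
    # causal anchors are restricted to LD blocks wholly outside every baseline
    # footprint, so the baseline mapping misses the planted signal both
    # directly and through LD with intragenic SNVs
    clean: dict[int, np.ndarray] = {}
    for c in pos0_by_chrom:
        blocks = block_by_chrom[c]
        dirty_blocks = set(blocks[~eligible[c]].tolist())
        clean[c] = eligible[c] & ~np.isin(blocks, list(dirty_blocks))

    gene_ids = [g.gene_id for g in genes]
    sets: list[GeneSetDef] = []
    for s in range(n_sets):
        size = int(rng.integers(set_size_range[0], set_size_range[1] + 1))
        members = rng.choice(gene_ids, size=min(size, len(gene_ids)), replace=False)
        sets.append(GeneSetDef(f"SET{s + 1:03d}", tuple(sorted(members))))
    enriched = sets[:n_enriched_sets]

    gene_by_id = {g.gene_id: g for g in genes}
    elements: list[RegulatoryElement] = []
    causal_plan: list[tuple[str, float]] = []
    uid_counter: dict[str, int] = {}

    def _new_element(gene: GeneModel, center_pos0: int) -> RegulatoryElement:
        k = uid_counter.get(gene.gene_id, 0) + 1
        uid_counter[gene.gene_id] = k
        start = max(0, center_pos0 - element_halfwidth)
        return RegulatoryElement(
            gene_id=gene.gene_id,
            chromosome=gene.chromosome,
            start=start,
            end=center_pos0 + element_halfwidth + 1,
            element_uid=f"{gene.gene_id}_RE{k}",
            source="synthetic",
        )

    def _pick_distal_snv(gene: GeneModel, max_dist: int | None = None, clean_block: bool = False) -> int | None:
        """Index (within chromosome) of an eligible SNV at an RI-like distance."""
        pos0 = pos0_by_chrom[gene.chromosome]
        ok = clean[gene.chromosome] if clean_block else eligible[gene.chromosome]
        anchor = gene.tss
        lo_d, hi_d = ri_distance_range
        if max_dist is not None:
            hi_d = min(hi_d, max_dist)
        dist = np.abs(pos0 - anchor)
        cand = np.flatnonzero(ok & (dist >= lo_d) & (dist <= hi_d))
        if len(cand) == 0:
            cand = np.flatnonzero(ok)
            if len(cand) == 0:
                return None
        return int(rng.choice(cand))

    causal_gene_ids: set[str] = set()
    for gs in enriched:
        n_causal = min(n_causal_genes_per_set, len(gs.gene_ids))
        if n_causal < 5:
            raise ValueError("enriched sets need >= 5 causal genes; enlarge set_size_range")
        chosen = rng.choice(np.array(gs.gene_ids), size=n_causal, replace=False)
        for gid in chosen:
            gene = gene_by_id[gid]
            idx = _pick_distal_snv(gene, clean_block=(signal_placement == "distal_elements"))
            if idx is None:
                continue
            causal_gene_ids.add(gid)
            chrom = gene.chromosome
            if signal_placement == "distal_elements":
                # the element spans the nearest eligible SNVs around the anchor,
                # so it genuinely carries the intended number of causal SNVs
                pos0 = pos0_by_chrom[chrom]
                anchor_pos = int(pos0[idx])
                # HiC-scale element: spans the nearest clean SNVs within 15 kb
                near = np.flatnonzero(clean[chrom] & (np.abs(pos0 - anchor_pos) <= 15_000))
                near = near[np.argsort(np.abs(pos0[near] - anchor_pos), kind="stable")]
                picked = np.sort(near[:n_causal_snvs_per_element])
                lo = int(pos0[picked].min()) - element_halfwidth
                hi = int(pos0[picked].max()) + element_halfwidth + 1
                k = uid_counter.get(gene.gene_id, 0) + 1
                uid_counter[gene.gene_id] = k
                elements.append(
                    RegulatoryElement(gene.gene_id, chrom, max(0, lo), hi,
                                      f"{gene.gene_id}_RE{k}", "synthetic")
                )
            else:  # dispersed_flanks: signal at distances the flank ladder sweeps
                pos0 = pos0_by_chrom[chrom]
                dist = np.abs(pos0 - gene.tss)
                target = rng.uniform(baseline_flank_bp + 2_000, 100_000)
                cand = np.flatnonzero(eligible[chrom] & (dist <= target + 20_000) & (dist > baseline_flank_bp))
                picked = rng.choice(cand, size=min(n_causal_snvs_per_element, len(cand)), replace=False) if len(cand) else np.empty(0, dtype=int)
            for j in picked:
                causal_plan.append((rsid_by_chrom[chrom][j], float(causal_lambda)))

    # background regulatory elements for every gene (no causal content)
    for gene in genes:
        n_elem = int(rng.integers(0, max_elements_per_gene + 1))
        for _ in range(n_elem):
            idx = _pick_distal_snv(gene)
            if idx is not None:
                elements.append(_new_element(gene, int(pos0_by_chrom[gene.chromosome][idx])))

    # dedupe causal plan (an element may be picked twice)
    seen: dict[str, float] = {}
    for rsid, lam in causal_plan:
        seen[rsid] = max(lam, seen.get(rsid, 0.0))
    causal_plan = sorted(seen.items())

    return SyntheticArchitecture(
        genes=genes,
        regulatory_interactions=elements,
        gene_sets=sets,
        causal_plan=causal_plan,
        enriched_set_ids=tuple(gs.set_id for gs in enriched),
    )


def _block_correlation(genotypes: np.ndarray) -> np.ndarray:
    """Empirical dosage correlation, eigenvalue-clipped to PSD with unit diagonal."""
    if genotypes.shape[1] == 1:
        return np.array([[1.0]])
    r = np.corrcoef(genotypes, rowvar=False)
    w, v = np.linalg.eigh(r)
    if w.min() < 1e-8:
        r = (v * np.clip(w, 1e-8, None)) @ v.T
        d = np.sqrt(np.diag(r))
        r = r / np.outer(d, d)
    return r


def simulate_sumstats(
    panel: ReferencePanel,
    causal_plan: list[tuple[str, float]] | np.ndarray,
    n_gwas: int = 50_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate marginal GWAS summary statistics over the panel's SNVs.

    ``causal_plan`` is either a list of (rsid, lambda) pairs or a dense
    per-SNV lambda vector.  Returns one row per panel SNV with columns
    rsid, chrom, pos, a1, a2, beta, se, pval, n.
    """
    if n_gwas <= 0:
        raise ValueError("n_gwas must be positive")
    rng = child_rng(seed, "sumstats")
    if isinstance(causal_plan, np.ndarray):
        lam = np.asarray(causal_plan, dtype=float)
        if lam.shape != (panel.n_variants,):
            raise ValueError("lambda vector length does not match panel")
    else:
        lam = np.zeros(panel.n_variants)
        idx = pd.Index(panel.variants["rsid"])
        missing = [rsid for rsid, _ in causal_plan if idx.get_indexer([rsid])[0] < 0]
        if missing:
            raise ValueError(f"causal SNVs not present in panel: {missing}")
        for rsid, value in causal_plan:
            lam[idx.get_indexer([rsid])[0]] = value

    z = np.empty(panel.n_variants)
    for cols in panel.block_slices():
        r = _block_correlation(panel.genotype_matrix[:, cols])
        mean = r @ lam[cols]
        chol = np.linalg.cholesky(r + 1e-10 * np.eye(len(cols)))
        z[cols] = mean + chol @ rng.standard_normal(len(cols))

    pval = np.clip(2.0 * stats.norm.sf(np.abs(z)), 1e-300, 1.0)
    maf = panel.variants["maf"].to_numpy()
    se = 1.0 / np.sqrt(2.0 * n_gwas * maf * (1.0 - maf))
    out = panel.variants[["rsid", "chrom", "pos", "a1", "a2"]].copy()
    out["beta"] = z * se
    out["se"] = se
    out["pval"] = pval
    out["n"] = n_gwas
    return out


def default_fixture(
    seed: int = 0,
    n_enriched_sets: int = 1,
    n_gwas: int = 50_000,
    signal_placement: str = "distal_elements",
    **architecture_overrides,
) -> tuple[ReferencePanel, SyntheticArchitecture, pd.DataFrame]:
    """The standard study conditions for desk-scale runs of the pipeline.

    One chromosome of 60 Mb carrying ~5,000 SNVs in 500 equicorrelated LD
    blocks of 10 SNVs (within-block r = 0.45; at this SNV density a block
    spans roughly 100 kb, a realistic LD-block scale), a 400-sample
    reference panel, 300 non-overlapping genes, 20 gene sets of 25-40 genes
    of which ``n_enriched_sets`` carry planted causal regulatory signal
    (10 causal genes per enriched set, 3 causal SNVs per distal element,
    per-SNV noncentrality 5.5 — i.e. genome-wide-significant-scale loci),
    and marginal summary statistics for a 50,000-sample GWAS.
    """
    panel = simulate_reference_panel(400, [(10, 0.45)] * 500, [60_000_000], seed=seed)
    arch = simulate_architecture(
        panel,
        n_genes=300,
        n_sets=20,
        set_size_range=(25, 40),
        n_enriched_sets=n_enriched_sets,
        seed=seed,
        chrom_layout=[60_000_000],
        signal_placement=signal_placement,
        **architecture_overrides,
    )
    sumstats = simulate_sumstats(panel, arch.causal_plan, n_gwas=n_gwas, seed=seed)
    return panel, arch, sumstats


def reassign_elements_randomly(
    elements: list[RegulatoryElement],
    genes: list[GeneModel],
    seed: int = 0,
) -> list[RegulatoryElement]:
    """Reassign each regulatory element to a random gene on its chromosome.

    Element intervals are untouched; only the target gene changes.  This breaks
    any genuine element-to-gene signal placement while preserving the marginal
    amount of augmentation, providing a negative control for the pipeline.
    """
    rng = child_rng(seed, "scramble")
    by_chrom: dict[int, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chromosome, []).append(g)
    out: list[RegulatoryElement] = []
    counter: dict[str, int] = {}
    for elem in elements:
        pool = by_chrom.get(elem.chromosome)
        if not pool:
            continue
        gene = pool[int(rng.integers(len(pool)))]
        k = counter.get(gene.gene_id, 0) + 1
        counter[gene.gene_id] = k
        out.append(
            RegulatoryElement(
                gene_id=gene.gene_id,
                chromosome=elem.chromosome,
                start=elem.start,
                end=elem.end,
                element_uid=f"{gene.gene_id}_RND{k}",
                source=elem.source,
            )
        )
    return out
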