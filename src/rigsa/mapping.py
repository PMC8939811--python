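"""SNV-to-gene mappings from gene bodies, flanks and regulatory interactions.

All interval arithmetic is 0-based half-open internally; file readers convert
1-based inclusive coordinates (gene.loc, .bim) on ingestion.  A SNV at 1-based
position ``p`` lies inside the half-open interval ``[s, e)`` iff ``s <= p-1 < e``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GeneModel",
    "RegulatoryElement",
    "Feature",
    "FeatureAnnotation",
    "SnvGeneMap",
    "GeneSnvs",
    "CoverageReport",
    "build_flanked_features",
    "derive_ri_from_contacts",
    "process_ri_dataset",
    "annotate_features_with_snvs",
    "aggregate_snv_gene_map",
    "compute_coverage",
    "merge_intervals",
    "MHC_REGION",
]

logger = logging.getLogger(__name__)

#: Human MHC exclusion region, 1-based inclusive (chrom, start, end).  Synthetic
#: genomes pass ``exclusion_region=None`` instead.
MHC_REGION = (6, 28_477_797, 33_448_354)


@dataclass(frozen=True)
class GeneModel:
    """A gene body with strand-aware transcription start/end sites.

    ``body_start``/``body_end`` are 0-based half-open.  The TSS is the first
    transcribed base: ``body_start`` on the + strand, ``body_end - 1`` on the
    - strand; the TES is the opposite end.
    """

    gene_id: str
    chromosome: int
    body_start: int
    body_end: int
    strand: str = "+"
    symbol: str | None = None

    def __post_init__(self) -> None:
        if self.body_start >= self.body_end:
            raise ValueError(f"{self.gene_id}: body_start must be < body_end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")

    @property
    def tss(self) -> int:
        return self.body_start if self.strand == "+" else self.body_end - 1

    @property
    def tes(self) -> int:
        return self.body_end - 1 if self.strand == "+" else self.body_start


@dataclass(frozen=True)
class RegulatoryElement:
    """A distal element linked to a target gene on the same chromosome."""

    gene_id: str
    chromosome: int
    start: int
    end: int
    element_uid: str
    source: str = "ri"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.element_uid}: start must be < end")


@dataclass(frozen=True)
class Feature:
    """One mapped interval of a gene: body, flank, or regulatory element."""

    name: str
    gene_id: str
    chromosome: int
    start: int
    end: int
    kind: str  # body | flank_up | flank_down | element


@dataclass
class FeatureAnnotation:
    feature: Feature
    snv_ids: np.ndarray  # ordered by position
    snv_idx: np.ndarray  # row indices into the variant table


@dataclass
class GeneSnvs:
    snv_ids: np.ndarray
    snv_idx: np.ndarray
    intragenic: np.ndarray  # bool, aligned with snv_ids


@dataclass
class SnvGeneMap:
    """Per-gene ordered SNV lists with intragenic/extragenic origin labels."""

    mapping_label: str
    genes: dict[str, GeneSnvs] = field(default_factory=dict)

    def n_snvs(self, gene_id: str) -> int:
        return len(self.genes[gene_id].snv_ids)


@dataclass
class CoverageReport:
    mapping_label: str
    coverage_bp: int
    per_gene: dict[str, int]


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals as a sorted list of maximal intervals."""
    merged: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def build_flanked_features(
    genes: list[GeneModel],
    up_kb: float,
    down_kb: float,
) -> list[Feature]:
    """Per gene: a body feature plus strand-aware upstream/downstream flanks.

    The upstream flank covers ``up_kb`` kilobases immediately 5' of the TSS,
    the downstream flank ``down_kb`` kilobases immediately 3' of the TES;
    neither overlaps the body, and flanks are clipped at position 0.
    """
    if up_kb < 0 or down_kb < 0:
        raise ValueError("flank sizes must be >= 0")
    up = int(round(up_kb * 1_000))
    down = int(round(down_kb * 1_000))
    features: list[Feature] = []
    for g in genes:
        features.append(Feature(g.gene_id, g.gene_id, g.chromosome, g.body_start, g.body_end, "body"))
        if g.strand == "+":
            up_iv = (max(0, g.body_start - up), g.body_start)
            down_iv = (g.body_end, g.body_end + down)
        else:
            up_iv = (g.body_end, g.body_end + up)
            down_iv = (max(0, g.body_start - down), g.body_start)
        if up > 0 and up_iv[0] < up_iv[1]:
            features.append(Feature(f"{g.gene_id}_U", g.gene_id, g.chromosome, up_iv[0], up_iv[1], "flank_up"))
        if down > 0 and down_iv[0] < down_iv[1]:
            features.append(Feature(f"{g.gene_id}_D", g.gene_id, g.chromosome, down_iv[0], down_iv[1], "flank_down"))
    return features


def _promoter_interval(gene: GeneModel, promoter_bp: int) -> tuple[int, int]:
    """The promoter window: ``promoter_bp`` immediately upstream of the TSS."""
    if gene.strand == "+":
        return (max(0, gene.body_start - promoter_bp), gene.body_start)
    return (gene.body_end, gene.body_end + promoter_bp)


def _overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def derive_ri_from_contacts(
    locus_pairs: list[tuple[tuple[int, int, int], tuple[int, int, int]]],
    genes: list[GeneModel],
    promoter_kb: float = 2.0,
) -> list[RegulatoryElement]:
    """Turn locus-pair contacts (e.g. HiC) into element-to-gene records.

    Each pair is ((chrom, start, end), (chrom, start, end)) in half-open
    coordinates.  If one locus overlaps the promoter window of a gene (the
    region ``promoter_kb`` upstream of its TSS), the *other* locus becomes a
    regulatory element of that gene; the rule is applied symmetrically.
    Inter-chromosomal pairs are dropped (counted, not an error).
    """
    promoter_bp = int(round(promoter_kb * 1_000))
    by_chrom: dict[int, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chromosome, []).append(g)
    n_inter = 0
    seen: set[tuple[str, int, int, int]] = set()
    elements: list[RegulatoryElement] = []
    counter: dict[str, int] = {}

    def _emit(gene: GeneModel, locus: tuple[int, int, int]) -> None:
        key = (gene.gene_id, *locus)
        if key in seen:
            return
        seen.add(key)
        k = counter.get(gene.gene_id, 0) + 1
        counter[gene.gene_id] = k
        elements.append(
            RegulatoryElement(gene.gene_id, locus[0], locus[1], locus[2], f"{gene.gene_id}_{k}", "contacts")
        )

    for locus_a, locus_b in locus_pairs:
        if locus_a[0] != locus_b[0]:
            n_inter += 1
            continue
        for anchor, other in ((locus_a, locus_b), (locus_b, locus_a)):
            for gene in by_chrom.get(anchor[0], []):
                if _overlaps((anchor[1], anchor[2]), _promoter_interval(gene, promoter_bp)):
                    _emit(gene, other)
    if n_inter:
        logger.warning("derive_ri_from_contacts: dropped %d inter-chromosomal pairs", n_inter)
    return elements


def process_ri_dataset(
    raw_ris: list[RegulatoryElement],
    genes: list[GeneModel],
) -> list[RegulatoryElement]:
    """Restrict, clean and merge a raw regulatory-interaction dataset.

    Records targeting genes outside the background list or on a different
    chromosome than their target gene are removed; per (gene, source),
    overlapping elements are merged into maximal intervals and element
    identifiers reassigned sequentially.
    """
    gene_by_id = {g.gene_id: g for g in genes}
    kept: dict[tuple[str, str], list[tuple[int, int]]] = {}
    n_bad = 0
    for r in raw_ris:
        gene = gene_by_id.get(r.gene_id)
        if gene is None or gene.chromosome != r.chromosome:
            continue
        if r.start >= r.end:  # defensive; the dataclass rejects these at build
            n_bad += 1
            continue
        kept.setdefault((r.gene_id, r.source), []).append((r.start, r.end))
    if n_bad:
        logger.warning("process_ri_dataset: rejected %d malformed intervals", n_bad)
    out: list[RegulatoryElement] = []
    for (gene_id, source), intervals in sorted(kept.items()):
        for k, (s, e) in enumerate(merge_intervals(intervals), start=1):
            out.append(
                RegulatoryElement(gene_id, gene_by_id[gene_id].chromosome, s, e, f"{gene_id}_{source}_{k}", source)
            )
    return out


def _region_to_halfopen(region: tuple[int, int, int]) -> tuple[int, int, int]:
    chrom, start1, end1 = region
    return chrom, start1 - 1, end1


def annotate_features_with_snvs(
    features: list[Feature | RegulatoryElement],
    variants: pd.DataFrame,
    exclusion_region: tuple[int, int, int] | None = None,
    excluded_gene_ids: set[str] | None = None,
) -> list[FeatureAnnotation]:
    """List, per feature, the SNVs whose position falls inside it.

    ``variants`` must be sorted by (chrom, pos) with 1-based positions.
    ``exclusion_region`` is (chrom, start, end), 1-based inclusive (e.g. the
    MHC region): SNVs inside it are annotated to no feature, and genes whose
    body overlaps it are excluded entirely.  Features with no overlapping SNV
    are retained with an empty annotation.
    """
    chroms = variants["chrom"].to_numpy()
    pos0 = variants["pos"].to_numpy() - 1
    rsids = variants["rsid"].to_numpy()
    allowed = np.ones(len(variants), dtype=bool)
    excl = None
    if exclusion_region is not None:
        excl = _region_to_halfopen(exclusion_region)
        allowed &= ~((chroms == excl[0]) & (pos0 >= excl[1]) & (pos0 < excl[2]))
    excluded_genes = set(excluded_gene_ids or ())
    if excl is not None:
        for f in features:
            kind = getattr(f, "kind", "element")
            if kind == "body" and f.chromosome == excl[0] and _overlaps((f.start, f.end), excl[1:]):
                excluded_genes.add(f.gene_id)

    # per-chromosome sorted position arrays for binary search
    starts: dict[int, int] = {}
    for c in pd.unique(chroms):
        starts[int(c)] = int(np.searchsorted(chroms, c, side="left"))

    annotations: list[FeatureAnnotation] = []
    for f in features:
        if f.gene_id in excluded_genes:
            continue
        c = f.chromosome
        if c not in starts:
            annotations.append(FeatureAnnotation(_as_feature(f), rsids[:0], np.empty(0, dtype=int)))
            continue
        lo = starts[c]
        hi = int(np.searchsorted(chroms, c, side="right"))
        i = lo + int(np.searchsorted(pos0[lo:hi], f.start, side="left"))
        j = lo + int(np.searchsorted(pos0[lo:hi], f.end, side="left"))
        idx = np.arange(i, j)
        idx = idx[allowed[idx]]
        annotations.append(FeatureAnnotation(_as_feature(f), rsids[idx], idx))
    return annotations


def _as_feature(f: Feature | RegulatoryElement) -> Feature:
    if isinstance(f, Feature):
        return f
    return Feature(f.element_uid, f.gene_id, f.chromosome, f.start, f.end, "element")


def aggregate_snv_gene_map(
    baseline_annotations: list[FeatureAnnotation],
    augmentation_annotations: list[FeatureAnnotation] | None = None,
    mapping_label: str = "mapping",
) -> SnvGeneMap:
    """Aggregate SNV-to-feature annotations into per-gene SNV lists.

    Per gene, the union of SNVs over all its features, in genomic order, with
    no SNV mapped twice to the same gene.  A SNV's origin is intragenic iff it
    occurs in any *baseline* feature of that gene, extragenic otherwise; a SNV
    may map to several genes with a different origin in each.
    """
    base_idx: dict[str, set[int]] = {}
    all_idx: dict[str, set[int]] = {}
    for ann in baseline_annotations:
        g = ann.feature.gene_id
        base_idx.setdefault(g, set()).update(ann.snv_idx.tolist())
        all_idx.setdefault(g, set()).update(ann.snv_idx.tolist())
    id_of: dict[int, str] = {}
    for ann in baseline_annotations:
        id_of.update(zip(ann.snv_idx.tolist(), ann.snv_ids.tolist()))
    for ann in augmentation_annotations or []:
        g = ann.feature.gene_id
        all_idx.setdefault(g, set()).update(ann.snv_idx.tolist())
        id_of.update(zip(ann.snv_idx.tolist(), ann.snv_ids.tolist()))

    out = SnvGeneMap(mapping_label)
    for gene_id in sorted(all_idx):
        idx = np.array(sorted(all_idx[gene_id]), dtype=int)
        base = base_idx.get(gene_id, set())
        out.genes[gene_id] = GeneSnvs(
            snv_ids=np.array([id_of[i] for i in idx]),
            snv_idx=idx,
            intragenic=np.array([i in base for i in idx], dtype=bool),
        )
    return out


def compute_coverage(
    annotations: list[FeatureAnnotation],
    sumstat_snv_ids: set[str] | pd.Index,
    mapping_label: str = "mapping",
) -> CoverageReport:
    """Coverage of a mapping: per-gene union length of qualifying features.

    A feature qualifies (defines its gene) iff it contains at least one SNV
    that is also present in the summary statistics; ``coverage_bp`` sums the
    per-gene union lengths, so base pairs shared between two genes count once
    per gene.
    """
    ids = set(sumstat_snv_ids)
    per_gene_iv: dict[str, list[tuple[int, int]]] = {}
    for ann in annotations:
        if any(s in ids for s in ann.snv_ids):
            f = ann.feature
            per_gene_iv.setdefault(f.gene_id, []).append((f.start, f.end))
    per_gene = {
        g: sum(e - s for s, e in merge_intervals(ivs)) for g, ivs in per_gene_iv.items()
    }
    return CoverageReport(mapping_label, sum(per_gene.values()), per_gene)
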