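"""Readers and writers for the plain-text formats the pipeline exchanges.

Conventions: .bim-like variant tables and gene.loc-style gene models are
1-based inclusive on disk and converted to the internal 0-based half-open
convention on ingestion; BED-like regulatory-interaction tables are already
0-based half-open; GMT is the usual tab-separated set format.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .mapping import FeatureAnnotation, GeneModel, RegulatoryElement
from .sumstats import SUMSTAT_COLUMNS

__all__ = [
    "write_bim",
    "read_bim",
    "write_sumstats",
    "read_sumstats",
    "write_gene_loc",
    "read_gene_loc",
    "write_ri_bed",
    "read_ri_bed",
    "write_gmt",
    "read_gmt",
    "write_annot",
]


def write_bim(variants: pd.DataFrame, path: str | Path) -> None:
    out = pd.DataFrame(
        {
            "chrom": variants["chrom"],
            "rsid": variants["rsid"],
            "cm": 0,
            "pos": variants["pos"],
            "a1": variants["a1"],
            "a2": variants["a2"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def read_bim(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "rsid", "cm", "pos", "a1", "a2"])
    return df.drop(columns="cm")


def write_sumstats(sumstats: pd.DataFrame, path: str | Path) -> None:
    sumstats[SUMSTAT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_sumstats(path: str | Path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a summary-statistics TSV; ``column_map`` maps internal names
    (rsid, chrom, pos, a1, a2, beta, se, pval, n) to the file's column names."""
    df = pd.read_csv(path, sep="\t")
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    missing = [c for c in SUMSTAT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"summary statistics missing columns: {missing}")
    return df[SUMSTAT_COLUMNS]


def write_gene_loc(genes: list[GeneModel], path: str | Path) -> None:
    rows = [
        {
            "gene_id": g.gene_id,
            "chrom": g.chromosome,
            "start": g.body_start + 1,
            "stop": g.body_end,
            "strand": g.strand,
            "symbol": g.symbol or g.gene_id,
        }
        for g in genes
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def read_gene_loc(path: str | Path) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "chrom", "start", "stop", "strand", "symbol"])
    return [
        GeneModel(str(r.gene_id), int(r.chrom), int(r.start) - 1, int(r.stop), str(r.strand), str(r.symbol))
        for r in df.itertuples(index=False)
    ]


def write_ri_bed(elements: list[RegulatoryElement], path: str | Path) -> None:
    rows = [
        {
            "chrom": e.chromosome,
            "start": e.start,
            "end": e.end,
            "gene_id": e.gene_id,
            "element_uid": e.element_uid,
            "source": e.source,
        }
        for e in elements
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def read_ri_bed(path: str | Path) -> list[RegulatoryElement]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end", "gene_id", "element_uid", "source"])
    return [
        RegulatoryElement(str(r.gene_id), int(r.chrom), int(r.start), int(r.end), str(r.element_uid), str(r.source))
        for r in df.itertuples(index=False)
    ]


def write_gmt(gene_sets, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in gene_sets:
            fh.write("\t".join([gs.set_id, "na", *gs.gene_ids]) + "\n")


def read_gmt(path: str | Path) -> dict[str, tuple[str, ...]]:
    out: dict[str, tuple[str, ...]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                out[parts[0]] = tuple(parts[2:])
    return out


def write_annot(annotations: list[FeatureAnnotation], path: str | Path) -> None:
    """One row per feature: name, chrom:start:end (1-based inclusive), SNV ids."""
    with open(path, "w") as fh:
        for ann in annotations:
            f = ann.feature
            loc = f"{f.chromosome}:{f.start + 1}:{f.end}"
            fh.write("\t".join([f.name, loc, *ann.snv_ids.tolist()]) + "\n")
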