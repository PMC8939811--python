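"""Harmonization and QC of GWAS summary statistics.

Raw per-SNV association records are filtered to biallelic, strand-unambiguous
SNVs with valid statistics, matched against a reference variant dictionary
(primary key: chromosome, position, unordered allele pair; fallback: the
original rs-identifier with matching alleles), and then passed through a fixed
sequence of final filters: duplicate removal, MAF floor, exclusion region, and
a sample-size outlier cut.  The filter order (QC -> harmonize -> duplicates ->
MAF -> exclusion -> n-outlier) is part of the contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SumstatRecord",
    "VariantDictionary",
    "qc_filter_records",
    "harmonize_variants",
    "apply_final_filters",
    "process_sumstats",
]

AMBIGUOUS_PAIRS = {frozenset(("A", "T")), frozenset(("C", "G"))}
SUMSTAT_COLUMNS = ["rsid", "chrom", "pos", "a1", "a2", "beta", "se", "pval", "n"]


@dataclass(frozen=True)
class SumstatRecord:
    rsid: str
    chromosome: int
    position: int
    allele_a1: str
    allele_a2: str
    beta: float
    se: float
    pval: float
    n: int


@dataclass
class VariantDictionary:
    """One-to-one lookup between rs-identifiers and variant meta-information."""

    table: pd.DataFrame  # columns: rsid, chrom, pos, a1, a2, maf
    _by_meta: dict[tuple[int, int, frozenset], str] = field(init=False, repr=False)
    _by_rsid: dict[str, tuple[int, int, frozenset]] = field(init=False, repr=False)
    _maf: dict[str, float] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        t = self.table
        if t["rsid"].duplicated().any():
            raise ValueError("dictionary rsids are not unique")
        self._by_meta = {}
        self._by_rsid = {}
        self._maf = {}
        for r in t.itertuples(index=False):
            key = (int(r.chrom), int(r.pos), frozenset((r.a1, r.a2)))
            if key in self._by_meta:
                raise ValueError(f"dictionary meta-information is not unique: {key}")
            self._by_meta[key] = r.rsid
            self._by_rsid[r.rsid] = key
            self._maf[r.rsid] = float(r.maf)

    @classmethod
    def from_panel(cls, panel) -> "VariantDictionary":
        return cls(panel.variants[["rsid", "chrom", "pos", "a1", "a2", "maf"]].copy())

    def rsid_for(self, chrom: int, pos: int, a1: str, a2: str) -> str | None:
        return self._by_meta.get((chrom, pos, frozenset((a1, a2))))

    def meta_for(self, rsid: str) -> tuple[int, int, frozenset] | None:
        return self._by_rsid.get(rsid)

    def maf(self, rsid: str) -> float:
        return self._maf[rsid]


def qc_filter_records(raw: pd.DataFrame) -> pd.DataFrame:
    """Retain biallelic, strand-unambiguous SNVs with valid statistics."""
    df = raw.copy()
    for col in ("beta", "se", "pval", "n"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    valid = (
        df["beta"].notna()
        & (df["se"] > 0)
        & (df["pval"] > 0)
        & (df["pval"] <= 1)
        & (df["n"] > 0)
    )
    a1 = df["a1"].astype(str).str.upper()
    a2 = df["a2"].astype(str).str.upper()
    single = a1.isin(list("ACGT")) & a2.isin(list("ACGT")) & (a1 != a2)
    ambiguous = [frozenset((x, y)) in AMBIGUOUS_PAIRS for x, y in zip(a1, a2)]
    keep = valid & single & ~pd.Series(ambiguous, index=df.index)
    out = df.loc[keep].copy()
    out["a1"] = a1[keep]
    out["a2"] = a2[keep]
    if out.empty:
        raise ValueError("no records survived QC")
    return out.reset_index(drop=True)


def harmonize_variants(records: pd.DataFrame, dictionary: VariantDictionary) -> pd.DataFrame:
    """Assign dictionary rs-identifiers; rescue stale coordinates via rsid.

    Primary match on (chrom, pos, allele pair) overwrites the rsid; unmatched
    records whose original rsid exists in the dictionary with the same allele
    pair have their chromosome/position updated from the dictionary;
    still-unmatched records are dropped.
    """
    rows = []
    for r in records.itertuples(index=False):
        rsid = dictionary.rsid_for(int(r.chrom), int(r.pos), r.a1, r.a2)
        if rsid is not None:
            rows.append({**r._asdict(), "rsid": rsid})
            continue
        meta = dictionary.meta_for(r.rsid)
        if meta is not None and meta[2] == frozenset((r.a1, r.a2)):
            rows.append({**r._asdict(), "chrom": meta[0], "pos": meta[1]})
    return pd.DataFrame(rows, columns=records.columns).reset_index(drop=True)


def apply_final_filters(
    records: pd.DataFrame,
    dictionary: VariantDictionary,
    exclusion_region: tuple[int, int, int] | None = None,
    n_sd: float = 5.0,
) -> pd.DataFrame:
    """Duplicate, MAF, exclusion-region and sample-size-outlier filters.

    Duplicated rsids with *different* statistics are removed entirely;
    byte-identical duplicate rows collapse to one.  Records with dictionary
    MAF < 1%, or inside the (1-based inclusive) exclusion region, are removed.
    Finally, records whose sample size is more than ``n_sd`` population
    standard deviations from the mean of the remaining records are removed
    (skipped for fewer than 3 records or zero spread).
    """
    df = records.drop_duplicates().copy()
    counts = df["rsid"].value_counts()
    df = df[~df["rsid"].isin(counts[counts > 1].index)]

    maf = df["rsid"].map(dictionary.maf)
    df = df[maf >= 0.01]

    if exclusion_region is not None:
        chrom, start, end = exclusion_region
        inside = (df["chrom"] == chrom) & (df["pos"] >= start) & (df["pos"] <= end)
        df = df[~inside]

    if len(df) >= 3:
        n = df["n"].to_numpy(dtype=float)
        sd = n.std()  # population SD
        if sd > 0:
            df = df[np.abs(n - n.mean()) <= n_sd * sd]
    return df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def process_sumstats(
    raw: pd.DataFrame,
    dictionary: VariantDictionary,
    exclusion_region: tuple[int, int, int] | None = None,
    n_sd: float = 5.0,
) -> pd.DataFrame:
    """Run the full QC chain in its fixed order."""
    return apply_final_filters(
        harmonize_variants(qc_filter_records(raw), dictionary),
        dictionary,
        exclusion_region=exclusion_region,
        n_sd=n_sd,
    )
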