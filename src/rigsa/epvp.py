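"""Extragenic p-value push (EPVP): a matched random-augmentation control.

Per permutation, SNV-level p-values and sample sizes — arranged along their
coordinate positions within each chromosome — are shifted en masse by one
randomly-chosen circular offset per chromosome.  Each gene then reads the
shifted values at its *extragenic* SNV positions (SNVs mapped to it only via
augmentation) and the original values at its intragenic positions, so the
mapping itself, the per-gene SNV lists, and all LD quantities are untouched.
Rescoring and the full competitive gene-set analysis are re-run on each
permutation; comparing a genuine set score against the permutation mean and SD
classifies its gain as strongly validated (>= 2 SD above the mean), mildly
validated (>= 1 and < 2 SD), or invalidated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import child_rng
from .gsa import run_gsa
from .scoring import ScoringContext, rescore_from_vectors

__all__ = [
    "PermutationRun",
    "ValidationResult",
    "circular_shift",
    "epvp_assign",
    "run_epvp",
    "classify_validation",
    "ttest_genuine_vs_permuted",
    "binomial_novel_vs_lost",
    "count_comparison_tests",
]

logger = logging.getLogger(__name__)

STRONG, MILD, INVALID = "strongly_validated", "mildly_validated", "invalidated"


@dataclass
class PermutationRun:
    perm_index: int
    offsets: dict[int, int]
    gene_results: pd.DataFrame
    set_results: pd.DataFrame


@dataclass(frozen=True)
class ValidationResult:
    set_id: str
    z_genuine: float
    perm_mean: float
    perm_sd: float
    category: str


def circular_shift(values: np.ndarray, offset: int) -> np.ndarray:
    """Circularly shift so that ``output[i] = values[(i - offset) mod L]``.

    Indices surpassing the end wrap back to the start (the chromosome is
    treated as circular).
    """
    values = np.asarray(values)
    L = len(values)
    if not (0 <= offset < L):
        raise ValueError(f"offset {offset} outside [0, {L})")
    return np.roll(values, offset)


def epvp_assign(
    ctx: ScoringContext,
    offsets: dict[int, int],
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-gene (p, n) vectors under one permutation's offsets.

    Intragenic positions keep the genuine values; extragenic positions take
    the circularly shifted values.  The p-value and sample size of a SNV shift
    jointly, and a shared extragenic SNV receives the same shifted pair in
    every gene containing it.
    """
    missing = set(c for g in ctx.genes for c in [g.chrom]) - set(offsets)
    if missing:
        raise ValueError(f"offsets missing for chromosomes: {sorted(missing)}")
    shifted_p = {c: circular_shift(ctx.chrom_p[c], offsets[c]) for c in offsets if c in ctx.chrom_p}
    shifted_n = {c: circular_shift(ctx.chrom_n[c], offsets[c]) for c in offsets if c in ctx.chrom_n}
    out = {}
    for g in ctx.genes:
        p = np.where(g.intragenic, ctx.chrom_p[g.chrom][g.idx_in_chrom], shifted_p[g.chrom][g.idx_in_chrom])
        n = np.where(g.intragenic, ctx.chrom_n[g.chrom][g.idx_in_chrom], shifted_n[g.chrom][g.idx_in_chrom])
        out[g.gene_id] = (p, n)
    return out


def run_epvp(
    ctx: ScoringContext,
    gene_sets: dict[str, tuple[str, ...]] | list,
    n_perm: int = 20,
    seed: int = 0,
    set_size_range: tuple[int, int] = (25, 200),
    offsets_list: list[dict[int, int]] | None = None,
) -> list[PermutationRun]:
    """Run the full permutation control against an augmented-mapping context.

    ``ctx`` must be the scoring context of the augmented mapping (it carries
    per-gene intragenic/extragenic labels and the genuine (p, n) vectors; its
    LD eigenvalues and gene-gene correlations are reused unchanged across
    permutations).  Each permutation draws one offset per chromosome, rescores
    every gene (including the per-gene mean sample size and the score
    adjustment) and re-runs the competitive gene-set analysis.
    ``offsets_list`` overrides the random offsets (e.g. all zero for the
    identity control).
    """
    if n_perm < 2 and offsets_list is None:
        raise ValueError("n_perm must be >= 2 (permutation SD undefined otherwise)")
    chroms = sorted(ctx.chrom_p)
    runs: list[PermutationRun] = []
    if offsets_list is None:
        rngs = [child_rng(seed, f"epvp:{k}") for k in range(1, n_perm + 1)]
        offsets_list = [
            {c: int(r.integers(0, len(ctx.chrom_p[c]))) for c in chroms} for r in rngs
        ]
    for k, offsets in enumerate(offsets_list, start=1):
        shifted_p = {c: circular_shift(ctx.chrom_p[c], offsets[c]) for c in chroms}
        shifted_n = {c: circular_shift(ctx.chrom_n[c], offsets[c]) for c in chroms}
        gene_df = rescore_from_vectors(ctx, extragenic_p=shifted_p, extragenic_n=shifted_n)
        set_df = run_gsa(gene_df, gene_sets, ctx.correlations, set_size_range=set_size_range)
        runs.append(PermutationRun(k, offsets, gene_df, set_df))
    return runs


def classify_validation(
    z_genuine: float,
    perm_scores: np.ndarray | list[float],
    set_id: str = "",
) -> ValidationResult:
    """Assign a gain to a validation category from its permutation scores."""
    scores = np.asarray(perm_scores, dtype=float)
    if len(scores) < 2:
        raise ValueError("need at least 2 permutation scores")
    mean = float(scores.mean())
    sd = float(scores.std(ddof=1))
    if sd == 0:
        logger.warning("classify_validation: zero permutation SD for %s", set_id or "<set>")
        category = STRONG if z_genuine > mean else INVALID
        return ValidationResult(set_id, float(z_genuine), mean, sd, category)
    d = (z_genuine - mean) / sd
    category = STRONG if d >= 2 else MILD if d >= 1 else INVALID
    return ValidationResult(set_id, float(z_genuine), mean, sd, category)


def ttest_genuine_vs_permuted(genuine_count: float, perm_counts: np.ndarray | list[float]) -> float:
    """One-sided, one-sample t-test: is the genuine count greater than the
    permutation counts?"""
    counts = np.asarray(perm_counts, dtype=float)
    if len(counts) < 2:
        raise ValueError("need at least 2 permutation counts")
    if counts.std(ddof=1) == 0:
        logger.warning("ttest_genuine_vs_permuted: zero variance in permutation counts")
        return 0.0 if genuine_count > counts[0] else 1.0
    return float(stats.ttest_1samp(counts, genuine_count, alternative="less").pvalue)


def binomial_novel_vs_lost(novel_count: int, lost_count: int) -> float:
    """Exact one-sided binomial test: more novel than lost entities, against a
    null where both outcomes are equally likely (or losing more likely)."""
    n = novel_count + lost_count
    if n < 1:
        raise ValueError("need novel_count + lost_count >= 1")
    return float(stats.binomtest(novel_count, n, 0.5, alternative="greater").pvalue)


def count_comparison_tests(
    genuine_count: float | None = None,
    perm_counts: np.ndarray | list[float] | None = None,
    novel_count: int | None = None,
    lost_count: int | None = None,
) -> dict[str, float]:
    """Convenience wrapper bundling the two count-comparison tests."""
    out: dict[str, float] = {}
    if genuine_count is not None and perm_counts is not None:
        out["p_ttest"] = ttest_genuine_vs_permuted(genuine_count, perm_counts)
    if novel_count is not None and lost_count is not None:
        out["p_binomial"] = binomial_novel_vs_lost(novel_count, lost_count)
    return out
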