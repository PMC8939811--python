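"""Iterative reduction (IRED): robustness of a gene set's gain.

Genes from a selected set are ranked by their gene-level gain (adjusted score
under the augmented mapping minus the baseline mapping) and removed
cumulatively, top-gaining first.  After each removal the competitive gene-set
analysis is re-run for both mappings (with FDR recomputed across the full
collection) and the set-level gain recomputed on the probit scale.  The
endpoint is the smallest number of removals at which the set's gain is lost;
a gain is robust when at least the top four genes must be removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gsa import compute_gains, run_gsa
from .scoring import GeneCorrelations

__all__ = ["IredTrace", "ired_run", "classify_robust", "ROBUST_MIN_REMOVALS"]

ROBUST_MIN_REMOVALS = 4


@dataclass
class IredTrace:
    set_id: str
    removal_order: list[str]
    iterations: list[dict] = field(default_factory=list)  # iteration, removed_gene, gene_gain, set_gain
    iterations_to_loss: int = 0
    censored: bool = False
    stopped_early: bool = False

    @property
    def robust(self) -> bool:
        return classify_robust(self)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.iterations)


def _set_gain(
    set_id: str,
    members: tuple[str, ...],
    gene_sets: dict[str, tuple[str, ...]],
    baseline: tuple[pd.DataFrame, GeneCorrelations | None],
    augmented: tuple[pd.DataFrame, GeneCorrelations | None],
    set_size_range: tuple[int, int],
) -> float | None:
    """Gain of ``set_id`` with its membership replaced by ``members``; the
    full collection is re-tested so the FDR step sees every set."""
    collection = dict(gene_sets)
    collection[set_id] = members
    out = {}
    for label, (gene_results, corr) in (("baseline", baseline), ("augmented", augmented)):
        res = run_gsa(gene_results, collection, corr, set_size_range=set_size_range)
        hit = res[res["set_id"] == set_id]
        if hit.empty:
            return None
        out[label] = float(hit["z_set"].iloc[0])
    return out["augmented"] - out["baseline"]


def ired_run(
    set_id: str,
    gene_results_baseline: pd.DataFrame,
    gene_results_augmented: pd.DataFrame,
    correlations_baseline: GeneCorrelations | None,
    correlations_augmented: GeneCorrelations | None,
    gene_sets: dict[str, tuple[str, ...]] | list,
    set_size_range: tuple[int, int] = (25, 200),
    max_iters: int | None = None,
) -> IredTrace:
    """Run the iterative-reduction procedure for one gene set.

    Genes scored in only one mapping are excluded from the ranking (the
    common-universe rule); ties in gain break by gene_id.  At iteration k the
    top-k gaining genes are removed (all other sets untouched) and both
    mappings' gene-set analyses re-run.  ``iterations_to_loss`` is the
    smallest k at which the set-level gain is <= 0; a trace that never loses
    its gain within ``max_iters`` is flagged censored.
    """
    if not isinstance(gene_sets, dict):
        gene_sets = {gs.set_id: tuple(gs.gene_ids) for gs in gene_sets}
    if set_id not in gene_sets:
        raise KeyError(f"unknown gene set {set_id!r}")
    members = tuple(gene_sets[set_id])

    gene_gains = compute_gains(gene_results_baseline, gene_results_augmented, level="gene")
    gains_by_gene = dict(zip(gene_gains["entity_id"], gene_gains["gain"]))
    rankable = [g for g in members if g in gains_by_gene]
    removal_order = sorted(rankable, key=lambda g: (-gains_by_gene[g], g))
    if max_iters is None:
        max_iters = max(len(removal_order) - set_size_range[0], 0)
    max_iters = min(max_iters, len(removal_order))

    trace = IredTrace(set_id=set_id, removal_order=removal_order)
    baseline = (gene_results_baseline, correlations_baseline)
    augmented = (gene_results_augmented, correlations_augmented)

    gain0 = _set_gain(set_id, members, gene_sets, baseline, augmented, set_size_range)
    if gain0 is None:
        trace.stopped_early = True
        return trace
    trace.iterations.append({"iteration": 0, "removed_gene": None, "gene_gain": np.nan, "set_gain": gain0})
    if gain0 <= 0:
        trace.iterations_to_loss = 0
        return trace

    lost_at = None
    for k in range(1, max_iters + 1):
        removed = removal_order[:k]
        reduced = tuple(g for g in members if g not in removed)
        gain = _set_gain(set_id, reduced, gene_sets, baseline, augmented, set_size_range)
        if gain is None:
            trace.stopped_early = True
            break
        trace.iterations.append(
            {
                "iteration": k,
                "removed_gene": removed[-1],
                "gene_gain": gains_by_gene[removed[-1]],
                "set_gain": gain,
            }
        )
        if gain <= 0:
            lost_at = k
            break

    if lost_at is not None:
        trace.iterations_to_loss = lost_at
    else:
        trace.iterations_to_loss = len(trace.iterations) - 1
        trace.censored = not trace.stopped_early
    return trace


def classify_robust(trace: IredTrace) -> bool:
    """A gain is robust iff at least the top four gaining genes must be
    removed before the set-level gain is lost (censored traces count as
    robust)."""
    if trace.censored:
        return True
    return trace.iterations_to_loss >= ROBUST_MIN_REMOVALS
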